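"""Synthetic session generator: chain statistics, renderer geometry,
manifest contracts and therapist-sheet correlation."""

import numpy as np
import pytest

from engagekit.emotion import VAState
from engagekit.errors import ConfigurationError
from engagekit.facegeom import template_landmarks
from engagekit.metrics import compute_ept
from engagekit.synthetic import (SessionConfig, read_manifest,
                                 render_face_frame, simulate_assessment,
                                 simulate_session, simulate_va_trajectory)


class TestTrajectory:
    def test_absorbing_engaged_state(self):
        traj = simulate_va_trajectory(50, 1.0, 0.5, seed=0, start_engaged=True)
        assert all(s.valence > 0 and s.arousal > 0 for s in traj)

    def test_deterministic_for_fixed_seed(self):
        a = simulate_va_trajectory(200, 0.8, 0.7, seed=42)
        b = simulate_va_trajectory(200, 0.8, 0.7, seed=42)
        assert a == b

    def test_stationary_fraction_symmetric_chain(self):
        """With equal stay probabilities the stationary engaged fraction
        is 1/2; check within 3 standard errors of the correlated-sample
        mean (autocorrelation rho = p + q - 1 = 0.8)."""
        n = 20_000
        traj = simulate_va_trajectory(n, 0.9, 0.9, seed=7)
        frac = np.mean([s.valence > 0 and s.arousal > 0 for s in traj])
        rho = 0.8
        se = 0.5 / np.sqrt(n * (1 - rho) / (1 + rho))
        assert abs(frac - 0.5) < 3 * se

    def test_rejects_bad_arguments(self):
        with pytest.raises(ValueError):
            simulate_va_trajectory(0, 0.5, 0.5, seed=0)
        with pytest.raises(ValueError):
            simulate_va_trajectory(10, 1.5, 0.5, seed=0)

    def test_margin_respected(self):
        traj = simulate_va_trajectory(500, 0.5, 0.5, seed=3, va_margin=0.1)
        for s in traj:
            assert abs(s.valence) >= 0.1 and abs(s.arousal) >= 0.1


class TestRenderer:
    def test_deterministic(self):
        cfg = SessionConfig(seed=0)
        va = VAState(0.5, 0.5)
        img1, _ = render_face_frame(va, cfg, np.random.default_rng(9))
        img2, _ = render_face_frame(va, cfg, np.random.default_rng(9))
        assert np.array_equal(img1, img2)

    def test_landmarks_inside_bbox(self):
        cfg = SessionConfig(seed=0)
        rng = np.random.default_rng(1)
        for _ in range(100):
            va = VAState(*rng.uniform(-1, 1, 2))
            _, truth = render_face_frame(va, cfg, rng)
            x, y, w, h = truth.bbox
            assert (truth.landmarks[:, 0] >= x).all()
            assert (truth.landmarks[:, 0] <= x + w).all()
            assert (truth.landmarks[:, 1] >= y).all()
            assert (truth.landmarks[:, 1] <= y + h).all()

    def test_mouth_corner_rises_with_valence(self):
        """Corner elevation (smaller y) strictly increases with valence
        at fixed arousal, on a grid of values."""
        for arousal in (-0.8, 0.0, 0.8):
            corner_y = [template_landmarks(v, arousal)[48, 1]
                        for v in np.linspace(-0.9, 0.9, 7)]
            assert all(a > b for a, b in zip(corner_y, corner_y[1:]))
        lo = template_landmarks(-0.9, 0.0)[48, 1]
        hi = template_landmarks(0.9, 0.0)[48, 1]
        assert hi < lo

    def test_eye_and_mouth_opening_grow_with_arousal(self):
        for valence in (-0.8, 0.0, 0.8):
            eye_open, mouth_open = [], []
            for a in np.linspace(-0.9, 0.9, 7):
                lm = template_landmarks(valence, a)
                eye_open.append(lm[41, 1] - lm[37, 1])
                mouth_open.append(lm[57, 1] - lm[51, 1])
            assert all(x < y for x, y in zip(eye_open, eye_open[1:]))
            assert all(x < y for x, y in zip(mouth_open, mouth_open[1:]))

    def test_too_small_image_rejected(self):
        with pytest.raises(ConfigurationError):
            SessionConfig(image_size=(40, 40))

    def test_no_face_frame(self):
        cfg = SessionConfig(no_face_prob=0.9999, seed=0)
        _, truth = render_face_frame(VAState(0.5, 0.5), cfg,
                                     np.random.default_rng(0))
        assert not truth.face_present
        assert truth.bbox is None and truth.landmarks is None
        assert truth.engaged  # engagement is defined from the VA quadrant


class TestSession:
    def test_printed_frame_counts(self, tmp_path):
        """Durations 19/8/19 s at per-task rates near 10 fps reproduce
        the published 186/84/187 frame counts."""
        cfg = SessionConfig(task_durations_s=(19, 8, 19),
                            fps=(9.79, 10.5, 9.84), seed=0)
        assert cfg.frames_per_task == (186, 84, 187)
        session = simulate_session(cfg, tmp_path / "s")
        manifest = read_manifest(session)
        counts = manifest.groupby("task_id")["frame_id"].count()
        assert tuple(counts[f"task_{i}"] for i in (1, 2, 3)) == (186, 84, 187)

    def test_fps_round_arithmetic(self):
        assert SessionConfig(n_tasks=1, task_durations_s=(10.0,),
                             fps=10.0).frames_per_task == (100,)

    def test_quadrant_consistency_and_conservation(self, tiny_session):
        session, config = tiny_session
        manifest = read_manifest(session)
        assert len(manifest) == sum(config.frames_per_task)
        n_files = sum(1 for d in session.iterdir() if d.is_dir()
                      for _ in d.glob("*.png"))
        assert n_files == len(manifest)
        engaged = manifest["engaged"].astype(bool)
        quadrant = (manifest["valence"] > 0) & (manifest["arousal"] > 0)
        assert (engaged == quadrant).all()

    def test_all_faces_present_when_prob_zero(self, tiny_session):
        session, _ = tiny_session
        manifest = read_manifest(session)
        assert manifest["face_present"].all()

    def test_manifest_byte_identical_across_runs(self, tmp_path):
        cfg = SessionConfig(n_tasks=1, task_durations_s=(1.0,), fps=5.0,
                            seed=21, landmark_noise_px=1.0)
        a = simulate_session(cfg, tmp_path / "a")
        b = simulate_session(cfg, tmp_path / "b")
        assert (a / "manifest.csv").read_bytes() == (b / "manifest.csv").read_bytes()
        assert ((a / "task_1" / "frame_000000.png").read_bytes()
                == (b / "task_1" / "frame_000000.png").read_bytes())


class TestAssessment:
    def test_extremes_without_noise(self):
        sheets = simulate_assessment([1.0, 0.0], rater_noise_sd=0.0, seed=0)
        assert sheets[0].item_scores == (3,) * 8
        assert sheets[0].sum_points == 24
        assert compute_ept(sheets[0]) == 100.0
        assert sheets[1].item_scores == (0,) * 8
        assert compute_ept(sheets[1]) == 0.0

    def test_rejects_negative_noise(self):
        with pytest.raises(ValueError):
            simulate_assessment([0.5], rater_noise_sd=-0.1, seed=0)

    def test_scores_track_true_fraction(self):
        """Monte-Carlo check of the rater noise model: totals correlate
        strongly with the true engaged fractions."""
        rng = np.random.default_rng(17)
        fractions = rng.uniform(0, 1, size=200)
        sheets = simulate_assessment(fractions, rater_noise_sd=0.1, seed=17)
        totals = [s.sum_points for s in sheets]
        r = np.corrcoef(totals, fractions)[0, 1]
        assert r > 0.8
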