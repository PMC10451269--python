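"""Synthetic therapy-session generator.

Emulates what the analysis pipeline consumes from a real session: a
~10 fps stream of face-visible grayscale frames for one child across a
few short tasks, plus a per-frame ground-truth manifest and correlated
therapist assessment sheets. Engagement dynamics follow a two-state
Markov chain over {engaged, disengaged}; the engaged state emits
valence/arousal from the positive-positive quadrant, the disengaged
state uniformly from the other three quadrants. Frames are schematic
faces whose geometry encodes the emitted (valence, arousal) (see
:mod:`engagekit.facegeom`), with optional Gaussian landmark jitter and
occasional faceless frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .emotion import VAState, map_va_to_engagement, EngagementLabel
from .errors import ConfigurationError
from .facegeom import LEVELS, draw_face, map_to_box, template_landmarks
from .metrics import AssessmentSheet, round_half_up

#: minimum |valence| and |arousal| of emitted affect states. Exactly
#: neutral affect is not a meaningful emitted state in the quadrant
#: model, and the margin keeps the rendered expression resolvable at
#: pixel scale.
VA_MARGIN = 0.1

#: face-box height as a fraction of image height, and width/height aspect
FACE_HEIGHT_FRAC = 0.75
FACE_ASPECT = 0.8

N_ASSESSMENT_ITEMS = 8
MAX_ITEM_SCORE = 3


@dataclass(frozen=True)
class SessionConfig:
    """Parameters of one simulated session."""

    n_tasks: int = 3
    task_durations_s: Sequence[float] = (19.0, 8.0, 19.0)
    fps: float | Sequence[float] = 10.0
    engage_stay_prob: float = 0.9
    disengage_stay_prob: float = 0.9
    landmark_noise_px: float = 0.0
    no_face_prob: float = 0.0
    image_size: tuple[int, int] = (128, 128)
    seed: int = 0
    va_margin: float = VA_MARGIN
    start_engaged: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.n_tasks < 1:
            raise ConfigurationError("n_tasks must be >= 1")
        if len(self.task_durations_s) != self.n_tasks:
            raise ConfigurationError("need one duration per task")
        if any(d <= 0 for d in self.task_durations_s):
            raise ConfigurationError("task durations must be > 0")
        if any(f <= 0 for f in self.fps_per_task):
            raise ConfigurationError("fps must be > 0")
        for name in ("engage_stay_prob", "disengage_stay_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.no_face_prob < 1.0:
            raise ConfigurationError("no_face_prob must be in [0, 1)")
        if self.landmark_noise_px < 0:
            raise ConfigurationError("landmark_noise_px must be >= 0")
        h, w = self.image_size
        if h < 64 or w < 64:
            raise ConfigurationError(
                f"image too small for the face template: {self.image_size}")

    @property
    def fps_per_task(self) -> tuple[float, ...]:
        if isinstance(self.fps, (int, float)):
            return (float(self.fps),) * self.n_tasks
        if len(self.fps) != self.n_tasks:
            raise ConfigurationError("need one fps per task")
        return tuple(float(f) for f in self.fps)

    @property
    def frames_per_task(self) -> tuple[int, ...]:
        return tuple(int(round(d * f))
                     for d, f in zip(self.task_durations_s, self.fps_per_task))


@dataclass
class FrameTruth:
    """Ground truth for one rendered frame. ``engaged`` is defined from
    the emitted VA quadrant only, so it stays meaningful on frames where
    the face is absent."""

    frame_index: int
    task_id: str
    t_seconds: float
    va: VAState
    engaged: bool
    face_present: bool
    bbox: Optional[tuple[int, int, int, int]] = None
    landmarks: Optional[np.ndarray] = None


def sample_va(rng: np.random.Generator, engaged: bool,
              margin: float = VA_MARGIN) -> VAState:
    """Emit a VA point for one chain state.

    Engaged: both coordinates uniform on [margin, 1]. Disengaged: a
    quadrant chosen uniformly from the other three, magnitudes uniform
    on [margin, 1].
    """
    mag_v, mag_a = rng.uniform(margin, 1.0, size=2)
    if engaged:
        return VAState(mag_v, mag_a)
    sign_v, sign_a = ((-1, 1), (-1, -1), (1, -1))[rng.integers(3)]
    return VAState(sign_v * mag_v, sign_a * mag_a)


def simulate_va_trajectory(
    n_frames: int,
    engage_stay_prob: float,
    disengage_stay_prob: float,
    seed: int,
    va_margin: float = VA_MARGIN,
    start_engaged: Optional[bool] = None,
) -> list[VAState]:
    """Two-state Markov chain over {engaged, disengaged} emitting VA points.

    The start state defaults to a draw from the chain's stationary
    distribution (uniform if both stay-probabilities are 1). Identical
    arguments produce identical trajectories.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    for name, p in (("engage_stay_prob", engage_stay_prob),
                    ("disengage_stay_prob", disengage_stay_prob)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")

    rng = np.random.default_rng(seed)
    if start_engaged is None:
        leave_e = 1.0 - engage_stay_prob
        leave_d = 1.0 - disengage_stay_prob
        p_engaged = 0.5 if leave_e + leave_d == 0 else leave_d / (leave_e + leave_d)
        state = rng.random() < p_engaged
    else:
        state = bool(start_engaged)

    out = []
    for _ in range(n_frames):
        out.append(sample_va(rng, state, va_margin))
        stay = engage_stay_prob if state else disengage_stay_prob
        if rng.random() >= stay:
            state = not state
    return out


def _face_box(config: SessionConfig,
              rng: np.random.Generator) -> tuple[int, int, int, int]:
    img_h, img_w = config.image_size
    fh = int(round(FACE_HEIGHT_FRAC * img_h))
    fw = int(round(FACE_ASPECT * fh))
    if fw >= img_w:
        fw = img_w - 2
        fh = int(round(fw / FACE_ASPECT))
    # small positional jitter, as a head is never perfectly centred
    max_dx = max((img_w - fw) // 2 - 1, 0)
    max_dy = max((img_h - fh) // 2 - 1, 0)
    dx = int(rng.integers(-max_dx, max_dx + 1)) if max_dx else 0
    dy = int(rng.integers(-max_dy, max_dy + 1)) if max_dy else 0
    return ((img_w - fw) // 2 + dx, (img_h - fh) // 2 + dy, fw, fh)


def render_face_frame(
    va: VAState,
    config: SessionConfig,
    rng: np.random.Generator,
    frame_index: int = 0,
    task_id: str = "task_1",
    t_seconds: float = 0.0,
) -> tuple[np.ndarray, FrameTruth]:
    """Render one frame and its ground truth.

    With probability ``no_face_prob`` the frame is a faceless background
    and ``bbox``/``landmarks`` are absent. Otherwise the schematic face
    is drawn from the template landmarks jittered by i.i.d. Gaussian
    noise of ``landmark_noise_px``; the truth records the jittered
    (drawn) landmark positions exactly.
    """
    img_h, img_w = config.image_size
    canvas = np.full((img_h, img_w), LEVELS["bg"], dtype=np.uint8)

    engaged = map_va_to_engagement(va) is EngagementLabel.ENGAGED
    if rng.random() < config.no_face_prob:
        truth = FrameTruth(frame_index, task_id, t_seconds, va, engaged,
                           face_present=False)
        return canvas, truth

    box = _face_box(config, rng)
    lm = map_to_box(template_landmarks(va.valence, va.arousal), *box)
    if config.landmark_noise_px > 0:
        lm = lm + rng.normal(0.0, config.landmark_noise_px, size=lm.shape)
    draw_face(canvas, lm, box)
    truth = FrameTruth(frame_index, task_id, t_seconds, va, engaged,
                       face_present=True, bbox=box, landmarks=lm)
    return canvas, truth


MANIFEST_NAME = "manifest.csv"


def _manifest_row(frame_id: str, truth: FrameTruth) -> dict:
    row = {
        "frame_id": frame_id,
        "task_id": truth.task_id,
        "t_seconds": round(truth.t_seconds, 6),
        "valence": round(truth.va.valence, 9),
        "arousal": round(truth.va.arousal, 9),
        "engaged": int(truth.engaged),
        "face_present": int(truth.face_present),
    }
    bbox = truth.bbox if truth.bbox is not None else ("", "", "", "")
    for key, val in zip(("bbox_x", "bbox_y", "bbox_w", "bbox_h"), bbox):
        row[key] = val
    for i in range(68):
        if truth.landmarks is None:
            row[f"lm_{i}_x"] = row[f"lm_{i}_y"] = ""
        else:
            row[f"lm_{i}_x"] = round(float(truth.landmarks[i, 0]), 4)
            row[f"lm_{i}_y"] = round(float(truth.landmarks[i, 1]), 4)
    return row


def simulate_session(config: SessionConfig, out_dir: str | Path) -> Path:
    """Write a full session: per-task PNG frame directories + manifest.

    Layout: ``out_dir/task_<k>/frame_<nnnnnn>.png`` and
    ``out_dir/manifest.csv`` with one row per frame. Returns the session
    directory. Frame counts are ``round(duration * fps)`` per task.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    rows = []
    for t_idx, (n_frames, fps) in enumerate(
            zip(config.frames_per_task, config.fps_per_task), start=1):
        task_id = f"task_{t_idx}"
        task_dir = out / task_id
        task_dir.mkdir(exist_ok=True)
        traj = simulate_va_trajectory(
            n_frames, config.engage_stay_prob, config.disengage_stay_prob,
            seed=int(rng.integers(2**31)), va_margin=config.va_margin,
            start_engaged=config.start_engaged)
        for i, va in enumerate(traj):
            image, truth = render_face_frame(
                va, config, rng, frame_index=i, task_id=task_id,
                t_seconds=i / fps)
            name = f"frame_{i:06d}.png"
            iio.imwrite(task_dir / name, image)
            rows.append(_manifest_row(f"{task_id}/{name}", truth))

    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / MANIFEST_NAME, index=False)
    return out


def read_manifest(session_dir: str | Path) -> pd.DataFrame:
    """Load a session's ground-truth manifest."""
    return pd.read_csv(Path(session_dir) / MANIFEST_NAME)


def true_task_fractions(manifest: pd.DataFrame) -> dict[str, float]:
    """Per-task ground-truth engaged fraction from a manifest."""
    return manifest.groupby("task_id", sort=True)["engaged"].mean().to_dict()


def simulate_assessment(
    true_fractions: Sequence[float],
    rater_noise_sd: float,
    seed: int,
    child_id: str = "C1",
) -> list[AssessmentSheet]:
    """Therapist sheets correlated with the true engaged fractions.

    Each of the 8 items of task ``k`` is scored
    ``clip(round(3 * (fraction_k + noise)), 0, 3)`` with item-wise
    Gaussian noise, mimicking a rater who agrees more, the more of the
    task the child spent engaged.
    """
    if rater_noise_sd < 0:
        raise ValueError("rater_noise_sd must be >= 0")
    if any(not 0.0 <= f <= 1.0 for f in true_fractions):
        raise ValueError("fractions must be in [0, 1]")
    rng = np.random.default_rng(seed)
    sheets = []
    for t_idx, frac in enumerate(true_fractions, start=1):
        noise = rng.normal(0.0, rater_noise_sd, size=N_ASSESSMENT_ITEMS)
        items = [
            int(min(max(round_half_up(MAX_ITEM_SCORE * (frac + e)), 0),
                    MAX_ITEM_SCORE))
            for e in noise
        ]
        sheets.append(AssessmentSheet(task_id=f"task_{t_idx}",
                                      item_scores=tuple(items),
                                      child_id=child_id))
    return sheets


def write_assessment_csv(sheets: Sequence[AssessmentSheet],
                         path: str | Path) -> Path:
    """Serialize sheets as CSV: child_id, task_id, item_1 ... item_8."""
    rows = []
    for s in sheets:
        row = {"child_id": s.child_id, "task_id": s.task_id}
        row.update({f"item_{i + 1}": v for i, v in enumerate(s.item_scores)})
        rows.append(row)
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_assessment_csv(path: str | Path) -> list[AssessmentSheet]:
    df = pd.read_csv(path)
    item_cols = [f"item_{i + 1}" for i in range(N_ASSESSMENT_ITEMS)]
    return [
        AssessmentSheet(task_id=str(r["task_id"]),
                        item_scores=tuple(int(r[c]) for c in item_cols),
                        child_id=str(r["child_id"]))
        for _, r in df.iterrows()
    ]
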