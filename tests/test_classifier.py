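"""Landmark rasterization and the convolutional frame classifier."""

import numpy as np
import pytest
from skimage.feature import peak_local_max

from engagekit.classifier import (ClassifierSpec, ENGAGED, NOT_ENGAGED,
                                  WINDOW_X, WINDOW_Y, build_classifier,
                                  classify_frames, load_checkpoint,
                                  make_landmark_dataset, rasterize_landmarks,
                                  save_checkpoint, train_classifier)
from engagekit.emotion import EngagementLabel
from engagekit.errors import ConfigurationError
from engagekit.facegeom import map_to_box, template_landmarks


class TestRasterize:
    def test_well_separated_points_give_distinct_maxima(self):
        """68 blobs spaced at least 4 raster pixels apart stay separate."""
        xs = np.linspace(WINDOW_X[0] + 0.2, WINDOW_X[1] - 0.2, 9)
        ys = np.linspace(WINDOW_Y[0] + 0.2, WINDOW_Y[1] - 0.2, 8)
        grid = np.array([(x, y) for y in ys for x in xs])[:68]
        raster = rasterize_landmarks(grid, (64, 64))
        peaks = peak_local_max(raster, min_distance=1, threshold_abs=0.5)
        assert len(peaks) == 68

    def test_intensity_contract(self):
        lm = template_landmarks(0.5, 0.5) * 2 - 0.5  # roughly in-window
        from engagekit.faces import normalize_landmarks
        raster = rasterize_landmarks(
            normalize_landmarks(map_to_box(template_landmarks(0.5, 0.5),
                                           0, 0, 80, 100)))
        assert raster.min() == 0.0 and raster.max() == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            rasterize_landmarks(np.empty((0, 2)))

    def test_out_of_window_points_clipped_with_warning(self):
        pts = np.array([[5.0, 5.0], [0.0, 0.0]])
        with pytest.warns(UserWarning, match="clipped"):
            raster = rasterize_landmarks(pts)
        assert raster.max() == 1.0


class TestArchitecture:
    def test_layer_sequence_matches_published_recipe(self):
        model = build_classifier(ClassifierSpec(seed=0))
        assert model.describe() == [
            ("conv", 32, (3, 3)), ("relu",), ("maxpool", (2, 2)),
            ("conv", 32, (3, 3)), ("relu",), ("maxpool", (2, 2)),
            ("conv", 64, (3, 3)), ("relu",), ("maxpool", (2, 2)),
            ("flatten",), ("dense", 2),
        ]

    def test_output_is_two_way(self):
        model = build_classifier(ClassifierSpec(seed=0))
        out = model.forward(np.zeros((3, 1, 64, 64), dtype=np.float32))
        assert out.shape == (3, 2)

    def test_same_seed_identical_initialization(self):
        m1 = build_classifier(ClassifierSpec(seed=7))
        m2 = build_classifier(ClassifierSpec(seed=7))
        for p1, p2 in zip(m1.params, m2.params):
            assert np.array_equal(p1, p2)

    def test_spec_rejects_deviations(self):
        with pytest.raises(ConfigurationError):
            ClassifierSpec(conv_filters=(16, 32, 64))
        with pytest.raises(ConfigurationError):
            ClassifierSpec(kernel=(5, 5))
        with pytest.raises(ConfigurationError):
            ClassifierSpec(input_size=(16, 16))


class TestTraining:
    def test_deterministic_history(self):
        spec = ClassifierSpec(input_size=(32, 32), seed=3)
        x, y = make_landmark_dataset(120, seed=3, spec=spec)
        h1 = train_classifier(build_classifier(spec), x, y, epochs=2,
                              seed=3, spec=spec).history
        h2 = train_classifier(build_classifier(spec), x, y, epochs=2,
                              seed=3, spec=spec).history
        assert h1 == h2

    def test_single_class_rejected(self):
        spec = ClassifierSpec(input_size=(32, 32), seed=0)
        x, y = make_landmark_dataset(40, seed=0, spec=spec)
        with pytest.raises(ValueError):
            train_classifier(build_classifier(spec), x,
                             np.zeros_like(y), epochs=1, seed=0)

    def test_permuted_labels_give_chance_accuracy(self):
        """Label permutation destroys the landmark-engagement link, so
        held-out accuracy falls to chance."""
        spec = ClassifierSpec(input_size=(32, 32), seed=1)
        x, y = make_landmark_dataset(500, seed=1, spec=spec)
        rng = np.random.default_rng(123)
        trained = train_classifier(build_classifier(spec), x,
                                   rng.permutation(y), epochs=3, seed=1,
                                   spec=spec)
        assert 0.4 <= trained.history[-1]["val_accuracy"] <= 0.6


class TestClassifyFrames:
    def test_record_conservation_and_no_face_flags(self, small_trained):
        lm = map_to_box(template_landmarks(0.6, 0.6), 0, 0, 80, 100)
        sets = [lm, None, lm, None]
        records = classify_frames(small_trained, sets)
        assert len(records) == 4
        assert [r.face_present for r in records] == [True, False, True, False]
        assert records[1].label is None
        assert records[0].label in (EngagementLabel.ENGAGED,
                                    EngagementLabel.NOT_ENGAGED)

    def test_all_blank_session(self, small_trained):
        records = classify_frames(small_trained, [None] * 5)
        assert all(not r.face_present for r in records)


def test_checkpoint_round_trip(tmp_path, small_trained):
    path = save_checkpoint(small_trained, tmp_path / "model.npz")
    loaded = load_checkpoint(path)
    assert loaded.spec == small_trained.spec
    assert loaded.history == small_trained.history
    x = np.zeros((2, 1, 32, 32), dtype=np.float32)
    assert np.allclose(loaded.model.forward(x),
                       small_trained.model.forward(x))
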