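import numpy as np
import pytest

from engagekit.classifier import (ClassifierSpec, build_classifier,
                                  make_landmark_dataset, train_classifier)
from engagekit.synthetic import SessionConfig, simulate_session


@pytest.fixture(scope="session")
def tiny_session(tmp_path_factory):
    """A small zero-noise two-task session (20 frames) on disk."""
    config = SessionConfig(n_tasks=2, task_durations_s=(2.0, 2.0), fps=5.0,
                           seed=5)
    out = tmp_path_factory.mktemp("session")
    return simulate_session(config, out), config


@pytest.fixture(scope="session")
def small_trained():
    """A quickly trained 32x32 classifier for structural pipeline tests."""
    spec = ClassifierSpec(input_size=(32, 32), seed=0)
    x, y = make_landmark_dataset(600, seed=0, spec=spec)
    model = build_classifier(spec)
    return train_classifier(model, x, y, epochs=2, seed=0, spec=spec)
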