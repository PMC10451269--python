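"""End-to-end session analysis.

``run_pipeline`` chains the stages the measurement framework defines:
frame extraction -> face detection -> landmark extraction -> per-frame
classification -> per-task engagement percentage -> per-child overall.
A failure on a single frame (no face, unresolvable landmarks) never
aborts the session; the frame is flagged no-face and counted according
to the chosen policy.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import __version__
from .classifier import TrainedClassifier, classify_frames, load_checkpoint
from .errors import DataError, EngagekitError, ExtractionError
from .faces import detect_face, extract_landmarks
from .metrics import (ChildSessionResult, TaskMetrics, compute_task_epm,
                      NO_FACE_POLICIES)
from .video_io import extract_frames


@dataclass(frozen=True)
class RunConfig:
    """Parameters of one analysis run; hashed into the report so a run
    can be reproduced from its own output."""

    session_dir: str
    model_path: str
    child_id: str = "C1"
    backend: str = "synthetic"
    no_face_policy: str = "count_not_engaged"
    target_fps: float | str = "native"
    native_fps: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.no_face_policy not in NO_FACE_POLICIES:
            raise DataError(f"no_face_policy must be one of {NO_FACE_POLICIES}")

    def to_dict(self) -> dict:
        return {
            "session_dir": str(self.session_dir),
            "model_path": str(self.model_path),
            "child_id": self.child_id,
            "backend": self.backend,
            "no_face_policy": self.no_face_policy,
            "target_fps": self.target_fps,
            "native_fps": self.native_fps,
            "seed": self.seed,
        }

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _task_dirs(session_dir: Path) -> list[Path]:
    dirs = sorted(p for p in session_dir.iterdir() if p.is_dir())
    if not dirs:
        raise DataError(f"no task directories under {session_dir}")
    return dirs


def analyze_task(
    task_dir: Path,
    trained: TrainedClassifier,
    config: RunConfig,
) -> tuple[TaskMetrics, int]:
    """Classify every frame of one task directory; returns the task
    metrics and the number of frames where landmark extraction failed
    despite a detected face."""
    frames = extract_frames(task_dir, config.target_fps, config.native_fps)
    landmark_sets: list[Optional[np.ndarray]] = []
    n_extraction_failures = 0
    for frame in frames:
        box = detect_face(frame, backend=config.backend)
        if box is None:
            landmark_sets.append(None)
            continue
        try:
            landmark_sets.append(
                extract_landmarks(frame, box, backend=config.backend))
        except ExtractionError:
            n_extraction_failures += 1
            landmark_sets.append(None)
    records = classify_frames(trained, landmark_sets)
    metrics = compute_task_epm(records, config.no_face_policy,
                               task_id=task_dir.name)
    return metrics, n_extraction_failures


def run_pipeline(config: RunConfig,
                 trained: Optional[TrainedClassifier] = None) -> dict:
    """Analyze a session directory and return the JSON-ready report."""
    session_dir = Path(config.session_dir)
    if not session_dir.is_dir():
        raise DataError(f"session directory not found: {session_dir}")
    if trained is None:
        trained = load_checkpoint(config.model_path)

    task_metrics = []
    extraction_failures = 0
    for task_dir in _task_dirs(session_dir):
        metrics, n_fail = analyze_task(task_dir, trained, config)
        task_metrics.append(metrics)
        extraction_failures += n_fail

    result = ChildSessionResult(child_id=config.child_id,
                                task_metrics=tuple(task_metrics))
    report = result.to_dict()
    report.update({
        "no_face_policy": config.no_face_policy,
        "n_extraction_failures": extraction_failures,
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "seed": config.seed,
        "version": __version__,
    })
    return report
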