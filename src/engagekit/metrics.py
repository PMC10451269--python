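"""Session-level engagement metrics.

Two percentages quantify a child's engagement in a task:

* EPM (engagement percentage, model):
  ``100 * engaged_frames / total_frames`` from per-frame classifier
  labels;
* EPT (engagement percentage, therapist): ``100 * sum_points /
  max_points`` from the 8-item, 0-3 scale behaviour sheet (24 points
  maximum per task).

Per-child overall values are the unweighted arithmetic mean of the
per-task percentages, rounded half-up to an integer percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .emotion import EngagementLabel
from .errors import UndefinedMetricError

NO_FACE_POLICIES = ("count_not_engaged", "exclude")


def round_half_up(x: float) -> int:
    """Round to nearest integer, ties away from .5 upward (83.5 -> 84)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class FrameLabelRecord:
    """One frame's classification outcome. ``label`` is ``None`` when no
    face was found; the no-face policy decides how such frames enter the
    metric."""

    index: int
    face_present: bool
    label: Optional[EngagementLabel]


@dataclass(frozen=True)
class TaskMetrics:
    task_id: str
    n_frames_total: int
    n_frames_engaged: int
    n_frames_no_face: int
    epm_percent: float
    policy: str = "count_not_engaged"

    def to_dict(self) -> dict:
        return {
            "task_id": self.task_id,
            "n_frames_total": self.n_frames_total,
            "n_frames_engaged": self.n_frames_engaged,
            "n_frames_no_face": self.n_frames_no_face,
            "epm_percent": round(self.epm_percent, 2),
            "policy": self.policy,
        }


def compute_task_epm(
    records: Sequence[FrameLabelRecord],
    no_face_policy: str = "count_not_engaged",
    task_id: str = "task",
) -> TaskMetrics:
    """EPM for one task from per-frame records.

    Under ``count_not_engaged`` (default) no-face frames stay in the
    denominator as not engaged; under ``exclude`` they are dropped from
    numerator and denominator alike.
    """
    if no_face_policy not in NO_FACE_POLICIES:
        raise ValueError(f"unknown no_face_policy {no_face_policy!r}")
    if len(records) == 0:
        raise UndefinedMetricError("no frame records")

    n_no_face = sum(1 for r in records if not r.face_present)
    n_engaged = sum(1 for r in records
                    if r.face_present and r.label is EngagementLabel.ENGAGED)
    n_total = len(records)
    if no_face_policy == "exclude":
        n_total -= n_no_face
    if n_total == 0:
        raise UndefinedMetricError(
            f"no frames left in task {task_id!r} after policy {no_face_policy!r}")
    return TaskMetrics(
        task_id=task_id,
        n_frames_total=n_total,
        n_frames_engaged=n_engaged,
        n_frames_no_face=n_no_face,
        epm_percent=100.0 * n_engaged / n_total,
        policy=no_face_policy,
    )


def _aggregate(values: Sequence[float], what: str) -> int:
    if len(values) == 0:
        raise ValueError(f"need at least one task {what} value")
    if any(not 0.0 <= v <= 100.0 for v in values):
        raise ValueError(f"{what} values must be in [0, 100]")
    return round_half_up(sum(values) / len(values))


def aggregate_child_epm(task_epms: Sequence[float]) -> int:
    """Per-child overall EPM: unweighted mean of task EPMs, rounded
    half-up to an integer percent."""
    return _aggregate(task_epms, "EPM")


def aggregate_child_ept(task_epts: Sequence[float]) -> int:
    """Per-child overall EPT, same aggregation rule as EPM."""
    return _aggregate(task_epts, "EPT")


N_ITEMS = 8
MAX_POINTS = 24  # 8 items x 0-3 scale


@dataclass(frozen=True)
class AssessmentSheet:
    """One task's therapist sheet: 8 items on a 0 ("strongly disagree")
    to 3 ("strongly agree") scale, 24 points maximum."""

    task_id: str
    item_scores: tuple[int, ...]
    child_id: str = "C1"

    def __post_init__(self) -> None:
        if len(self.item_scores) != N_ITEMS:
            raise ValueError(f"expected {N_ITEMS} items, got {len(self.item_scores)}")
        if any(not (isinstance(s, int) and 0 <= s <= 3) for s in self.item_scores):
            raise ValueError(f"item scores must be integers in 0..3: {self.item_scores}")

    @property
    def sum_points(self) -> int:
        return sum(self.item_scores)

    @property
    def max_points(self) -> int:
        return MAX_POINTS

    @property
    def ept_percent(self) -> float:
        return compute_ept(self)


def compute_ept(sheet: AssessmentSheet) -> float:
    """EPT for one sheet: 100 * sum of points / maximum points."""
    return 100.0 * sheet.sum_points / sheet.max_points


@dataclass(frozen=True)
class ChildSessionResult:
    """One child's session: per-task metrics plus rounded overalls."""

    child_id: str
    task_metrics: tuple[TaskMetrics, ...]
    assessment: tuple[AssessmentSheet, ...] = ()

    @property
    def overall_epm_percent(self) -> int:
        return aggregate_child_epm([t.epm_percent for t in self.task_metrics])

    @property
    def overall_ept_percent(self) -> Optional[int]:
        if not self.assessment:
            return None
        return aggregate_child_ept([s.ept_percent for s in self.assessment])

    def to_dict(self) -> dict:
        out = {
            "child_id": self.child_id,
            "task_metrics": [t.to_dict() for t in self.task_metrics],
            "overall_epm_percent": self.overall_epm_percent,
        }
        if self.assessment:
            out["task_ept_percent"] = [s.ept_percent for s in self.assessment]
            out["overall_ept_percent"] = self.overall_ept_percent
        return out
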