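"""Engagement percentages (model and therapist) and their aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from engagekit.emotion import EngagementLabel
from engagekit.errors import UndefinedMetricError
from engagekit.metrics import (AssessmentSheet, FrameLabelRecord,
                               aggregate_child_epm, aggregate_child_ept,
                               compute_ept, compute_task_epm, round_half_up)


def _records(n_engaged, n_not, n_no_face=0):
    records = []
    i = 0
    for _ in range(n_engaged):
        records.append(FrameLabelRecord(i, True, EngagementLabel.ENGAGED)); i += 1
    for _ in range(n_not):
        records.append(FrameLabelRecord(i, True, EngagementLabel.NOT_ENGAGED)); i += 1
    for _ in range(n_no_face):
        records.append(FrameLabelRecord(i, False, None)); i += 1
    return records


class TestTaskEpm:
    @pytest.mark.parametrize("n_engaged,n_total,expected", [
        (0, 100, 0.0),
        (100, 100, 100.0),
        (121, 186, 100 * 121 / 186),  # prints as the published 65%
    ])
    def test_direct_division(self, n_engaged, n_total, expected):
        m = compute_task_epm(_records(n_engaged, n_total - n_engaged))
        assert m.epm_percent == pytest.approx(expected)
        assert round_half_up(m.epm_percent) == round_half_up(expected)

    def test_no_face_policies(self):
        records = _records(30, 50, n_no_face=20)
        default = compute_task_epm(records, "count_not_engaged")
        assert default.n_frames_total == 100
        assert default.epm_percent == pytest.approx(30.0)
        excl = compute_task_epm(records, "exclude")
        assert excl.n_frames_total == 80
        assert excl.epm_percent == pytest.approx(37.5)
        assert excl.n_frames_no_face == 20

    def test_empty_and_degenerate(self):
        with pytest.raises(UndefinedMetricError):
            compute_task_epm([])
        with pytest.raises(UndefinedMetricError):
            compute_task_epm(_records(0, 0, n_no_face=5), "exclude")
        with pytest.raises(ValueError):
            compute_task_epm(_records(1, 1), "bogus")

    @settings(derandomize=True, max_examples=200)
    @given(n_engaged=st.integers(0, 300), n_not=st.integers(0, 300),
           seed=st.integers(0, 10_000))
    def test_bounds_and_permutation_invariance(self, n_engaged, n_not, seed):
        if n_engaged + n_not == 0:
            return
        records = _records(n_engaged, n_not)
        m = compute_task_epm(records)
        assert 0.0 <= m.epm_percent <= 100.0
        shuffled = list(records)
        np.random.default_rng(seed).shuffle(shuffled)
        assert compute_task_epm(shuffled).epm_percent == m.epm_percent

    def test_monotone_in_engaged_count(self):
        total = 57
        values = [compute_task_epm(_records(k, total - k)).epm_percent
                  for k in range(total + 1)]
        assert all(a < b for a, b in zip(values, values[1:]))


class TestAggregation:
    @pytest.mark.parametrize("tasks,expected", [
        ((65, 88, 98), 84),   # published child 1
        ((7, 22, 16), 15),    # published child 4
        ((52, 0, 72), 41),    # published child 3
        ((0, 28, 0), 9),      # published child 5
        ((42.0,), 42),
        ((100, 50), 75),
        ((88, 88, 88), 88),
    ])
    def test_unweighted_mean_half_up(self, tasks, expected):
        assert aggregate_child_epm(tasks) == expected
        assert aggregate_child_ept(tasks) == expected

    def test_rejects_empty_or_out_of_range(self):
        with pytest.raises(ValueError):
            aggregate_child_epm([])
        with pytest.raises(ValueError):
            aggregate_child_epm([50, 120])

    def test_half_up_rounding(self):
        assert aggregate_child_epm([83, 84]) == 84  # 83.5 rounds up
        assert round_half_up(13.333) == 13


class TestEpt:
    def test_direct_division(self):
        full = AssessmentSheet("t", (3,) * 8)
        assert compute_ept(full) == 100.0
        empty = AssessmentSheet("t", (0,) * 8)
        assert compute_ept(empty) == 0.0
        sheet = AssessmentSheet("t", (3, 3, 3, 3, 3, 3, 0, 0))
        assert sheet.sum_points == 18
        assert compute_ept(sheet) == 75.0

    def test_item_validation(self):
        with pytest.raises(ValueError):
            AssessmentSheet("t", (4, 0, 0, 0, 0, 0, 0, 0))
        with pytest.raises(ValueError):
            AssessmentSheet("t", (1, 1, 1))

    @settings(derandomize=True, max_examples=200)
    @given(items=st.tuples(*[st.integers(0, 3)] * 8))
    def test_randomized_against_direct_division(self, items):
        sheet = AssessmentSheet("t", items)
        assert compute_ept(sheet) == pytest.approx(100.0 * sum(items) / 24)
        assert 0.0 <= compute_ept(sheet) <= 100.0
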