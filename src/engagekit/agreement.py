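"""Model-vs-therapist agreement.

Both raters' session-level percentages are binarized at an inclusive
50% threshold (>= 50 means "engaged"), then compared with Cohen's
kappa, the chance-corrected two-rater agreement statistic computed from
the 2x2 contingency table:

    kappa = (p_o - p_e) / (1 - p_e)

with p_o the observed agreement and p_e the agreement expected from the
marginal label frequencies. Kappa values are read against the
conventional interpretation bands (<= 0 none, 0.01-0.20 slight,
0.21-0.40 fair, 0.41-0.60 moderate, 0.61-0.80 substantial, 0.81-1.00
almost perfect); the gap (0, 0.01) is mapped to "slight" by continuity.

Small studies easily produce degenerate tables (a rater using a single
label); those cases are defined explicitly rather than raised, and
flagged for auditability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np


class Band(Enum):
    NO_AGREEMENT = "no_agreement"
    SLIGHT = "slight"
    FAIR = "fair"
    MODERATE = "moderate"
    SUBSTANTIAL = "substantial"
    ALMOST_PERFECT = "almost_perfect"


@dataclass(frozen=True)
class AgreementResult:
    labels_a: tuple[int, ...]
    labels_b: tuple[int, ...]
    p_observed: float
    p_expected: float
    kappa: float
    band: Band
    degenerate_flag: bool

    def to_dict(self) -> dict:
        return {
            "labels_model": list(self.labels_a),
            "labels_therapist": list(self.labels_b),
            "p_observed": self.p_observed,
            "p_expected": self.p_expected,
            "kappa": self.kappa,
            "band": self.band.value,
            "degenerate": self.degenerate_flag,
        }


def binarize_engagement(percent: float) -> int:
    """1 (engaged) iff the percentage is >= 50, else 0. The threshold is
    inclusive: exactly 50% counts as engaged."""
    if not math.isfinite(percent) or not 0.0 <= percent <= 100.0:
        raise ValueError(f"percentage out of [0, 100]: {percent!r}")
    return int(percent >= 50.0)


def _as_binary(v: Sequence) -> np.ndarray:
    arr = np.asarray(v)
    out = arr.astype(int)
    if not np.isin(out, (0, 1)).all():
        raise ValueError("labels must be binary (0/1)")
    return out


def cohen_kappa(a: Sequence, b: Sequence) -> AgreementResult:
    """Two-rater Cohen's kappa on binary label vectors of equal length.

    Degenerate conventions: if both raters are constant and identical,
    kappa = 1; if both constant but different, kappa = 0; both flagged.
    """
    va, vb = _as_binary(a), _as_binary(b)
    if len(va) != len(vb):
        raise ValueError(f"length mismatch: {len(va)} vs {len(vb)}")
    if len(va) < 2:
        raise ValueError("need at least 2 paired labels")

    n = len(va)
    p_o = float((va == vb).mean())
    pa1, pb1 = va.mean(), vb.mean()
    p_e = float(pa1 * pb1 + (1 - pa1) * (1 - pb1))

    both_constant = (va == va[0]).all() and (vb == vb[0]).all()
    if both_constant:
        kappa = 1.0 if va[0] == vb[0] else 0.0
        degenerate = True
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
        degenerate = False

    return AgreementResult(
        labels_a=tuple(int(x) for x in va),
        labels_b=tuple(int(x) for x in vb),
        p_observed=p_o, p_expected=p_e, kappa=float(kappa),
        band=interpret_kappa(float(np.clip(kappa, -1.0, 1.0))),
        degenerate_flag=degenerate,
    )


def interpret_kappa(kappa: float) -> Band:
    """Interpretation band of an (unrounded) kappa value."""
    if not math.isfinite(kappa) or not -1.0 <= kappa <= 1.0:
        raise ValueError(f"kappa out of [-1, 1]: {kappa!r}")
    if kappa <= 0.0:
        return Band.NO_AGREEMENT
    if kappa <= 0.20:
        return Band.SLIGHT
    if kappa <= 0.40:
        return Band.FAIR
    if kappa <= 0.60:
        return Band.MODERATE
    if kappa <= 0.80:
        return Band.SUBSTANTIAL
    return Band.ALMOST_PERFECT
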