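"""Circumplex emotion model: valence/arousal to binary engagement.

Engagement is defined as the positive-valence, high-arousal quadrant of
Russell's circumplex model of affect. The mapping is binary and uses
strict inequalities: points on either axis (valence = 0 or arousal = 0)
are conservatively labelled not engaged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum


class EngagementLabel(Enum):
    ENGAGED = "engaged"
    NOT_ENGAGED = "not_engaged"


@dataclass(frozen=True)
class VAState:
    """A point in the valence-arousal plane, both coordinates in [-1, 1]."""

    valence: float
    arousal: float

    def __post_init__(self) -> None:
        for name, val in (("valence", self.valence), ("arousal", self.arousal)):
            if not math.isfinite(val):
                raise ValueError(f"{name} must be finite, got {val!r}")
            if not -1.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [-1, 1], got {val}")


def map_va_to_engagement(va: VAState) -> EngagementLabel:
    """Engaged iff valence > 0 and arousal > 0 (strict quadrant rule).

    The map is invariant to positive rescaling of the coordinates; only
    their signs matter.
    """
    if va.valence > 0.0 and va.arousal > 0.0:
        return EngagementLabel.ENGAGED
    return EngagementLabel.NOT_ENGAGED
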