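"""CIELAB color difference, clinical thresholds, and trial-level pooling.

Tooth color is recorded as CIE L*a*b* coordinates: L* is lightness (0 black to
100 white), a* runs red (+) to green (-), b* yellow (+) to blue (-). Bleaching
shows up as higher L* and lower b*. The effectiveness outcome is ΔE*ab, the
Euclidean distance between the before and after coordinates. Two clinical
thresholds from the shade-matching literature are applied: a change is
perceptible above 1.2 ΔE*ab units and clinically acceptable (i.e. an evident
whitening result) above 2.7.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from .parameters import ConfigError, TrialArm

__all__ = [
    "PERCEPTIBILITY_THRESHOLD",
    "ACCEPTABILITY_THRESHOLD",
    "LabColor",
    "ColorChangeClass",
    "delta_e_ab",
    "classify_color_change",
    "pool_effectiveness",
]

#: ΔE*ab above which a color change is clinically perceptible.
PERCEPTIBILITY_THRESHOLD = 1.2
#: ΔE*ab above which a color change is clinically acceptable as whitening.
ACCEPTABILITY_THRESHOLD = 2.7


@dataclass(frozen=True)
class LabColor:
    """A CIE L*a*b* coordinate triplet."""

    L: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.L, self.a, self.b)):
            raise ConfigError(f"LabColor: coordinates must be finite, got {self}")
        if not 0.0 <= self.L <= 100.0:
            raise ConfigError(f"L: lightness must lie in [0, 100], got {self.L}")


class ColorChangeClass(str, Enum):
    IMPERCEPTIBLE = "imperceptible"
    PERCEPTIBLE_ONLY = "perceptible_only"
    ACCEPTABLE_CHANGE = "acceptable_change"


def delta_e_ab(before: LabColor, after: LabColor) -> float:
    """CIELAB color difference ΔE*ab = sqrt(ΔL² + Δa² + Δb²)."""
    return math.sqrt(
        (after.L - before.L) ** 2 + (after.a - before.a) ** 2 + (after.b - before.b) ** 2
    )


def classify_color_change(delta_e: float) -> ColorChangeClass:
    """Classify a ΔE*ab value against the perceptibility/acceptability thresholds.

    ``<= 1.2`` imperceptible; ``(1.2, 2.7]`` perceptible but not an acceptable
    whitening result; ``> 2.7`` clinically acceptable change.
    """
    if not (math.isfinite(delta_e) and delta_e >= 0):
        raise ConfigError(f"delta_e: must be a non-negative finite number, got {delta_e!r}")
    if delta_e <= PERCEPTIBILITY_THRESHOLD:
        return ColorChangeClass.IMPERCEPTIBLE
    if delta_e <= ACCEPTABILITY_THRESHOLD:
        return ColorChangeClass.PERCEPTIBLE_ONLY
    return ColorChangeClass.ACCEPTABLE_CHANGE


def pool_effectiveness(arms: Sequence[TrialArm]) -> tuple[float, float | None]:
    """Pool per-arm ΔE*ab means into one strategy-level (mean, SD).

    The pooled mean is the sample-size-weighted mean sum(n_i x_i) / sum(n_i).
    When every arm reports an SD the pooled SD combines within-arm and
    between-arm variance,

        s² = [ sum((n_i - 1) s_i²) + sum(n_i (x_i - x̄)²) ] / (sum(n_i) - 1),

    i.e. the sample variance of the concatenated subject-level data implied by
    the arm summaries; with any arm SD missing the pooled SD is ``None``.
    A single arm returns that arm's mean and SD unchanged.
    """
    arms = list(arms)
    if not arms:
        raise ConfigError("arms: need at least one trial arm to pool")
    if len(arms) == 1:
        return arms[0].delta_e_mean, arms[0].delta_e_sd
    total_n = sum(a.n for a in arms)
    mean = sum(a.n * a.delta_e_mean for a in arms) / total_n
    if any(a.delta_e_sd is None for a in arms):
        return mean, None
    if total_n < 2:
        return mean, arms[0].delta_e_sd
    within = sum((a.n - 1) * a.delta_e_sd**2 for a in arms)  # type: ignore[operator]
    between = sum(a.n * (a.delta_e_mean - mean) ** 2 for a in arms)
    return mean, math.sqrt((within + between) / (total_n - 1))
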