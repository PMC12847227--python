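"""Reliable-change and clinical-significance thresholds, five-way outcome
classification of pre/post score pairs, and severity-band lookup."""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .scoring import DescriptiveStats

__all__ = [
    "OutcomeCategory",
    "ChangeThresholds",
    "SeverityBands",
    "DEFAULT_BANDS",
    "standard_error_measurement",
    "rci",
    "cs_cutoff",
    "compute_thresholds",
    "classify_change",
    "severity_band",
]

#: two-sided z multipliers for the supported confidence levels
Z_LEVELS = {80: 1.282, 90: 1.645, 95: 1.960}


class OutcomeCategory(str, Enum):
    RECOVERED = "Recovered"
    RELIABLY_IMPROVED = "Reliably Improved"
    UNCHANGED = "Unchanged"
    RELIABLY_DETERIORATED = "Reliably Deteriorated"
    RELAPSED = "Relapsed"


def standard_error_measurement(sd: float, r_xx: float) -> float:
    """S_E = SD * sqrt(1 - r_xx)."""
    if not 0.0 <= r_xx <= 1.0:
        raise ValueError("reliability must lie in [0, 1]")
    if sd < 0:
        raise ValueError("SD must be non-negative")
    return float(sd * np.sqrt(1.0 - r_xx))


def rci(se: float, level: int = 95) -> float:
    """Minimum reliable change: z_level * sqrt(2) * S_E."""
    if se < 0:
        raise ValueError("standard error must be non-negative")
    if level not in Z_LEVELS:
        raise ValueError(f"unsupported confidence level {level}; use one of {sorted(Z_LEVELS)}")
    return float(Z_LEVELS[level] * np.sqrt(2.0) * se)


def cs_cutoff(clinical: DescriptiveStats, normative: DescriptiveStats) -> float:
    """SD-weighted midpoint of the two group means:
    (sd_norm * M_clin + sd_clin * M_norm) / (sd_clin + sd_norm)."""
    if clinical.sd <= 0 or normative.sd <= 0:
        raise ValueError("both group SDs must be positive")
    c = (normative.sd * clinical.mean + clinical.sd * normative.mean) / (
        clinical.sd + normative.sd
    )
    if clinical.mean != normative.mean:
        lo, hi = sorted((clinical.mean, normative.mean))
        assert lo < c < hi, "cutoff escaped the interval between the group means"
    return float(c)


@dataclass
class ChangeThresholds:
    """Measurement error, reliable-change minima, and the clinical cutoff.

    ``boundary_functional``: whether a score exactly at the cutoff counts as
    being on the functional side (default True for higher-is-better scales).
    """

    se: float
    rci: dict[int, float]
    cs: float
    higher_is_better: bool = True
    boundary_functional: bool = True

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("se must be non-negative")
        levels = sorted(self.rci)
        vals = [self.rci[lv] for lv in levels]
        if self.se > 0 and any(v2 <= v1 for v1, v2 in zip(vals, vals[1:])):
            raise ValueError("RCI values must increase with confidence level")

    def is_functional(self, score: float) -> bool:
        if self.higher_is_better:
            return score >= self.cs if self.boundary_functional else score > self.cs
        return score <= self.cs if self.boundary_functional else score < self.cs

    def to_dict(self) -> dict:
        return {
            "schema": "change-thresholds/1",
            "se": self.se,
            "rci": {int(k): float(v) for k, v in self.rci.items()},
            "cs": self.cs,
            "higher_is_better": self.higher_is_better,
            "boundary_functional": self.boundary_functional,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChangeThresholds":
        return cls(
            se=float(d["se"]),
            rci={int(k): float(v) for k, v in d["rci"].items()},
            cs=float(d["cs"]),
            higher_is_better=bool(d.get("higher_is_better", True)),
            boundary_functional=bool(d.get("boundary_functional", True)),
        )


def compute_thresholds(
    clinical: DescriptiveStats,
    normative: DescriptiveStats,
    r_xx: float,
    higher_is_better: bool = True,
) -> ChangeThresholds:
    """Assemble thresholds from group summaries: S_E from the normative SD,
    RCIs at 80/90/95%, and the SD-weighted cutoff."""
    se = standard_error_measurement(normative.sd, r_xx)
    return ChangeThresholds(
        se=se,
        rci={lv: rci(se, lv) for lv in Z_LEVELS},
        cs=cs_cutoff(clinical, normative),
        higher_is_better=higher_is_better,
    )


def classify_change(
    pre: float, post: float, thresholds: ChangeThresholds, level: int = 95
) -> OutcomeCategory:
    """Five-way outcome of a pre -> post change.

    With a higher-is-better scale and delta = post - pre:

    * delta >= RCI: reliable improvement; *Recovered* when the pre score was
      on the dysfunctional side and the post score on the functional side,
      otherwise *Reliably Improved*.
    * delta <= -RCI: reliable deterioration; *Relapsed* when the score
      crossed from the functional to the dysfunctional side, otherwise
      *Reliably Deteriorated*.
    * |delta| < RCI: *Unchanged*.
    """
    if level not in thresholds.rci:
        raise ValueError(f"no RCI stored for level {level}")
    threshold = thresholds.rci[level]
    delta = post - pre
    if not thresholds.higher_is_better:
        delta = -delta
    pre_fn = thresholds.is_functional(pre)
    post_fn = thresholds.is_functional(post)
    if delta >= threshold and delta != 0:
        if not pre_fn and post_fn:
            return OutcomeCategory.RECOVERED
        return OutcomeCategory.RELIABLY_IMPROVED
    if delta <= -threshold and delta != 0:
        if pre_fn and not post_fn:
            return OutcomeCategory.RELAPSED
        return OutcomeCategory.RELIABLY_DETERIORATED
    return OutcomeCategory.UNCHANGED


@dataclass
class SeverityBands:
    """Ordered cutpoints with one more label than cutpoint.

    For a higher-is-better scale, labels run from worst (lowest scores) to
    best; a score exactly on a cutpoint is assigned to the worse-severity
    side.
    """

    cutpoints: list[float]
    labels: list[str]
    higher_is_better: bool = True

    def __post_init__(self) -> None:
        if any(c2 <= c1 for c1, c2 in zip(self.cutpoints, self.cutpoints[1:])):
            raise ValueError("cutpoints must be strictly increasing")
        if len(self.labels) != len(self.cutpoints) + 1:
            raise ValueError("need exactly one more label than cutpoint")


DEFAULT_BANDS = SeverityBands(
    cutpoints=[40.0, 45.7, 55.0, 60.0],
    labels=["Poor", "Below Average", "Average", "Above Average", "High"],
)


def severity_band(t: float, bands: SeverityBands = DEFAULT_BANDS) -> str:
    """Half-open interval lookup with ties going to the worse-severity side."""
    cuts = bands.cutpoints
    if bands.higher_is_better:
        # worse side is below: intervals (-inf, c1], (c1, c2], ..., (ck, inf)
        idx = int(np.searchsorted(cuts, t, side="left"))
    else:
        # worse side is above: intervals (-inf, c1), [c1, c2), ..., [ck, inf)
        idx = int(np.searchsorted(cuts, t, side="right"))
    return bands.labels[idx]
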