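"""Linear T-scores and rank-based inverse-normal (Rankit-family) T-scores."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RankTransformConfig",
    "linear_t",
    "inverse_normal_rank",
    "rankit_t",
    "rankit_t_table",
]

#: named plotting-position offsets: Rankit (0.5), Blom (0.375), van der Waerden (0)
RANK_OFFSETS = {"rankit": 0.5, "blom": 0.375, "waerden": 0.0}


@dataclass
class RankTransformConfig:
    """Plotting-position offset k for the (r - k)/(n - 2k + 1) position.

    k = 0.5 is the Rankit position (denominator n); 0.375 is Blom; 0 is
    van der Waerden.  Ties always receive average ranks so equal raw scores
    map to equal Z.
    """

    offset: float = 0.5
    tie_rule: str = "average"

    def __post_init__(self) -> None:
        if not 0.0 <= self.offset <= 0.5:
            raise ValueError("offset must lie in [0, 0.5]")
        if self.tie_rule != "average":
            raise ValueError("only average-rank tie handling is supported")


def linear_t(rs, ref_mean: float, ref_sd: float):
    """T = 10 * (rs - ref_mean)/ref_sd + 50."""
    if ref_sd <= 0:
        raise ValueError("reference SD must be positive")
    return 10.0 * (np.asarray(rs, dtype=float) - ref_mean) / ref_sd + 50.0


def inverse_normal_rank(values, config: RankTransformConfig | None = None) -> np.ndarray:
    """Map a sample through average ranks and plotting positions into normal
    quantiles: Z_i = Phi^-1((r_i - k)/(n - 2k + 1)).  Order-preserving."""
    if config is None:
        config = RankTransformConfig()
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    if np.isnan(x).any():
        raise ValueError("missing values not allowed; filter them first")
    r = stats.rankdata(x, method="average")
    k = config.offset
    p = (r - k) / (x.size - 2.0 * k + 1.0)
    assert np.all((p > 0) & (p < 1)), "plotting positions escaped (0,1)"
    return stats.norm.ppf(p)


def rankit_t_table(reference, config: RankTransformConfig | None = None) -> dict[float, float]:
    """Map each distinct raw score observed in the reference to its shared
    rank-normalized T value."""
    ref = np.asarray(reference, dtype=float)
    ref = ref[~np.isnan(ref)]
    z = inverse_normal_rank(ref, config)
    table: dict[float, float] = {}
    for rs in np.unique(ref):
        # average ranks guarantee all members of a tie share one Z
        table[float(rs)] = float(10.0 * z[ref == rs][0] + 50.0)
    return table


def rankit_t(rs, reference, config: RankTransformConfig | None = None) -> float:
    """Rank-normalized T for a raw score observed in the reference sample.

    Returns NaN (the explicit not-observed signal) when ``rs`` does not occur
    in the reference; interpolation for unobserved scores is the crosswalk's
    job, not this transform's.
    """
    table = rankit_t_table(reference, config)
    return table.get(float(rs), float("nan"))
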