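"""Closed-form raw-score conversion formulas (quintic polynomial and
log-Weibull sigmoid) fitted by least squares, and rounded crosswalk tables."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "ConversionFormula",
    "CrosswalkTable",
    "fit_polynomial",
    "fit_weibull_sigmoid",
    "evaluate_formula",
    "build_crosswalk",
    "round_half_away",
]

logger = logging.getLogger(__name__)

WEIBULL_EPS = 1e-4  # additive guard inside ln(rs + eps)


def round_half_away(x, decimals: int = 0):
    """Round half away from zero (not banker's rounding)."""
    x = np.asarray(x, dtype=float)
    factor = 10.0**decimals
    return np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor


@dataclass
class ConversionFormula:
    """A fitted raw-score -> target map.

    ``kind='polynomial'``: coefficients c0..cd, ascending powers.
    ``kind='weibull-sigmoid'``: coefficients (lower, upper, shape, scale) of
    y = L + (U - L) * (1 - exp(-exp(s * (ln(rs + eps) - ln(m))))).
    """

    kind: str
    coefficients: list[float]
    domain: tuple[float, float]
    residual_sd: float | None = None
    r_squared: float | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("polynomial", "weibull-sigmoid"):
            raise ValueError(f"unknown formula kind {self.kind!r}")
        if self.kind == "polynomial" and len(self.coefficients) > 6:
            raise ValueError("polynomial degree must be <= 5")
        if self.kind == "weibull-sigmoid":
            if len(self.coefficients) != 4:
                raise ValueError("weibull-sigmoid needs 4 coefficients (L, U, s, m)")
            if self.coefficients[1] <= self.coefficients[0]:
                raise ValueError("upper asymptote must exceed lower asymptote")
        if self.domain[1] < self.domain[0]:
            raise ValueError("empty domain")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "coefficients": [float(c) for c in self.coefficients],
            "domain": [float(self.domain[0]), float(self.domain[1])],
            "residual_sd": self.residual_sd,
            "r_squared": self.r_squared,
            "converged": self.converged,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConversionFormula":
        return cls(
            kind=d["kind"],
            coefficients=list(d["coefficients"]),
            domain=tuple(d["domain"]),
            residual_sd=d.get("residual_sd"),
            r_squared=d.get("r_squared"),
            converged=d.get("converged", True),
        )


def _weibull_sigmoid(rs, lower, upper, shape, scale):
    rs = np.asarray(rs, dtype=float)
    return lower + (upper - lower) * (
        1.0 - np.exp(-np.exp(shape * (np.log(rs + WEIBULL_EPS) - np.log(scale))))
    )


def fit_polynomial(x, y, degree: int = 5) -> ConversionFormula:
    """Least-squares polynomial over per-respondent (rs, target) pairs."""
    if degree > 5:
        raise ValueError("polynomial degree must be <= 5")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[m], y[m]
    if np.unique(x).size < degree + 2:
        raise ValueError(
            f"need at least {degree + 2} distinct raw-score values for degree {degree}"
        )
    # fit in a scaled window for conditioning, convert back to plain powers
    V = np.vander((x - x.mean()) / max(np.ptp(x), 1.0), degree + 1, increasing=True)
    rank = np.linalg.matrix_rank(V)
    if rank < degree + 1:
        raise ValueError(
            f"rank-deficient design (rank {rank} < {degree + 1}); "
            "raw-score values are too collinear for this degree"
        )
    poly = np.polynomial.Polynomial.fit(x, y, degree)
    coef = poly.convert().coef
    if coef.size < degree + 1:  # trailing exact zeros trimmed by convert()
        coef = np.pad(coef, (0, degree + 1 - coef.size))
    resid = y - np.polynomial.polynomial.polyval(x, coef)
    dof = max(x.size - (degree + 1), 1)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return ConversionFormula(
        kind="polynomial",
        coefficients=[float(c) for c in coef],
        domain=(float(x.min()), float(x.max())),
        residual_sd=float(np.sqrt((resid**2).sum() / dof)),
        r_squared=r2,
    )


def fit_weibull_sigmoid(x, y, starts=None) -> ConversionFormula:
    """Fit the four-parameter log-Weibull sigmoid to (rs, percentile) pairs by
    iterative least squares.

    Documented starts: L = min(y), U = max(y), shape = 5, scale = median(x).
    Non-convergence is flagged (``converged=False``) with best-so-far values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[m], y[m]
    if np.any((y < 0) | (y > 100)):
        raise ValueError("percentile targets must lie in [0, 100]")
    if np.unique(x).size < 5:
        raise ValueError("need at least 5 distinct raw-score values")
    if starts is None:
        starts = (float(y.min()), float(y.max()) + 0.5, 5.0, float(np.median(x)))
    converged = True
    try:
        popt, _ = optimize.curve_fit(
            _weibull_sigmoid, x, y, p0=starts, maxfev=20000,
            bounds=([-np.inf, -np.inf, 1e-6, 1e-6], [np.inf, np.inf, np.inf, np.inf]),
        )
    except RuntimeError:
        converged = False
        res = optimize.least_squares(
            lambda p: _weibull_sigmoid(x, *p) - y, x0=starts, max_nfev=5000
        )
        popt = res.x
        logger.warning("weibull-sigmoid fit did not converge; best-so-far returned")
    resid = y - _weibull_sigmoid(x, *popt)
    dof = max(x.size - 4, 1)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return ConversionFormula(
        kind="weibull-sigmoid",
        coefficients=[float(c) for c in popt],
        domain=(float(x.min()), float(x.max())),
        residual_sd=float(np.sqrt((resid**2).sum() / dof)),
        r_squared=r2,
        converged=converged,
    )


def evaluate_formula(formula: ConversionFormula, rs):
    """Evaluate the stored closed form; warns when extrapolating."""
    rs_arr = np.asarray(rs, dtype=float)
    lo, hi = formula.domain
    if np.any(rs_arr < lo) or np.any(rs_arr > hi):
        warnings.warn(
            f"raw score outside fitted domain [{lo}, {hi}]; extrapolating",
            RuntimeWarning,
        )
    if formula.kind == "polynomial":
        out = np.polynomial.polynomial.polyval(rs_arr, np.asarray(formula.coefficients))
    else:
        out = _weibull_sigmoid(rs_arr, *formula.coefficients)
    return float(out) if np.isscalar(rs) or np.ndim(rs) == 0 else out


@dataclass
class CrosswalkTable:
    """Rounded integer-raw-score lookup: columns rs, t_irt, pr_population,
    pr_clinical."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        req = ["rs", "t_irt", "pr_population", "pr_clinical"]
        if list(self.table.columns) != req:
            raise ValueError(f"crosswalk table must have columns {req}")
        if np.any(np.diff(self.table["t_irt"].to_numpy()) < 0):
            raise ValueError("T column must be non-decreasing")
        for c in ("pr_population", "pr_clinical"):
            col = self.table[c].to_numpy()
            if np.any(np.diff(col) < 0) or col.min() < 0 or col.max() > 100:
                raise ValueError(f"{c} must be non-decreasing within [0, 100]")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CrosswalkTable":
        return cls(pd.read_csv(path))

    def lookup(self, rs: int) -> tuple[float, int, int]:
        row = self.table.loc[self.table["rs"] == rs]
        if row.empty:
            raise KeyError(f"raw score {rs} outside crosswalk range")
        r = row.iloc[0]
        return float(r["t_irt"]), int(r["pr_population"]), int(r["pr_clinical"])


def _isotonize(values: np.ndarray, label: str) -> np.ndarray:
    """Clamp tiny non-monotone dips with a running maximum, logging if any."""
    iso = np.maximum.accumulate(values)
    n_fix = int((iso != values).sum())
    if n_fix:
        logger.info("isotonic adjustment applied to %d %s value(s) "
                    "(max dip %.4g)", n_fix, label, float(np.max(iso - values)))
    return iso


def build_crosswalk(
    t_formula: ConversionFormula,
    pr_population: ConversionFormula | dict[int, float],
    pr_clinical: ConversionFormula | dict[int, float],
    rs_range: tuple[int, int] = (12, 84),
) -> CrosswalkTable:
    """One row per integer raw score: T at 1 decimal, percentile ranks as
    clipped integers.  PR inputs may be fitted formulas or empirical
    {rs: PR} maps (empirical preferred when data exist); empirical maps are
    linearly interpolated at unobserved raw scores.

    Monotonicity is enforced before rounding by a running maximum; any
    adjustment is logged.
    """
    lo, hi = rs_range
    rs = np.arange(lo, hi + 1)

    def _domain(src) -> tuple[float, float]:
        if isinstance(src, dict):
            return (min(src), max(src))
        return src.domain

    for src, name in ((t_formula, "T"), (pr_population, "PR_pop"), (pr_clinical, "PR_clin")):
        dlo, dhi = _domain(src)
        if dlo > lo or dhi < hi:
            raise ValueError(
                f"{name} source domain [{dlo}, {dhi}] does not cover rs range [{lo}, {hi}]"
            )

    def _values(src) -> np.ndarray:
        if isinstance(src, dict):
            keys = np.array(sorted(src))
            vals = np.array([src[k] for k in keys], dtype=float)
            return np.interp(rs, keys, vals)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.asarray(evaluate_formula(src, rs), dtype=float)

    t = _isotonize(_values(t_formula), "T")
    prn = np.clip(_isotonize(_values(pr_population), "PR_pop"), 0.0, 100.0)
    prc = np.clip(_isotonize(_values(pr_clinical), "PR_clin"), 0.0, 100.0)

    df = pd.DataFrame(
        {
            "rs": rs,
            "t_irt": round_half_away(t, 1),
            "pr_population": round_half_away(prn, 0).astype(int),
            "pr_clinical": round_half_away(prc, 0).astype(int),
        }
    )
    return CrosswalkTable(df)
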