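"""End-to-end norming pipeline: raw scores -> linear / rank-normalized /
IRT T-scores -> crosswalk, change thresholds and agreement reports."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import agreement as agr
from . import clinical_change as cc
from . import crosswalk as cw
from . import grm
from . import normalization as nz
from . import scoring
from .data import ItemResponseMatrix

__all__ = ["PipelineConfig", "PipelineResult", "PipelineStageError", "run_pipeline", "write_outputs"]

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Validated knobs for a full pipeline run; echoed into every output."""

    reference_group: str = "population"
    clinical_group: str | None = None  # inferred as the other group when None
    rank_offset: float = 0.5
    n_quadrature: int = 61
    quad_range: tuple[float, float] = (-6.0, 6.0)
    rci_level: int = 95
    rs_range: tuple[int, int] | None = None  # derived from the instrument when None
    pr_source: str = "empirical"  # empirical | formula
    age_bands: list[tuple[int, int]] | None = None
    missing_policy: str = "complete"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pr_source not in ("empirical", "formula"):
            raise ValueError("pr_source must be 'empirical' or 'formula'")
        if not 0.0 <= self.rank_offset <= 0.5:
            raise ValueError("rank_offset must lie in [0, 0.5]")
        if self.rci_level not in cc.Z_LEVELS:
            raise ValueError(f"rci_level must be one of {sorted(cc.Z_LEVELS)}")
        if self.missing_policy not in ("complete", "person_mean"):
            raise ValueError("missing_policy must be 'complete' or 'person_mean'")

    def to_dict(self) -> dict:
        return {
            "schema": "pipeline-config/1",
            "reference_group": self.reference_group,
            "clinical_group": self.clinical_group,
            "rank_offset": self.rank_offset,
            "n_quadrature": self.n_quadrature,
            "quad_range": list(self.quad_range),
            "rci_level": self.rci_level,
            "rs_range": list(self.rs_range) if self.rs_range else None,
            "pr_source": self.pr_source,
            "age_bands": [list(b) for b in self.age_bands] if self.age_bands else None,
            "missing_policy": self.missing_policy,
            "seed": self.seed,
        }

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        d.pop("schema", None)
        if d.get("quad_range"):
            d["quad_range"] = tuple(d["quad_range"])
        if d.get("rs_range"):
            d["rs_range"] = tuple(d["rs_range"])
        if d.get("age_bands"):
            d["age_bands"] = [tuple(b) for b in d["age_bands"]]
        return cls(**d)


@dataclass
class PipelineResult:
    scores: pd.DataFrame
    params: grm.GRMParameters
    formulas: dict[str, cw.ConversionFormula]
    crosswalk: cw.CrosswalkTable
    stratified_crosswalks: dict[str, cw.CrosswalkTable]
    thresholds_raw: cc.ChangeThresholds
    thresholds_t: cc.ChangeThresholds
    agreement: dict[str, agr.AgreementReport]
    descriptives: pd.DataFrame
    reliability: float
    config: PipelineConfig = field(repr=False)


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineStageError:
                raise
            except Exception as e:  # noqa: BLE001 - wrap with stage name
                raise PipelineStageError(name, e) from e

        return wrapper

    return deco


def _empirical_pr_map(rs_grid: np.ndarray, reference_scores: np.ndarray) -> dict[int, float]:
    return {
        int(rs): scoring.percentile_rank(rs, reference_scores) for rs in rs_grid
    }


def run_pipeline(config: PipelineConfig, data: ItemResponseMatrix) -> PipelineResult:
    """Execute every stage in order on one response matrix.

    Deterministic given (data, config); the input matrix is never mutated.
    """
    groups = data.groups
    ref = config.reference_group
    if ref not in groups:
        raise PipelineStageError("validate", ValueError(f"reference group {ref!r} not in data"))
    clin = config.clinical_group
    if clin is None:
        others = [g for g in groups if g != ref]
        clin = others[0] if others else ref
    rs_range = config.rs_range
    if rs_range is None:
        lo = data.n_items * data.min_category
        hi = data.n_items * (data.min_category + data.n_categories - 1)
        rs_range = (lo, hi)

    glabels = np.asarray([str(g) for g in data.group])

    # --- raw scores & descriptives -------------------------------------
    @_stage("scoring")
    def _score():
        rs = scoring.sum_scores(data, policy=config.missing_policy)
        rows = []
        for g in groups:
            d = scoring.descriptives(rs[glabels == g], seed=config.seed)
            rows.append({"group": g, "scale": "raw", "n": d.n, "mean": d.mean,
                         "sd": d.sd, "skew": d.skew, "kurt": d.kurt, "w": d.w})
        return rs, rows

    rs, desc_rows = _score()
    ref_rs = rs[glabels == ref]
    ref_rs_obs = ref_rs[~np.isnan(ref_rs)]
    clin_rs_obs = rs[(glabels == clin) & ~np.isnan(rs)]

    # --- reliability ----------------------------------------------------
    @_stage("reliability")
    def _alpha():
        return scoring.cronbach_alpha(data.for_group(ref))

    r_xx = _alpha()

    # --- classic T-scores ----------------------------------------------
    @_stage("normalization")
    def _normalize():
        ref_mean, ref_sd = float(ref_rs_obs.mean()), float(ref_rs_obs.std(ddof=1))
        z = (rs - ref_mean) / ref_sd
        t_lin = nz.linear_t(rs, ref_mean, ref_sd)
        rk_cfg = nz.RankTransformConfig(offset=config.rank_offset)
        table = nz.rankit_t_table(ref_rs_obs, rk_cfg)
        t_rank = np.array([table.get(float(v), np.nan) for v in rs])
        return z, t_lin, t_rank

    z, t_linear, t_rankit = _normalize()

    # --- IRT ------------------------------------------------------------
    @_stage("grm")
    def _fit():
        params = grm.fit_grm_multigroup(
            data,
            n_quadrature=config.n_quadrature,
            quad_range=config.quad_range,
            reference_group=ref,
        )
        theta = grm.eap_scores(data, params, config.n_quadrature, config.quad_range)
        return params, theta

    params, theta = _fit()
    t_irt = grm.theta_to_t(theta[:, 0])

    # --- percentile ranks ----------------------------------------------
    @_stage("percentiles")
    def _pr():
        pr_n = np.array([scoring.percentile_rank(v, ref_rs_obs) if not np.isnan(v) else np.nan
                         for v in rs])
        pr_c = np.array([scoring.percentile_rank(v, clin_rs_obs) if not np.isnan(v) else np.nan
                         for v in rs])
        return pr_n, pr_c

    pr_pop, pr_clin = _pr()

    scores = pd.DataFrame(
        {
            "group": glabels,
            "rs": rs,
            "z": z,
            "t_linear": t_linear,
            "t_rankit": t_rankit,
            "theta": theta[:, 0],
            "theta_se": theta[:, 1],
            "t_irt": t_irt,
            "pr_population": pr_pop,
            "pr_clinical": pr_clin,
        }
    )
    if data.covariates is not None:
        for c in data.covariates.columns:
            scores[c] = data.covariates[c].to_numpy()

    # T-scale descriptives feed the T-scale change thresholds
    for g in groups:
        d = scoring.descriptives(t_irt[glabels == g], seed=config.seed)
        desc_rows.append({"group": g, "scale": "t_irt", "n": d.n, "mean": d.mean,
                          "sd": d.sd, "skew": d.skew, "kurt": d.kurt, "w": d.w})
    descriptives = pd.DataFrame(desc_rows)

    # --- crosswalk ------------------------------------------------------
    @_stage("crosswalk")
    def _crosswalk(mask=None, label=""):
        sel = ~np.isnan(rs)
        if mask is not None:
            sel &= mask
        ref_sel = sel & (glabels == ref)
        clin_sel = sel & (glabels == clin)
        t_formula = cw.fit_polynomial(rs[ref_sel], t_irt[ref_sel], degree=5)
        # the crosswalk interpolates raw scores absent from the data, so the
        # formulas' declared domain is the instrument's full range
        t_formula.domain = (float(rs_range[0]), float(rs_range[1]))
        rs_grid = np.arange(rs_range[0], rs_range[1] + 1)
        if config.pr_source == "empirical":
            pr_n_src: object = _empirical_pr_map(rs_grid, rs[ref_sel])
            pr_c_src: object = _empirical_pr_map(rs_grid, rs[clin_sel])
        else:
            pr_n_src = cw.fit_weibull_sigmoid(rs[ref_sel], pr_pop[ref_sel])
            pr_c_src = cw.fit_polynomial(rs[clin_sel], pr_clin[clin_sel], degree=5)
            pr_n_src.domain = pr_c_src.domain = (float(rs_range[0]), float(rs_range[1]))
        table = cw.build_crosswalk(t_formula, pr_n_src, pr_c_src, rs_range)
        formulas = {f"t_irt{label}": t_formula}
        if config.pr_source == "formula":
            formulas[f"pr_population{label}"] = pr_n_src
            formulas[f"pr_clinical{label}"] = pr_c_src
        return table, formulas

    xwalk, formulas = _crosswalk()

    stratified: dict[str, cw.CrosswalkTable] = {}
    if config.age_bands:
        if data.covariates is None or "age" not in data.covariates.columns:
            raise PipelineStageError(
                "stratify", ValueError("age stratification requested but no age column")
            )
        ages = data.covariates["age"].to_numpy()
        for lo_a, hi_a in config.age_bands:
            mask = (ages >= lo_a) & (ages <= hi_a)
            label = f"_age{lo_a}-{hi_a}"
            tbl, f = _crosswalk(mask=mask, label=label)
            stratified[f"age{lo_a}-{hi_a}"] = tbl
            formulas.update(f)

    # --- change thresholds ---------------------------------------------
    @_stage("change")
    def _change():
        d_clin_raw = scoring.descriptives(clin_rs_obs, shapiro=False)
        d_ref_raw = scoring.descriptives(ref_rs_obs, shapiro=False)
        d_clin_t = scoring.descriptives(t_irt[glabels == clin], shapiro=False)
        d_ref_t = scoring.descriptives(t_irt[glabels == ref], shapiro=False)
        return (
            cc.compute_thresholds(d_clin_raw, d_ref_raw, r_xx),
            cc.compute_thresholds(d_clin_t, d_ref_t, r_xx),
        )

    thr_raw, thr_t = _change()

    # --- agreement ------------------------------------------------------
    @_stage("agreement")
    def _agree():
        out = {}
        for name, col in (("t_linear", t_linear), ("t_rankit", t_rankit)):
            m = ~np.isnan(col) & ~np.isnan(t_irt)
            out[name] = agr.agreement_report(col[m], t_irt[m])
        return out

    reports = _agree()

    return PipelineResult(
        scores=scores,
        params=params,
        formulas=formulas,
        crosswalk=xwalk,
        stratified_crosswalks=stratified,
        thresholds_raw=thr_raw,
        thresholds_t=thr_t,
        agreement=reports,
        descriptives=descriptives,
        reliability=r_xx,
        config=config,
    )


def write_outputs(result: PipelineResult, out_dir) -> list[Path]:
    """Write every artifact (CSV / YAML) plus a metadata echo of the config.

    All files land atomically only after every table has been serialized, so
    a failure leaves no partial output behind.
    """
    out = Path(out_dir)
    payload: dict[str, str] = {}

    payload["scores.csv"] = result.scores.to_csv(index=False)
    payload["descriptives.csv"] = result.descriptives.to_csv(index=False)
    payload["crosswalk.csv"] = result.crosswalk.table.to_csv(index=False)
    for name, tbl in result.stratified_crosswalks.items():
        payload[f"crosswalk_{name}.csv"] = tbl.table.to_csv(index=False)
    payload["params.yaml"] = yaml.safe_dump(result.params.to_dict(), sort_keys=True)
    payload["formulas.yaml"] = yaml.safe_dump(
        {k: f.to_dict() for k, f in result.formulas.items()}, sort_keys=True
    )
    payload["thresholds.yaml"] = yaml.safe_dump(
        {
            "raw": result.thresholds_raw.to_dict(),
            "t_score": result.thresholds_t.to_dict(),
            "reliability": result.reliability,
        },
        sort_keys=True,
    )
    payload["agreement.csv"] = pd.DataFrame(
        [{"pair": f"{k} vs t_irt", **v.to_dict()} for k, v in result.agreement.items()]
    ).to_csv(index=False)
    payload["metadata.yaml"] = yaml.safe_dump(result.config.to_dict(), sort_keys=True)

    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, text in payload.items():
        p = out / name
        p.write_text(text)
        written.append(p)
    return written
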