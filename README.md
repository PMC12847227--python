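# likertnorm

Norming pipeline for summed Likert-scale instruments, exemplified by the
12-item MANSA (7-point items, total score 12–84). The package converts raw
summed scores into three T-score variants and percentile ranks against two
reference groups, derives closed-form raw-score conversion formulas and a
rounded crosswalk table, and computes reliable-change and
clinical-significance thresholds:

- **synthetic_mansa** — two-group polytomous response simulation from a
  graded response model (GRM), with a calibrated default parameter fixture
  emulating a left-skewed general-population reference and a flatter, more
  dispersed clinical group.
- **scoring** — summed scores, descriptives (skew/kurtosis, Shapiro–Wilk
  pass-through), Cronbach's alpha, McDonald's omega, pooled-SD Cohen's d
  with a Welch t-test, mid-rank percentile ranks.
- **grm** — multigroup GRM fitted by Bock–Aitkin EM on a fixed quadrature
  grid (item parameters shared across groups, reference group anchored at
  N(0,1)), EAP latent scoring, `T = 10·θ + 50`, and a polychoric eigenvalue
  screen.
- **normalization** — linear T-scores and rank-based inverse-normal T-scores
  (Rankit plotting position by default; Blom and van der Waerden offsets
  selectable).
- **crosswalk** — degree-≤5 polynomial and log-Weibull sigmoid conversion
  formulas fitted by least squares; rounded monotone crosswalk tables with
  empirical or formula-based percentile columns.
- **clinical_change** — standard error of measurement, reliable-change
  thresholds at 80/90/95%, SD-weighted clinical-significance cutoff,
  five-way outcome classification, severity bands.
- **agreement** — two-way absolute-agreement ICC (A,1) with CI and F test,
  Bland–Altman bias/limits, percentage error, exceedance counts.
- **pipeline / cli** — end-to-end orchestration and a `likertnorm` command.

## CLI

```sh
likertnorm simulate --n 2000 --seed 1 --out matrix.csv
likertnorm score --matrix matrix.csv --out scores.csv
likertnorm fit-grm --matrix matrix.csv --out params.yaml
likertnorm normalize --matrix matrix.csv --rank-offset 0.5 --out norm.csv
likertnorm crosswalk --matrix matrix.csv --range 12:84 --pr-source empirical --out xwalk.csv
likertnorm run-all --matrix matrix.csv --out-dir results/
```

`run-all` writes `scores.csv`, `descriptives.csv`, `crosswalk.csv`,
`params.yaml`, `formulas.yaml`, `thresholds.yaml`, `agreement.csv` and a
`metadata.yaml` echoing the configuration; runs are deterministic given
(data, config, seed). Exit codes: 0 success, 2 validation error, 3
numerical failure.

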