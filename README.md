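# clonosurv

Dose-response modelling and reanalysis of *in vitro* clonogenic-assay
survival curves, aimed at datasets showing **low-dose
hyper-radiosensitivity (HRS)** and **induced radioresistance (IRR)** —
data typically digitized from published graphs and collected into
tabular databases for meta-analysis and biophysical model validation.

## The models

The surviving fraction *SF* of a cell population after an absorbed dose
*D* (Gy) is normally described by the **linear-quadratic (LQ) model**

```
SF(D) = exp(−α·D − β·D²)
```

with linear (α, Gy⁻¹) and quadratic (β, Gy⁻²) radiosensitivity
coefficients. HRS cell lines deviate from the LQ curve at very low
doses (~0.1 Gy) and recover resistance above ~0.3 Gy; the
**induced-repair (IR) model** captures this by letting the linear
coefficient transition from a low-dose value α_s to a high-dose value
α_r with a dose constant D_c:

```
SF(D) = exp(−α_r·(1 + (α_s/α_r − 1)·exp(−D/D_c))·D − β·D²)
```

At *D = D_c* the α_s→α_r transition is 63 % (1 − 1/e) complete.

## What the package does

* `LQModel` / `IRModel` — statsmodels-style model objects bound to a
  `SurvivalDataset`; `fit()` returns a `FitResult` with estimates,
  standard errors, convergence diagnostics and a `summary()` table.
  Backends: weighted Levenberg–Marquardt-style least squares
  (linear or log SF space) and orthogonal distance regression.
* `IRModel.fit_cascade()` — an eight-step refit protocol for the
  four-parameter IR model, whose optimum is highly sensitive to
  starting values: starts from a high-dose LQ anchor and from the
  published parameters, with weighted/unweighted/log-space/ODR
  variants and one-parameter-fixed fallbacks.
* `params_differ` / `reproduced` — the reproduction criterion between
  published and refitted parameters: two values differ if their gap
  exceeds the **sum of their uncertainties** (SE, CI half-width, or 0
  when unreported).
* `qc` — digitization quality control: dual-reading concordance at a
  0.01 SF tolerance, dose snapping to the 0.05 Gy lattice, and dataset
  validation.
* `dbio` — reader/writer for the database schema (canonical tidy CSV
  and a deposited-style single-sheet XLSX with `'X'`/`'-'` sentinels),
  plus metadata filtering (e.g. cell line "V79", radiation "X-rays").
* `synth` — synthetic-data generator (lattice dose grids,
  multiplicative lognormal noise, SD/SEM whiskers) and
  simulate-then-refit recovery experiments.
* `run_reanalysis` / the `clonosurv` CLI — the end-to-end pipeline:
  read → QC → LQ fit → IR cascade → comparison → report.

## Worked example

```python
import clonosurv as cs
from clonosurv.synth import simulate_database

db = simulate_database(3, seed=7, published_se_frac=0.05)
report = cs.run_reanalysis(db)
print(report.summary())
```

prints

```
datasets analysed:        3
LQ fit converged:         3
IR cascade converged:     3
IR cascade not converged: 0
with published LQ:        0 (reproduced: 0)
with published IR:        3 (reproduced: 3)
```

Each synthetic dataset records its generating IR parameters as its
"published" fit, so a correct refit pipeline must reproduce all of
them: the cascade converges on every curve and each refit lands within
the summed uncertainties of the recorded truth. A single fit looks
like:

```python
cascade = cs.IRModel(db[0]).fit_cascade()
print(cascade.summary())
```

```
IR refit cascade: step_reached=1, reproduced=True, attempts=1
IR model fit (converged)
  algorithm=ls, space=linear, weighting=whiskers, n_points=11
  objective=3.22521, iterations=22
  parameter         value      std err
  alpha_r          0.6245      0.01976
  alpha_s          1.7851       0.7411
  beta            0.30938     0.003789
  d_c             0.22867      0.07643
```

`step_reached=1` means the very first cascade attempt (whisker-weighted
fit started from the high-dose LQ anchor) already reproduced the
recorded parameters; for harder curves the cascade walks through the
published-parameter starts, unweighted, log-space, ODR and
fixed-parameter variants.

From a shell, the same pipeline is:

```sh
clonosurv simulate --n-datasets 3 --seed 7 --out db.csv
clonosurv reanalyze --in db.csv --out report.csv
```

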