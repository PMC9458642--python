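# Methods

## Survival models

The package fits two closed-form survival models to clonogenic-assay
dose-response data. The linear-quadratic (LQ) model,
`SF = exp(−αD − βD²)`, describes most survival curves with a linear
coefficient α (Gy⁻¹) and a quadratic coefficient β (Gy⁻²). The
induced-repair (IR) model extends it for cell lines showing low-dose
hyper-radiosensitivity (HRS) and induced radioresistance (IRR): the
linear coefficient becomes dose-dependent,
`α_eff(D) = α_r + (α_s − α_r)·exp(−D/D_c)`, equal to α_s at zero dose
and approaching α_r at high dose, with the transition 63 % (1 − 1/e)
complete at the critical dose D_c. Both models are normalized to
`SF(0) = 1` for any parameters, because the surviving fraction is by
construction relative to the unirradiated control.

Numerically the IR exponent is evaluated in the division-free form
`α_r + (α_s − α_r)·u`, so no singularity arises during optimization;
the published ratio form makes `α_r = 0` undefined, and the parameter
type rejects it at the API level. Negative doses are rejected rather
than extrapolated. No sign constraints are imposed on α or β: refits
of digitized literature data legitimately produce negative β, and one
of the documented worked examples is exactly such a case. The only
bounds kept during fitting are `D_c ≥ 1e−6 Gy` (so `exp(−D/D_c)` stays
defined) — imposed via a bounded trust-region least-squares solve when
D_c is free.

With `α_s > α_r` the IR curve can be non-monotonic below 1 Gy (a local
minimum in the HRS dip followed by a local maximum); this is a real
feature of the model and is covered by a regression test so that no
"sanitizing" change can remove it.

## Weighting

Digitized survival points carry the plotted error-whisker extremes.
The per-point uncertainty is taken as half the whisker span,
`σᵢ = (whisker_max − whisker_min)/2`, and weighted fits minimize the
standard chi-square `Σ ((model − SFᵢ)/σᵢ)²`. Whether the source
article's whiskers represent SD or SEM is usually unknowable, so spans
are used verbatim and never reinterpreted; since weighted least
squares is invariant to a common rescaling of all σᵢ, the SD/SEM
ambiguity does not move the point estimates, only the absolute scale
of the input uncertainties. A point with a zero-width whisker receives
the median σ of the remaining points; if every span is zero the
dataset carries no usable uncertainty information and weighted fitting
falls back to an unweighted fit (this also makes noise-free synthetic
data, whose whiskers are exactly zero-width, fittable by the weighted
cascade steps).

## LQ fitting protocol

The LQ model ignores HRS, so it is first fitted only to the points
above 1 Gy; when fewer than three points exceed 1 Gy, the three
highest-dose points are used instead. Starting values come from a
weighted linear solve of `−ln SF = αD + βD²` (the model is linear in
(α, β) on the log scale), followed by a nonlinear least-squares polish
in linear SF space. When published LQ parameters exist and the
high-dose fit fails to reproduce them, the model is refitted to the
entire curve including the HRS region; the reproducing fit (or, if
none reproduces, the first converged one) is canonical.

## The IR refit cascade

The IR model's four parameters make convergence highly sensitive to
starting values, so refitting a published dataset walks an ordered
cascade of attempts, stopping at the first converged fit that
reproduces the published parameters:

1. start (α_r, β) at the high-dose LQ fit, α_s = 1 Gy⁻¹, D_c = 1 Gy;
   whisker-weighted least squares in linear SF space;
2. start at the published parameters; weighted;
3. as 1, unweighted; 4. as 2, unweighted;
5. as 1, fitted as ln SF against the negated exponent, unweighted;
6. as 2, in log space, unweighted;
7. variants 1–6 with orthogonal distance regression (labels 7.1–7.6);
8. variants 1–7 with one parameter fixed (labels 8.1–8.12): β fixed to
   0 when the LQ anchor's β was negative, otherwise α_r fixed at the
   LQ α — fitting three parameters instead of four is easier when the
   optimum is shallow.

Reproduction is judged with the same sum-of-uncertainties criterion
used for the final published-vs-refit comparison, restricted to the
parameters the source actually reported. Without published IR
parameters only the published-independent variants (1, 3, 5, their ODR
copies, and their fixed-parameter copies) run, and the first converged
fit is canonical with reproduction not applicable. When attempts
converge but none reproduces, the canonical fit is the first converged
attempt — earliest in protocol order — and `reproduced` is false.

Convergence of a least-squares attempt requires both the optimizer's
own termination test (relative objective/step/gradient change below
1e−10, at most 1000 evaluations) and a finite, non-singular covariance
from the Jacobian at the optimum: a singular normal matrix means a
flat parameter direction, i.e. the data do not determine the
parameters, and such an attempt is reported as not converged rather
than returning meaningless SEs. Standard errors are the square roots
of the covariance diagonal scaled by the reduced chi-square, matching
the default convention of common curve-fitting software. Fixed
parameters are reported with their fixed value and no standard error.
The ODR backend treats doses with unit uncertainty (digitized doses
come without error bars) and the whisker σ on SF when weighting is
requested; its convergence is taken from the solver's own stop reason
plus finiteness of estimates and SEs.

## Comparison criterion

A published and a refitted value of the same parameter are *different*
when `|v_pub − v_fit|` strictly exceeds the sum of their uncertainty
magnitudes. A standard error contributes itself; a confidence interval
contributes its half-width without rescaling (the interval's level —
90 %, 95 % — is typically not recoverable from the source); a missing
uncertainty contributes zero, which is the only reading consistent
with the documented LQ worked example where a bare published α is
flagged against a refit with a larger SE. Equality passes ("larger
than" is strict). The criterion is symmetric and monotone: inflating
any uncertainty can only turn "different" into "not different".

## Quality control

Dual digitization of the same graph with two tools must agree within
0.01 on the SF scale per point, whiskers included; larger differences
are flagged for re-digitization (strict inequality — a difference of
exactly 0.01 passes). Dose values are in practice integer multiples of
0.05 Gy, so a digitized dose within 0.01 Gy of a lattice multiple can
be snapped onto it; doses farther off-lattice are flagged but never
auto-corrected, since some experiments may use other grids. Dataset
validation checks whisker ordering, positive surviving fractions and
lattice membership, reporting all violations rather than failing on
the first.

## Database schema

The canonical interchange format is a flat tidy CSV, one row per
survival point, with dataset metadata (source, figure, cell type,
irradiation, fit type) and the published parameter block — named
columns `alpha_or_alpha_r`, `beta`, `alpha_s`, `d_c`, each with `_se`,
`_ci_low`, `_ci_high` companions — repeated on every row of a dataset.
(A single α-slot is shared between the LQ α and the IR α_r, mirroring
the deposited layout where one column serves both fits.) Two sentinels
are preserved verbatim: `'X'` for values the source did not give and
`'-'` for values not applicable to the fit type. Floats are written in
shortest-repr form, so read–write round-trips are bit-exact. A
deposited-style single-sheet XLSX dialect maps columns A–AA (dose in
B, SF in C, whiskers in D/E, fit type in G, parameters with SEs and
confidence limits in H–X, cell type in Z, irradiation in AA); the
upstream description names five parameter columns for at most four
parameters, so two columns (P, Y) are left unassigned and the dialect
is a best-effort import/export mapping. Free-text metadata is stored
verbatim, never parsed into structured fields.

## Synthetic data

The generator emulates the statistical structure of digitized HRS
survival curves. Dose grids are integer multiples of 0.05 Gy with
dense sampling below 1 Gy (where HRS/IRR live) and sparser anchors up
to the maximum dose; the defaults (6 low doses, 4–5 high doses, 6 Gy
maximum) match typical HRS experimental designs. Per dose, replicate
surviving fractions are drawn as `truth · exp(σZ)` — multiplicative
lognormal noise, chosen because survival data on log axes show roughly
constant relative scatter — with σ = 0.05 and 3 replicates by default,
a realistic precision for clonogenic assays; the stored SF is the
replicate mean and the whiskers span ±SD (or ±SEM, exactly SD/√n).
The default truth sampler draws uniformly from the parameter ranges
observed across refits of literature HRS datasets (α_r ∈ [0.005, 0.8],
α_s ∈ [0.8, 9.3], β ∈ [0, 0.52], D_c ∈ [0.1, 0.35] in their usual
units), deliberately including nearly-degenerate α_r ≈ 0 regimes. A
single integer seed drives everything; per-dataset substreams are
spawned by counter from a `SeedSequence`, so simulated databases and
recovery tables are bit-reproducible.

What the generator does **not** emulate: colony-count (Poisson)
statistics, plating-efficiency estimation, digitization error on the
dose axis, and systematic inter-laboratory differences. Passing
recovery tests therefore demonstrates correctness of the fitting and
comparison machinery under a known, well-behaved error model — not
that literature data satisfy that model.

## Recovery experiments and their scale

The simulate-then-refit study (`recovery_experiment`) uses the
cascade's first attempt (weighted fit from the LQ anchor) per
replicate and reports per-parameter bias, median relative error, RMSE
and ±2 SE coverage against the generating truth. The packaged
acceptance checks use a 10-dose grid, 5 % noise and 200 replicates
with the truth `(α_r = 0.18, α_s = 1.86, β = 0.14, D_c = 0.27)` — a
well-identified HRS regime taken from a documented worked example's
original fit. Identifiability matters here: when the true α_r is
nearly zero (as in one refitted literature case, α_r = 0.005 with a
reported SE fourteen times larger), the high-dose slope carries
essentially no information about α_r and no estimator can recover it
to within a few percent; the generator can produce such regimes, but
they are not meaningful benchmarks for relative parameter error.

## Known limitations

* Convergence counts on real digitized databases are
  optimizer-sensitive; a different solver or tolerance can move
  borderline datasets between "converged" and "not converged".
* The ODR dose uncertainty (set to 1 Gy per point) is a convention,
  not an estimate; refits dominated by the ODR steps inherit it.
* The comparison criterion treats CI half-widths and SEs as
  commensurable uncertainty magnitudes; converting between them would
  require interval levels the sources rarely state.
* The deposited-sheet dialect's parameter-column pairing is inferred,
  not documented upstream; round-trips within this package are exact,
  but reading third-party files of that layout should be followed by
  `validate_dataset` and a spot check.
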