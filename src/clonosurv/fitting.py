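"""Model fitting for clonogenic-survival curves.

Provides statsmodels-style model objects — :class:`LQModel` and
:class:`IRModel` — built from a :class:`~clonosurv.data.SurvivalDataset`,
whose ``fit`` methods return :class:`FitResult` objects carrying point
estimates, standard errors, convergence diagnostics and a ``summary()``
table.  Thin functional wrappers (:func:`fit_lq`, :func:`fit_ir_single`,
:func:`run_ir_cascade`) expose the same operations.

The induced-repair model has four parameters and its optimum is highly
sensitive to starting values, so refitting published datasets uses a
*cascade* of attempts (:meth:`IRModel.fit_cascade`):

1. start ``alpha_r``/``beta`` at the high-dose LQ fit, ``alpha_s`` at
   1/Gy, ``d_c`` at 1 Gy; whisker-weighted least squares;
2. start at the published parameters; whisker-weighted;
3. as 1, unweighted;
4. as 2, unweighted;
5. as 1, fitted in log space (ln SF), unweighted;
6. as 2, in log space, unweighted;
7. variants 1-6 repeated with orthogonal distance regression;
8. variants 1-7 repeated with one parameter fixed: ``beta = 0`` if the
   LQ fit gave a negative ``beta``, otherwise ``alpha_r`` fixed at the
   LQ ``alpha``.

The cascade stops at the first converged attempt judged to *reproduce*
the published parameters under the sum-of-uncertainties criterion
(:mod:`clonosurv.comparison`).  Without published parameters only the
published-independent variants run and the first converged fit is
canonical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import odr as scipy_odr
from scipy.optimize import least_squares

from .comparison import ParamEstimate, reproduced as _judge_reproduced
from .data import SurvivalDataset
from .models import IRParams, LQParams

__all__ = [
    "FitOptions",
    "FitResult",
    "CascadeResult",
    "select_lq_subset",
    "weights_from_whiskers",
    "sigmas_from_whiskers",
    "LQModel",
    "IRModel",
    "fit_lq",
    "fit_ir_single",
    "run_ir_cascade",
    "run_lq_protocol",
]

_LQ_NAMES = ("alpha", "beta")
_IR_NAMES = ("alpha_r", "alpha_s", "beta", "d_c")

# Keep d_c away from 0 so exp(-D/d_c) stays defined during optimization.
_DC_FLOOR = 1e-6


@dataclass(frozen=True)
class FitOptions:
    """Options controlling a single least-squares attempt.

    ``weighting``: ``"whiskers"`` (inverse-variance from whisker
    half-spans) or ``"none"``.  ``space``: ``"linear"`` (residuals on
    SF) or ``"log"`` (residuals on ln SF).  ``algorithm``: ``"ls"``
    (Levenberg-Marquardt-style least squares) or ``"odr"`` (orthogonal
    distance regression, unit dose uncertainty).  ``fixed`` maps
    parameter names to values held constant during the fit.
    """

    weighting: str = "whiskers"
    space: str = "linear"
    algorithm: str = "ls"
    fixed: Mapping[str, float] | None = None
    max_iterations: int = 1000
    tolerance: float = 1e-10

    def __post_init__(self) -> None:
        if self.weighting not in ("whiskers", "none"):
            raise ValueError(f"unknown weighting {self.weighting!r}")
        if self.space not in ("linear", "log"):
            raise ValueError(f"unknown space {self.space!r}")
        if self.algorithm not in ("ls", "odr"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass(frozen=True)
class FitResult:
    """Estimates and diagnostics from one model fit.

    ``estimates`` maps parameter names to
    :class:`~clonosurv.comparison.ParamEstimate`; fixed parameters
    appear with their fixed value and no SE.  ``subset_used`` records
    which point indices of the dataset entered the objective.
    """

    model: str  # "LQ" | "IR"
    estimates: Mapping[str, ParamEstimate]
    converged: bool
    options_used: FitOptions
    subset_used: tuple[int, ...]
    step: str | None = None
    objective: float = math.nan
    n_iterations: int = 0
    message: str = ""

    @property
    def params(self) -> dict[str, float]:
        return {k: v.value for k, v in self.estimates.items()}

    @property
    def bse(self) -> dict[str, float | None]:
        return {k: v.se for k, v in self.estimates.items()}

    def to_lq_params(self) -> LQParams:
        return LQParams(self.params["alpha"], self.params["beta"])

    def to_ir_params(self) -> IRParams:
        p = self.params
        return IRParams(p["alpha_r"], p["alpha_s"], p["beta"], p["d_c"])

    def summary(self) -> str:
        opt = self.options_used
        lines = [
            f"{self.model} model fit "
            f"({'converged' if self.converged else 'NOT converged'})",
            f"  algorithm={opt.algorithm}, space={opt.space}, "
            f"weighting={opt.weighting}, n_points={len(self.subset_used)}",
            f"  objective={self.objective:.6g}, iterations={self.n_iterations}",
            f"  {'parameter':<10} {'value':>12} {'std err':>12}",
        ]
        for name, est in self.estimates.items():
            se = f"{est.se:.4g}" if est.se is not None else "(fixed)"
            lines.append(f"  {name:<10} {est.value:>12.5g} {se:>12}")
        return "\n".join(lines)

    def plot(self, dataset: SurvivalDataset | None = None, ax=None):
        """Plot the fitted curve (and the data, if given) on a log SF axis."""
        import matplotlib.pyplot as plt

        from .models import ir_survival, lq_survival

        if ax is None:
            _, ax = plt.subplots()
        if dataset is not None:
            yerr = None
            if dataset.has_whiskers:
                yerr = [
                    dataset.sf - dataset.whisker_min,
                    dataset.whisker_max - dataset.sf,
                ]
            ax.errorbar(
                dataset.dose, dataset.sf, yerr=yerr, fmt="ks", capsize=3, label="data"
            )
            dmax = dataset.dose.max()
        else:
            dmax = 6.0
        grid = np.linspace(0, dmax, 300)
        if self.model == "LQ":
            curve = lq_survival(grid, self.to_lq_params())
        else:
            curve = ir_survival(grid, self.to_ir_params())
        ax.plot(grid, curve, "r--", label=f"{self.model} fit")
        ax.set_yscale("log")
        ax.set_xlabel("Absorbed dose (Gy)")
        ax.set_ylabel("Surviving fraction")
        ax.legend()
        return ax


@dataclass(frozen=True)
class CascadeResult:
    """Outcome of the multi-step IR refit cascade.

    ``step_reached`` is the major step (1-8) of the canonical fit, or
    ``"none-converged"``.  ``reproduced`` is ``True``/``False`` against
    the published parameters, or ``None`` when the source article
    published no IR fit.  ``attempts`` records every attempt in cascade
    order with its step label (e.g. ``"7.3"`` for the third ODR variant).
    """

    canonical_fit: FitResult | None
    step_reached: int | str
    reproduced: bool | None
    attempts: tuple[tuple[str, FitResult], ...] = field(default_factory=tuple)

    @property
    def converged(self) -> bool:
        return self.canonical_fit is not None

    def summary(self) -> str:
        header = (
            f"IR refit cascade: step_reached={self.step_reached}, "
            f"reproduced={self.reproduced}, attempts={len(self.attempts)}"
        )
        if self.canonical_fit is None:
            return header + "\n  no attempt converged"
        return header + "\n" + self.canonical_fit.summary()


# ---------------------------------------------------------------------------
# subset selection and weights


def select_lq_subset(dataset: SurvivalDataset) -> tuple[int, ...]:
    """Indices of the points used for the high-dose LQ fit.

    All points above 1 Gy; when fewer than three such points exist, the
    three highest-dose points are used instead, even if some lie below
    1 Gy.  The LQ model ignores low-dose hyper-radiosensitivity, so the
    HRS region must be excluded from its primary fit.
    """
    doses = dataset.dose
    high = tuple(int(i) for i in np.flatnonzero(doses > 1.0))
    if len(high) >= 3:
        return high
    order = np.argsort(doses)
    return tuple(int(i) for i in sorted(order[-3:]))


def sigmas_from_whiskers(dataset: SurvivalDataset) -> np.ndarray:
    """Per-point SF standard deviations from whisker half-spans.

    ``sigma_i = (whisker_max - whisker_min) / 2``.  Points with a
    zero-width whisker receive the median sigma of the remaining
    points; a dataset whose spans are all zero (or absent) has no
    usable uncertainty information and is rejected.
    """
    if not dataset.has_whiskers:
        raise ValueError("dataset has points without whiskers")
    spans = dataset.whisker_max - dataset.whisker_min
    sigma = spans / 2.0
    sigma[sigma <= 1e-12] = 0.0  # guard against float fuzz in zero-width whiskers
    nonzero = sigma[sigma > 0]
    if nonzero.size == 0:
        raise ValueError("all whisker spans are zero: no usable weights")
    if nonzero.size < sigma.size:
        sigma = np.where(sigma > 0, sigma, np.median(nonzero))
    return sigma


def weights_from_whiskers(dataset: SurvivalDataset) -> np.ndarray:
    """Inverse-variance weights ``1/sigma_i**2`` from the whiskers."""
    return 1.0 / sigmas_from_whiskers(dataset) ** 2


def _usable_sigmas(dataset: SurvivalDataset) -> np.ndarray | None:
    """Sigmas if the whiskers support weighting, else None."""
    try:
        return sigmas_from_whiskers(dataset)
    except ValueError:
        return None


# ---------------------------------------------------------------------------
# model internals: predicted exponent E(D) with SF = exp(-E)


def _lq_exponent(theta: np.ndarray, d: np.ndarray) -> np.ndarray:
    alpha, beta = theta
    return alpha * d + beta * d * d


def _lq_exponent_jac(theta: np.ndarray, d: np.ndarray) -> np.ndarray:
    return np.column_stack([d, d * d])


def _ir_exponent(theta: np.ndarray, d: np.ndarray) -> np.ndarray:
    alpha_r, alpha_s, beta, d_c = theta
    u = np.exp(-d / d_c)
    return (alpha_r + (alpha_s - alpha_r) * u) * d + beta * d * d


def _ir_exponent_jac(theta: np.ndarray, d: np.ndarray) -> np.ndarray:
    alpha_r, alpha_s, beta, d_c = theta
    u = np.exp(-d / d_c)
    return np.column_stack(
        [
            d * (1.0 - u),
            d * u,
            d * d,
            (alpha_s - alpha_r) * u * d * d / (d_c * d_c),
        ]
    )


_MODEL_FUNCS = {
    "LQ": (_LQ_NAMES, _lq_exponent, _lq_exponent_jac),
    "IR": (_IR_NAMES, _ir_exponent, _ir_exponent_jac),
}


def _pack_free(names, fixed):
    fixed = dict(fixed or {})
    unknown = set(fixed) - set(names)
    if unknown:
        raise ValueError(f"cannot fix unknown parameters {sorted(unknown)}")
    free_idx = [i for i, n in enumerate(names) if n not in fixed]
    if not free_idx:
        raise ValueError("at least one parameter must be free")

    def expand(x_free: np.ndarray) -> np.ndarray:
        full = np.array([fixed.get(n, 0.0) for n in names], dtype=float)
        full[free_idx] = x_free
        return full

    return fixed, free_idx, expand


def _covariance_se(jac_free: np.ndarray, resid: np.ndarray, n_free: int):
    """SEs from the local linearization, scaled by reduced chi-square.

    Returns None when the normal matrix is singular (the fit is then
    treated as unconverged: a flat direction means the parameters are
    not determined by the data).
    """
    n = resid.size
    jtj = jac_free.T @ jac_free
    try:
        cov = np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(cov)):
        return None
    dof = max(n - n_free, 1)
    s2 = float(resid @ resid) / dof if n > n_free else 0.0
    var = np.diag(cov) * s2
    if np.any(var < 0):
        return None
    return np.sqrt(var)


def _fit_least_squares(model, dataset, subset, init_vec, options):
    names, exponent, exponent_jac = _MODEL_FUNCS[model]
    sub = dataset.subset(subset)
    d, y = sub.dose, sub.sf

    sigma = None
    if options.weighting == "whiskers":
        sigma = sigmas_from_whiskers(sub)

    if options.space == "log":
        if np.any(y <= 0):
            raise ValueError("log-space fit requires strictly positive SF")
        target = np.log(y)
        # delta method: sd of ln SF ~ sd(SF)/SF
        w = 1.0 / (sigma / y) if sigma is not None else np.ones_like(y)

        def resid_full(theta):
            return (-exponent(theta, d) - target) * w

        def jac_full(theta):
            return -exponent_jac(theta, d) * w[:, None]

    else:
        w = 1.0 / sigma if sigma is not None else np.ones_like(y)

        def resid_full(theta):
            return (np.exp(-exponent(theta, d)) - y) * w

        def jac_full(theta):
            sf = np.exp(-exponent(theta, d))
            return -(sf * w)[:, None] * exponent_jac(theta, d)

    fixed, free_idx, expand = _pack_free(names, options.fixed)
    if len(subset) <= len(free_idx):
        raise ValueError(
            f"{len(subset)} points cannot determine {len(free_idx)} free parameters"
        )

    lower = np.full(len(free_idx), -np.inf)
    upper = np.full(len(free_idx), np.inf)
    for j, i in enumerate(free_idx):
        if names[i] == "d_c":
            lower[j] = _DC_FLOOR

    x0 = np.asarray(init_vec, dtype=float)[free_idx]
    x0 = np.clip(x0, lower, upper)
    bounded = np.any(np.isfinite(lower)) or np.any(np.isfinite(upper))
    method = "trf" if bounded else "lm"

    try:
        res = least_squares(
            lambda x: resid_full(expand(x)),
            x0,
            jac=lambda x: jac_full(expand(x))[:, free_idx],
            bounds=(lower, upper) if bounded else (-np.inf, np.inf),
            method=method,
            xtol=options.tolerance,
            ftol=options.tolerance,
            gtol=options.tolerance,
            max_nfev=options.max_iterations,
        )
    except (ValueError, FloatingPointError) as exc:
        return _failed_result(model, names, options, subset, str(exc))

    theta = expand(res.x)
    se_free = None
    if res.success and np.all(np.isfinite(theta)):
        se_free = _covariance_se(res.jac, res.fun, len(free_idx))
    converged = res.success and se_free is not None

    estimates = {}
    for i, name in enumerate(names):
        if name in fixed:
            estimates[name] = ParamEstimate.bare(fixed[name])
        elif converged:
            estimates[name] = ParamEstimate.from_se(
                float(theta[i]), float(se_free[free_idx.index(i)])
            )
        else:
            estimates[name] = ParamEstimate.bare(float(theta[i]))
    return FitResult(
        model=model,
        estimates=estimates,
        converged=converged,
        options_used=options,
        subset_used=tuple(subset),
        objective=float(res.cost),
        n_iterations=int(res.nfev),
        message=res.message,
    )


def _fit_odr(model, dataset, subset, init_vec, options):
    """Orthogonal-distance fit via scipy.odr.

    Doses carry unit uncertainty (no per-point dose errors are
    available for digitized data); SF uncertainties come from the
    whiskers when weighting is requested.
    """
    names, exponent, exponent_jac = _MODEL_FUNCS[model]
    sub = dataset.subset(subset)
    d, y = sub.dose, sub.sf

    sigma = None
    if options.weighting == "whiskers":
        sigma = sigmas_from_whiskers(sub)

    if options.space == "log":
        if np.any(y <= 0):
            raise ValueError("log-space fit requires strictly positive SF")
        obs = np.log(y)
        sy = sigma / y if sigma is not None else np.ones_like(y)

        def fcn(theta, x):
            return -exponent(np.asarray(theta), np.asarray(x))

    else:
        obs = y
        sy = sigma if sigma is not None else np.ones_like(y)

        def fcn(theta, x):
            return np.exp(-exponent(np.asarray(theta), np.asarray(x)))

    fixed, free_idx, expand = _pack_free(names, options.fixed)
    if len(subset) <= len(free_idx):
        raise ValueError(
            f"{len(subset)} points cannot determine {len(free_idx)} free parameters"
        )

    beta0 = np.asarray(init_vec, dtype=float)
    for name, value in fixed.items():
        beta0[names.index(name)] = value
    if "d_c" in names:
        i_dc = names.index("d_c")
        beta0[i_dc] = max(beta0[i_dc], _DC_FLOOR)
    ifixb = [0 if n in fixed else 1 for n in names]

    odr_data = scipy_odr.RealData(d, obs, sx=np.ones_like(d), sy=sy)
    odr_model = scipy_odr.Model(fcn)
    runner = scipy_odr.ODR(
        odr_data,
        odr_model,
        beta0=beta0,
        ifixb=ifixb,
        maxit=options.max_iterations,
    )
    try:
        out = runner.run()
    except Exception as exc:  # scipy.odr raises bare exceptions on failure
        return _failed_result(model, names, options, subset, str(exc))

    theta = np.asarray(out.beta, dtype=float)
    converged = (
        out.info in (1, 2, 3)
        and np.all(np.isfinite(theta))
        and np.all(np.isfinite(out.sd_beta))
        and ("d_c" not in names or theta[names.index("d_c")] > 0)
    )

    estimates = {}
    for i, name in enumerate(names):
        if name in fixed:
            estimates[name] = ParamEstimate.bare(fixed[name])
        elif converged:
            estimates[name] = ParamEstimate.from_se(
                float(theta[i]), float(out.sd_beta[i])
            )
        else:
            estimates[name] = ParamEstimate.bare(float(theta[i]))
    return FitResult(
        model=model,
        estimates=estimates,
        converged=converged,
        options_used=options,
        subset_used=tuple(subset),
        objective=float(out.sum_square),
        n_iterations=int(getattr(out, "iwork", [0])[0] or 0),
        message="; ".join(out.stopreason),
    )


def _failed_result(model, names, options, subset, message):
    estimates = {n: ParamEstimate.bare(math.nan) for n in names}
    return FitResult(
        model=model,
        estimates=estimates,
        converged=False,
        options_used=options,
        subset_used=tuple(subset),
        message=message,
    )


def _fit(model, dataset, subset, init_vec, options):
    if options.algorithm == "odr":
        return _fit_odr(model, dataset, subset, init_vec, options)
    return _fit_least_squares(model, dataset, subset, init_vec, options)


# ---------------------------------------------------------------------------
# model classes


class LQModel:
    """Linear-quadratic survival model bound to one dataset.

    By default :meth:`fit` uses the high-dose subset chosen by
    :func:`select_lq_subset`, since the LQ model does not describe the
    hyper-radiosensitive region; pass ``subset="all"`` to fit the
    entire curve (the documented fallback when the subset fit fails to
    reproduce published parameters).
    """

    param_names = _LQ_NAMES

    def __init__(self, dataset: SurvivalDataset):
        self.dataset = dataset

    def _initial_values(self, subset, sigma) -> np.ndarray:
        """Weighted linear solve of -ln SF = alpha*D + beta*D^2."""
        sub = self.dataset.subset(subset)
        d, y = sub.dose, sub.sf
        if np.any(y <= 0):
            return np.array([0.3, 0.03])
        target = -np.log(y)
        design = np.column_stack([d, d * d])
        if sigma is not None:
            w = 1.0 / sigma
            design = design * w[:, None]
            target = target * w
        try:
            theta, *_ = np.linalg.lstsq(design, target, rcond=None)
        except np.linalg.LinAlgError:
            return np.array([0.3, 0.03])
        if not np.all(np.isfinite(theta)):
            return np.array([0.3, 0.03])
        return theta

    def fit(
        self,
        options: FitOptions | None = None,
        subset: str | Sequence[int] = "high-dose",
    ) -> FitResult:
        if subset == "high-dose":
            idx = select_lq_subset(self.dataset)
        elif subset == "all":
            idx = tuple(range(len(self.dataset)))
        else:
            idx = tuple(int(i) for i in subset)
        if options is None:
            usable = _usable_sigmas(self.dataset.subset(idx)) is not None
            options = FitOptions(weighting="whiskers" if usable else "none")
        sigma = None
        if options.weighting == "whiskers":
            sigma = sigmas_from_whiskers(self.dataset.subset(idx))
        x0 = self._initial_values(idx, sigma)
        return _fit("LQ", self.dataset, idx, x0, options)


class IRModel:
    """Induced-repair survival model bound to one dataset."""

    param_names = _IR_NAMES

    def __init__(self, dataset: SurvivalDataset):
        self.dataset = dataset

    def fit(self, start: IRParams, options: FitOptions | None = None) -> FitResult:
        """One fit attempt from explicit starting values."""
        if options is None:
            options = FitOptions()
        init = np.array([start.alpha_r, start.alpha_s, start.beta, start.d_c])
        idx = tuple(range(len(self.dataset)))
        return _fit("IR", self.dataset, idx, init, options)

    # -- cascade ------------------------------------------------------

    def _lq_anchor(self) -> FitResult:
        """High-dose LQ fit supplying cascade starting values."""
        lq = LQModel(self.dataset).fit()
        if not lq.converged:
            lq = LQModel(self.dataset).fit(FitOptions(weighting="none"))
        return lq

    def cascade_plan(
        self, published: Mapping[str, ParamEstimate] | None
    ) -> list[tuple[str, IRParams, FitOptions]]:
        """The ordered list of (step label, start values, options)."""
        lq = self._lq_anchor()
        lq_alpha = lq.params.get("alpha", 0.3)
        lq_beta = lq.params.get("beta", 0.03)
        if not np.isfinite(lq_alpha):
            lq_alpha = 0.3
        if not np.isfinite(lq_beta):
            lq_beta = 0.03

        def mk_ir(alpha_r, alpha_s, beta, d_c):
            if alpha_r == 0:
                alpha_r = 1e-9
            return IRParams(alpha_r, alpha_s, beta, max(d_c, _DC_FLOOR))

        init1 = mk_ir(lq_alpha, 1.0, lq_beta, 1.0)
        init2 = None
        if published:
            vals = {k: published[k].value for k in published}
            init2 = mk_ir(
                vals.get("alpha_r", init1.alpha_r),
                vals.get("alpha_s", init1.alpha_s),
                vals.get("beta", init1.beta),
                vals.get("d_c", init1.d_c),
            )

        weighted = _usable_sigmas(self.dataset) is not None
        w = "whiskers" if weighted else "none"

        base = [
            ("1", init1, FitOptions(weighting=w)),
            ("2", init2, FitOptions(weighting=w)),
            ("3", init1, FitOptions(weighting="none")),
            ("4", init2, FitOptions(weighting="none")),
            ("5", init1, FitOptions(weighting="none", space="log")),
            ("6", init2, FitOptions(weighting="none", space="log")),
        ]
        base = [(label, init, opt) for label, init, opt in base if init is not None]

        plan = list(base)
        for i, (label, init, opt) in enumerate(base, start=1):
            plan.append((f"7.{i}", init, replace(opt, algorithm="odr")))

        if lq_beta < 0:
            fixed = {"beta": 0.0}
        else:
            fixed = {"alpha_r": lq_alpha}
        for i, (label, init, opt) in enumerate(list(plan), start=1):
            if "beta" in fixed:
                init = replace(init, beta=0.0)
            plan.append((f"8.{i}", init, replace(opt, fixed=fixed)))
        return plan

    def fit_cascade(
        self, published: Mapping[str, ParamEstimate] | None = None
    ) -> CascadeResult:
        """Run the full refit cascade against the published parameters.

        When ``published`` is omitted, the dataset's own
        ``published_ir`` mapping is used if present.
        """
        if published is None:
            published = self.dataset.published_ir
        plan = self.cascade_plan(published)

        attempts: list[tuple[str, FitResult]] = []
        first_converged: tuple[str, FitResult] | None = None
        for label, init, options in plan:
            try:
                fit = self.fit(init, options)
            except ValueError as exc:
                fit = _failed_result(
                    "IR", _IR_NAMES, options, range(len(self.dataset)), str(exc)
                )
            fit = replace(fit, step=label)
            attempts.append((label, fit))
            if not fit.converged:
                continue
            if first_converged is None:
                first_converged = (label, fit)
            if not published:
                return CascadeResult(
                    canonical_fit=fit,
                    step_reached=_major_step(label),
                    reproduced=None,
                    attempts=tuple(attempts),
                )
            if _judge_reproduced(fit, published):
                return CascadeResult(
                    canonical_fit=fit,
                    step_reached=_major_step(label),
                    reproduced=True,
                    attempts=tuple(attempts),
                )
        if first_converged is None:
            return CascadeResult(
                canonical_fit=None,
                step_reached="none-converged",
                reproduced=False if published else None,
                attempts=tuple(attempts),
            )
        label, fit = first_converged
        return CascadeResult(
            canonical_fit=fit,
            step_reached=_major_step(label),
            reproduced=False,
            attempts=tuple(attempts),
        )


def _major_step(label: str) -> int:
    return int(label.split(".")[0])


# ---------------------------------------------------------------------------
# functional wrappers


def fit_lq(
    dataset: SurvivalDataset,
    options: FitOptions | None = None,
    subset: str | Sequence[int] = "high-dose",
) -> FitResult:
    """Fit the LQ model (high-dose subset by default)."""
    return LQModel(dataset).fit(options=options, subset=subset)


def fit_ir_single(
    dataset: SurvivalDataset, init: IRParams, options: FitOptions | None = None
) -> FitResult:
    """Fit the IR model once from explicit starting values."""
    return IRModel(dataset).fit(init, options)


def run_ir_cascade(
    dataset: SurvivalDataset,
    published: Mapping[str, ParamEstimate] | None = None,
) -> CascadeResult:
    """Run the eight-step IR refit cascade on one dataset."""
    return IRModel(dataset).fit_cascade(published)


def run_lq_protocol(
    dataset: SurvivalDataset,
    published: Mapping[str, ParamEstimate] | None = None,
) -> tuple[FitResult, bool | None]:
    """LQ refit protocol: high-dose subset first, whole curve as fallback.

    Returns the canonical LQ fit and a reproduced flag (None when the
    source published no LQ parameters).  The whole-curve fallback runs
    only when published parameters exist and the subset fit does not
    reproduce them.
    """
    if published is None:
        published = dataset.published_lq
    fit = fit_lq(dataset)
    if not published:
        if not fit.converged:
            fit = fit_lq(dataset, subset="all")
        return fit, None
    if fit.converged and _judge_reproduced(fit, published):
        return fit, True
    full = fit_lq(dataset, subset="all")
    if full.converged and _judge_reproduced(full, published):
        return full, True
    canonical = fit if fit.converged else full
    return canonical, False
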