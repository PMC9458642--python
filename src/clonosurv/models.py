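"""Closed-form cell-survival models for clonogenic assays.

Two dose-response models are provided:

* the linear-quadratic (LQ) model,

  .. math:: SF(D) = e^{-\\alpha D - \\beta D^2},

  the standard description of clonogenic survival, with linear
  radiosensitivity ``alpha`` (1/Gy) and quadratic radiosensitivity
  ``beta`` (1/Gy^2);

* the induced-repair (IR) model, a four-parameter extension describing
  low-dose hyper-radiosensitivity (HRS) and induced radioresistance
  (IRR), in which the linear coefficient transitions from ``alpha_s``
  at very low doses to ``alpha_r`` at high doses with a dose constant
  ``d_c``:

  .. math::

     SF(D) = \\exp\\left[-\\alpha_r\\left(1 + \\left(
        \\frac{\\alpha_s}{\\alpha_r} - 1\\right) e^{-D/D_c}\\right) D
        - \\beta D^2\\right].

Both models are normalized to the unirradiated control: ``SF(0) = 1``
for any parameters.  ``d_c`` is the "critical dose" at which the
``alpha_s -> alpha_r`` transition is 63 % (``1 - 1/e``) complete.

All functions accept scalar doses or numpy arrays and broadcast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LQParams",
    "IRParams",
    "lq_survival",
    "ir_survival",
    "transition_completion",
    "ir_effective_alpha",
]


def _require_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class LQParams:
    """Linear-quadratic model parameters.

    Parameters
    ----------
    alpha : float
        Linear coefficient (1/Gy).
    beta : float
        Quadratic coefficient (1/Gy^2).

    No sign constraint is enforced: a refit of digitized literature
    data may legitimately produce a negative ``beta``.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        _require_finite("alpha", self.alpha)
        _require_finite("beta", self.beta)

    def as_dict(self) -> dict[str, float]:
        return {"alpha": self.alpha, "beta": self.beta}


@dataclass(frozen=True)
class IRParams:
    """Induced-repair model parameters.

    Parameters
    ----------
    alpha_r : float
        High-dose linear coefficient (1/Gy).  Must be nonzero, since
        the model is written in terms of the ratio ``alpha_s/alpha_r``.
    alpha_s : float
        Low-dose linear coefficient (1/Gy); ``alpha_s > alpha_r``
        produces hyper-radiosensitivity below ~``d_c``.
    beta : float
        Quadratic coefficient (1/Gy^2), shared with the LQ model.
    d_c : float
        Critical/transition dose (Gy), strictly positive.
    """

    alpha_r: float
    alpha_s: float
    beta: float
    d_c: float

    def __post_init__(self) -> None:
        for name in ("alpha_r", "alpha_s", "beta", "d_c"):
            _require_finite(name, getattr(self, name))
        if self.alpha_r == 0.0:
            raise ValueError("alpha_r must be nonzero (alpha_s/alpha_r ratio undefined)")
        if self.d_c <= 0.0:
            raise ValueError(f"d_c must be positive, got {self.d_c!r}")

    def as_dict(self) -> dict[str, float]:
        return {
            "alpha_r": self.alpha_r,
            "alpha_s": self.alpha_s,
            "beta": self.beta,
            "d_c": self.d_c,
        }


def _check_dose(dose):
    d = np.asarray(dose, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("dose must be finite")
    if np.any(d < 0):
        raise ValueError("dose must be nonnegative (Gy)")
    return d


def lq_survival(dose, params: LQParams):
    """Surviving fraction under the linear-quadratic model.

    ``SF = exp(-alpha*D - beta*D**2)``; equals 1 at ``D = 0`` for any
    parameters.  ``dose`` may be a scalar or array (Gy, nonnegative).
    """
    d = _check_dose(dose)
    sf = np.exp(-params.alpha * d - params.beta * d * d)
    return sf if sf.ndim else float(sf)


def ir_effective_alpha(dose, params: IRParams):
    """Dose-dependent linear coefficient implied by the IR model.

    ``alpha_eff(D) = alpha_r * (1 + (alpha_s/alpha_r - 1) * exp(-D/d_c))``,
    which equals ``alpha_s`` at zero dose and tends to ``alpha_r`` at
    high dose.  Evaluated in the algebraically equivalent form
    ``alpha_r + (alpha_s - alpha_r) * exp(-D/d_c)``.
    """
    d = _check_dose(dose)
    a = params.alpha_r + (params.alpha_s - params.alpha_r) * np.exp(-d / params.d_c)
    return a if a.ndim else float(a)


def ir_survival(dose, params: IRParams):
    """Surviving fraction under the induced-repair model.

    Equals 1 at ``D = 0`` and reduces exactly to :func:`lq_survival`
    when ``alpha_s == alpha_r``.
    """
    d = _check_dose(dose)
    a_eff = params.alpha_r + (params.alpha_s - params.alpha_r) * np.exp(-d / params.d_c)
    sf = np.exp(-a_eff * d - params.beta * d * d)
    return sf if sf.ndim else float(sf)


def transition_completion(dose, d_c: float):
    """Fractional completion of the ``alpha_s -> alpha_r`` transition.

    Returns ``1 - exp(-D/d_c)``, in ``[0, 1)``.  At ``D = d_c`` the
    transition is ``1 - 1/e`` (about 63 %) complete, which is the
    defining interpretation of the critical dose.
    """
    if not math.isfinite(d_c) or d_c <= 0:
        raise ValueError(f"d_c must be positive and finite, got {d_c!r}")
    d = _check_dose(dose)
    f = -np.expm1(-d / d_c)
    return f if f.ndim else float(f)
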