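"""Reproduction criterion between published and refitted parameters.

Literature fits come with heterogeneous uncertainty reporting: some
articles give standard errors, some give confidence intervals, some
give none at all.  A refit is judged *different* from the published fit
if, for any shared parameter, the absolute difference between the two
values exceeds the sum of their uncertainties; otherwise the refit is
said to *reproduce* the published one.

Uncertainty magnitudes are taken at face value: a standard error
contributes ``se``, a confidence interval contributes its half-width
(no rescaling to an SE, since the interval's level is typically
unrecorded), and a missing uncertainty contributes zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "ParamEstimate",
    "ComparisonResult",
    "uncertainty_magnitude",
    "params_differ",
    "reproduced",
]


@dataclass(frozen=True)
class ParamEstimate:
    """A parameter value with its (possibly absent) uncertainty.

    ``uncertainty_kind`` is one of ``"SE"`` (standard error in ``se``),
    ``"CI"`` (interval in ``ci_low``/``ci_high``) or ``"missing"``
    (value published without any uncertainty).
    """

    value: float
    uncertainty_kind: str = "missing"
    se: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self) -> None:
        if self.uncertainty_kind not in ("SE", "CI", "missing"):
            raise ValueError(f"unknown uncertainty kind {self.uncertainty_kind!r}")
        if self.uncertainty_kind == "SE":
            if self.se is None or self.se < 0:
                raise ValueError("SE estimate requires se >= 0")
        if self.uncertainty_kind == "CI":
            if self.ci_low is None or self.ci_high is None:
                raise ValueError("CI estimate requires ci_low and ci_high")
            if not (self.ci_low <= self.value <= self.ci_high):
                raise ValueError(
                    f"CI must bracket the value: {self.ci_low} <= {self.value} <= {self.ci_high}"
                )

    @classmethod
    def from_se(cls, value: float, se: float) -> "ParamEstimate":
        return cls(value=value, uncertainty_kind="SE", se=se)

    @classmethod
    def from_ci(cls, value: float, ci_low: float, ci_high: float) -> "ParamEstimate":
        return cls(value=value, uncertainty_kind="CI", ci_low=ci_low, ci_high=ci_high)

    @classmethod
    def bare(cls, value: float) -> "ParamEstimate":
        """A value published without uncertainty."""
        return cls(value=value, uncertainty_kind="missing")


@dataclass(frozen=True)
class ComparisonResult:
    """Per-parameter difference flags and their disjunction."""

    flags: Mapping[str, bool] = field(default_factory=dict)

    @property
    def overall(self) -> bool:
        """True if any parameter is flagged different."""
        return any(self.flags.values())

    @property
    def different(self) -> tuple[str, ...]:
        return tuple(k for k, v in self.flags.items() if v)


def uncertainty_magnitude(estimate: ParamEstimate) -> float:
    """The scalar uncertainty entering the sum-of-uncertainties rule.

    SE -> ``se``; CI -> half-width; missing -> 0.
    """
    if estimate.uncertainty_kind == "SE":
        return float(estimate.se)
    if estimate.uncertainty_kind == "CI":
        return (estimate.ci_high - estimate.ci_low) / 2.0
    return 0.0


def params_differ(
    published: Mapping[str, ParamEstimate],
    refit: Mapping[str, ParamEstimate],
) -> ComparisonResult:
    """Apply the sum-of-uncertainties criterion parameter by parameter.

    A parameter is *different* iff ``|v_pub - v_fit|`` is strictly
    larger than ``u_pub + u_fit``; equality passes.  Both mappings must
    cover the same parameter names.
    """
    if set(published) != set(refit):
        raise ValueError(
            f"parameter sets differ: {sorted(published)} vs {sorted(refit)}"
        )
    flags = {}
    for name in published:
        p, f = published[name], refit[name]
        margin = uncertainty_magnitude(p) + uncertainty_magnitude(f)
        flags[name] = abs(p.value - f.value) > margin
    return ComparisonResult(flags=flags)


def reproduced(cascade_fit, published: Mapping[str, ParamEstimate]) -> bool:
    """Whether a converged refit reproduces the published parameters.

    ``cascade_fit`` is a fit result exposing ``converged`` and
    ``estimates`` (a mapping of parameter name to :class:`ParamEstimate`).
    Only the parameter names present in ``published`` are compared, so
    fixed parameters without SEs and parameters the source article did
    not report are handled uniformly.
    """
    if not cascade_fit.converged:
        raise ValueError("cannot judge reproduction of an unconverged fit")
    fit_estimates = {k: v for k, v in cascade_fit.estimates.items() if k in published}
    return not params_differ(published, fit_estimates).overall
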