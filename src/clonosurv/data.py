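"""In-memory containers for digitized clonogenic-survival datasets.

A dataset is an ordered series of (dose, surviving fraction) points,
each optionally carrying the minimum and maximum of the plotted error
whisker, plus provenance metadata (source article, figure, cell line,
irradiation) and the LQ/IR parameters published by the source article
when available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

from .comparison import ParamEstimate

__all__ = ["SurvivalPoint", "DatasetMeta", "SurvivalDataset"]


@dataclass(frozen=True)
class SurvivalPoint:
    """One digitized observation: dose (Gy), surviving fraction, and
    the whisker extremes of the SF uncertainty (may be equal to ``sf``
    when no whisker was plotted).

    Dose and SF must be finite and the dose nonnegative.  Whisker
    ordering (``whisker_min <= sf <= whisker_max``) and ``sf > 0`` are
    *quality-control* conditions, checked by :func:`clonosurv.qc.validate_dataset`
    rather than at construction, so that raw digitization errors can be
    represented and reported.
    """

    dose: float
    sf: float
    whisker_min: float | None = None
    whisker_max: float | None = None

    def __post_init__(self) -> None:
        for name in ("dose", "sf"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.dose < 0:
            raise ValueError(f"dose must be nonnegative, got {self.dose!r}")
        if (self.whisker_min is None) != (self.whisker_max is None):
            raise ValueError("whisker_min and whisker_max must be given together")

    @property
    def has_whisker(self) -> bool:
        return self.whisker_min is not None

    @property
    def whisker_span(self) -> float | None:
        if self.whisker_min is None:
            return None
        return self.whisker_max - self.whisker_min


@dataclass(frozen=True)
class DatasetMeta:
    """Provenance and experimental metadata, stored as free text."""

    source: str = ""
    figure: str = ""
    cell_type: str = ""
    irradiation: str = ""

    @property
    def dataset_id(self) -> str:
        return f"{self.source}/{self.figure}" if self.figure else self.source


@dataclass(frozen=True)
class SurvivalDataset:
    """An ordered survival curve with metadata and published fits.

    Points are sorted by dose at construction; at least three points
    are required and dose values must be distinct.  ``published_lq``
    and ``published_ir`` map parameter names (``alpha``/``beta`` and
    ``alpha_r``/``alpha_s``/``beta``/``d_c``) to
    :class:`~clonosurv.comparison.ParamEstimate` when the source
    article reported a fit.
    """

    points: tuple[SurvivalPoint, ...]
    meta: DatasetMeta = field(default_factory=DatasetMeta)
    published_lq: Mapping[str, ParamEstimate] | None = None
    published_ir: Mapping[str, ParamEstimate] | None = None
    fit_type: str = "none"  # {LQ, IR, both, none}: which fit the source published

    def __post_init__(self) -> None:
        pts = tuple(sorted(self.points, key=lambda p: p.dose))
        if len(pts) < 3:
            raise ValueError(f"a dataset needs >= 3 points, got {len(pts)}")
        doses = [p.dose for p in pts]
        if len(set(doses)) != len(doses):
            raise ValueError("duplicate dose values in dataset")
        object.__setattr__(self, "points", pts)

    @classmethod
    def from_arrays(
        cls,
        dose: Iterable[float],
        sf: Iterable[float],
        whisker_min: Iterable[float] | None = None,
        whisker_max: Iterable[float] | None = None,
        **kwargs,
    ) -> "SurvivalDataset":
        dose = list(dose)
        sf = list(sf)
        if whisker_min is None:
            pts = [SurvivalPoint(d, s) for d, s in zip(dose, sf, strict=True)]
        else:
            pts = [
                SurvivalPoint(d, s, lo, hi)
                for d, s, lo, hi in zip(dose, sf, whisker_min, whisker_max, strict=True)
            ]
        return cls(points=tuple(pts), **kwargs)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def dose(self) -> np.ndarray:
        return np.array([p.dose for p in self.points])

    @property
    def sf(self) -> np.ndarray:
        return np.array([p.sf for p in self.points])

    @property
    def whisker_min(self) -> np.ndarray:
        return np.array(
            [p.whisker_min if p.has_whisker else np.nan for p in self.points]
        )

    @property
    def whisker_max(self) -> np.ndarray:
        return np.array(
            [p.whisker_max if p.has_whisker else np.nan for p in self.points]
        )

    @property
    def has_whiskers(self) -> bool:
        return all(p.has_whisker for p in self.points)

    def subset(self, indices: Iterable[int]) -> "SurvivalDataset":
        """A new dataset restricted to the given point indices."""
        pts = tuple(self.points[i] for i in indices)
        return replace(self, points=pts)
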