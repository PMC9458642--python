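"""Quality control for digitized survival data.

Points digitized from published graphs carry digitization error on top
of the experimental uncertainty.  Two safeguards are supported: a
dual-reading concordance check (each point digitized with two
independent tools must agree within a tolerance, 0.01 on the SF scale
by default) and a dose-lattice check (experimental dose values are, in
practice, integer multiples of 0.05 Gy, so a digitized dose close to a
lattice multiple can be snapped onto it).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .data import SurvivalDataset

__all__ = ["QCIssue", "QCReport", "concordance_check", "snap_dose", "validate_dataset"]

DOSE_LATTICE = 0.05
SNAP_TOL = 0.01
CONCORDANCE_TOL = 0.01

ISSUE_KINDS = (
    "sf-discordance",
    "whisker-discordance",
    "dose-off-lattice",
    "whisker-order",
    "sf-out-of-range",
)


@dataclass(frozen=True)
class QCIssue:
    index: int
    kind: str
    magnitude: float

    def __post_init__(self) -> None:
        if self.kind not in ISSUE_KINDS:
            raise ValueError(f"unknown issue kind {self.kind!r}")


@dataclass(frozen=True)
class QCReport:
    """A list of issues; empty iff the checked data passed."""

    issues: tuple[QCIssue, ...] = field(default_factory=tuple)

    def __bool__(self) -> bool:
        return bool(self.issues)

    def __len__(self) -> int:
        return len(self.issues)

    @property
    def passed(self) -> bool:
        return not self.issues

    def kinds(self) -> set[str]:
        return {i.kind for i in self.issues}


def concordance_check(
    reading_a: SurvivalDataset,
    reading_b: SurvivalDataset,
    tol: float = CONCORDANCE_TOL,
) -> QCReport:
    """Compare two independent digitizations of the same graph.

    Flags every point whose surviving fractions differ by strictly more
    than ``tol`` (``sf-discordance``), and applies the same rule to the
    whisker minima and maxima (``whisker-discordance``).  Differences
    exactly equal to the tolerance pass.
    """
    if len(reading_a) != len(reading_b):
        raise ValueError(
            f"readings have different point counts: {len(reading_a)} vs {len(reading_b)}"
        )
    issues: list[QCIssue] = []
    for i, (pa, pb) in enumerate(zip(reading_a.points, reading_b.points)):
        d_sf = abs(pa.sf - pb.sf)
        if d_sf > tol:
            issues.append(QCIssue(i, "sf-discordance", d_sf))
        if pa.has_whisker and pb.has_whisker:
            for a, b in ((pa.whisker_min, pb.whisker_min), (pa.whisker_max, pb.whisker_max)):
                d_w = abs(a - b)
                if d_w > tol:
                    issues.append(QCIssue(i, "whisker-discordance", d_w))
    return QCReport(tuple(issues))


def snap_dose(
    dose: float, lattice: float = DOSE_LATTICE, snap_tol: float = SNAP_TOL
) -> tuple[float, bool]:
    """Snap a digitized dose onto the nearest lattice multiple.

    Returns ``(snapped_dose, off_lattice)``.  If the nearest integer
    multiple of ``lattice`` lies within ``snap_tol``, that multiple is
    returned un-flagged; otherwise the input is returned unchanged with
    ``off_lattice=True``.  Doses are never moved by more than
    ``snap_tol``.
    """
    if dose < 0:
        raise ValueError(f"dose must be nonnegative, got {dose!r}")
    nearest = round(dose / lattice) * lattice
    if abs(dose - nearest) <= snap_tol:
        return float(nearest), False
    return float(dose), True


def validate_dataset(
    dataset: SurvivalDataset,
    lattice: float = DOSE_LATTICE,
    snap_tol: float = SNAP_TOL,
) -> QCReport:
    """Check a dataset against the structural constraints of the schema.

    Flags whisker disorder (``whisker_min <= sf <= whisker_max``
    violated), nonpositive surviving fractions, dose ordering and
    off-lattice doses.  Nothing is auto-corrected.
    """
    issues: list[QCIssue] = []
    for i, p in enumerate(dataset.points):
        if p.sf <= 0:
            issues.append(QCIssue(i, "sf-out-of-range", abs(p.sf)))
        if p.has_whisker and not (p.whisker_min <= p.sf <= p.whisker_max):
            mag = max(p.whisker_min - p.sf, p.sf - p.whisker_max, 0.0)
            issues.append(QCIssue(i, "whisker-order", mag))
        _, off = snap_dose(p.dose, lattice=lattice, snap_tol=snap_tol)
        if off:
            nearest = round(p.dose / lattice) * lattice
            issues.append(QCIssue(i, "dose-off-lattice", abs(p.dose - nearest)))
    return QCReport(tuple(issues))
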