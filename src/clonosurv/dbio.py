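"""Reading and writing the survival-curve database.

Two dialects are supported:

* ``canonical-long`` — a named-column CSV, one row per survival point,
  with dataset-level metadata and published parameters repeated on
  every row of a dataset.  This is the package's primary interchange
  format.
* ``deposited-sheet`` — a single-sheet XLSX laid out like the deposited
  spreadsheet database: dose in column B, SF in column C, whisker
  minimum/maximum in D/E, fit type in G, published parameters with
  their standard errors and confidence limits in columns H-X, cell
  type in Z and irradiation description in AA.  The exact pairing of
  the parameter columns is under-documented upstream, so this dialect
  is a best-effort import/export mapping.

Two cell sentinels are used throughout: ``'X'`` marks a value the
source article did not give, and ``'-'`` marks a value that is not
applicable to the dataset's fit type (e.g. ``alpha_s`` for a pure LQ
fit).
"""

from __future__ import annotations

import io
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .comparison import ParamEstimate
from .data import DatasetMeta, SurvivalDataset, SurvivalPoint

__all__ = [
    "MISSING",
    "NOT_APPLICABLE",
    "parse_param_cell",
    "read_database",
    "write_database",
    "filter_records",
    "SchemaError",
]


class _Sentinel:
    def __init__(self, name: str, token: str):
        self.name = name
        self.token = token

    def __repr__(self) -> str:
        return f"<{self.name}>"


#: value not given in the source article ('X' cell)
MISSING = _Sentinel("missing", "X")
#: value not applicable to the fit type ('-' cell)
NOT_APPLICABLE = _Sentinel("not-applicable", "-")


class SchemaError(ValueError):
    """A database file violates the tabular schema."""


def parse_param_cell(text, location: str = "") -> ParamEstimate | _Sentinel:
    """Interpret one parameter cell.

    ``'X'`` means the source did not give the value, ``'-'`` means the
    value does not apply to the fit type; anything else must be
    numeric.  Non-numeric, non-sentinel content is a schema error
    reported with the cell location.
    """
    if text is None:
        return MISSING
    s = str(text).strip()
    if s == "X":
        return MISSING
    if s in ("-", "—"):
        return NOT_APPLICABLE
    if s == "":
        return MISSING
    try:
        return ParamEstimate.bare(float(s))
    except ValueError:
        where = f" at {location}" if location else ""
        raise SchemaError(f"cannot parse parameter cell {s!r}{where}") from None


_PARAM_FIELDS = ("alpha_or_alpha_r", "beta", "alpha_s", "d_c")

_META_COLS = ("source", "figure", "cell_type", "irradiation", "fit_type")
_POINT_COLS = ("dose", "sf", "whisker_min", "whisker_max")


def _param_cols() -> list[str]:
    cols = []
    for p in _PARAM_FIELDS:
        cols += [p, f"{p}_se", f"{p}_ci_low", f"{p}_ci_high"]
    return cols


CANONICAL_COLUMNS = list(_META_COLS) + list(_POINT_COLS) + _param_cols()

_FIT_TYPES = ("LQ", "IR", "both", "none")


def _fmt(x) -> str:
    if x is None:
        return ""
    return repr(float(x))


def _parse_float(s: str, location: str):
    s = str(s).strip()
    if s == "":
        return None
    try:
        return float(s)
    except ValueError:
        raise SchemaError(f"expected a number at {location}, got {s!r}") from None


def _applicable(param: str, fit_type: str) -> bool:
    if fit_type == "none":
        return False
    if param in ("alpha_or_alpha_r", "beta"):
        return True
    return fit_type in ("IR", "both")  # alpha_s, d_c


def _estimate_from_cells(value_cell, se_cell, lo_cell, hi_cell, location: str):
    """Build a ParamEstimate from a value cell plus its uncertainty cells.

    Returns a sentinel when the value itself is 'X' or '-'.
    """
    base = parse_param_cell(value_cell, location)
    if isinstance(base, _Sentinel):
        return base
    se = parse_param_cell(se_cell, location + " (se)")
    lo = parse_param_cell(lo_cell, location + " (ci_low)")
    hi = parse_param_cell(hi_cell, location + " (ci_high)")
    if not isinstance(se, _Sentinel):
        return ParamEstimate.from_se(base.value, se.value)
    if not isinstance(lo, _Sentinel) and not isinstance(hi, _Sentinel):
        return ParamEstimate.from_ci(base.value, lo.value, hi.value)
    return base  # value published without uncertainty


def _cells_from_estimate(est: ParamEstimate | None, applicable: bool) -> list[str]:
    """Inverse of :func:`_estimate_from_cells` -> [value, se, lo, hi]."""
    if not applicable:
        return ["-"] * 4
    if est is None:
        return ["X"] * 4
    if est.uncertainty_kind == "SE":
        return [_fmt(est.value), _fmt(est.se), "X", "X"]
    if est.uncertainty_kind == "CI":
        return [_fmt(est.value), "X", _fmt(est.ci_low), _fmt(est.ci_high)]
    return [_fmt(est.value), "X", "X", "X"]


def _published_maps(fit_type, estimates: dict):
    """Split the shared parameter fields into LQ and IR mappings."""
    published_lq = None
    published_ir = None
    if fit_type in ("LQ", "both"):
        lq = {}
        if "alpha_or_alpha_r" in estimates:
            lq["alpha"] = estimates["alpha_or_alpha_r"]
        if "beta" in estimates:
            lq["beta"] = estimates["beta"]
        published_lq = lq or None
    if fit_type in ("IR", "both"):
        ir = {}
        if "alpha_or_alpha_r" in estimates:
            ir["alpha_r"] = estimates["alpha_or_alpha_r"]
        for name in ("beta", "alpha_s", "d_c"):
            if name in estimates:
                ir[name] = estimates[name]
        published_ir = ir or None
    return published_lq, published_ir


def _dataset_from_rows(rows: list[dict], first_row_no: int) -> SurvivalDataset:
    meta = DatasetMeta(
        source=rows[0]["source"],
        figure=rows[0]["figure"],
        cell_type=rows[0]["cell_type"],
        irradiation=rows[0]["irradiation"],
    )
    fit_type = rows[0]["fit_type"] or "none"
    if fit_type not in _FIT_TYPES:
        raise SchemaError(
            f"unknown fit type {fit_type!r} at row {first_row_no}"
        )
    points = []
    for offset, row in enumerate(rows):
        row_no = first_row_no + offset
        dose = _parse_float(row["dose"], f"row {row_no}, dose")
        sf = _parse_float(row["sf"], f"row {row_no}, sf")
        lo = _parse_float(row["whisker_min"], f"row {row_no}, whisker_min")
        hi = _parse_float(row["whisker_max"], f"row {row_no}, whisker_max")
        if dose is None or sf is None:
            raise SchemaError(f"missing dose or sf at row {row_no}")
        if lo is not None and hi is not None:
            if not (lo <= sf <= hi):
                raise SchemaError(
                    f"whisker ordering violated at row {row_no}: "
                    f"{lo} <= {sf} <= {hi} fails"
                )
        points.append(SurvivalPoint(dose, sf, lo, hi))

    estimates = {}
    for p in _PARAM_FIELDS:
        est = _estimate_from_cells(
            rows[0][p],
            rows[0][f"{p}_se"],
            rows[0][f"{p}_ci_low"],
            rows[0][f"{p}_ci_high"],
            f"row {first_row_no}, {p}",
        )
        if not isinstance(est, _Sentinel):
            estimates[p] = est
    published_lq, published_ir = _published_maps(fit_type, estimates)
    return SurvivalDataset(
        points=tuple(points),
        meta=meta,
        published_lq=published_lq,
        published_ir=published_ir,
        fit_type=fit_type,
    )


def _group_rows(records: list[dict], start_row: int) -> list[SurvivalDataset]:
    datasets = []
    group: list[dict] = []
    group_start = start_row
    key = None
    for i, row in enumerate(records):
        row_key = (row["source"], row["figure"])
        if key is None or row_key == key:
            group.append(row)
            key = row_key
        else:
            datasets.append(_dataset_from_rows(group, group_start))
            group = [row]
            key = row_key
            group_start = start_row + i
    if group:
        datasets.append(_dataset_from_rows(group, group_start))
    return datasets


# ---------------------------------------------------------------------------
# canonical-long CSV


def _read_canonical(stream) -> list[SurvivalDataset]:
    df = pd.read_csv(stream, dtype=str, keep_default_na=False)
    missing_cols = set(CANONICAL_COLUMNS) - set(df.columns)
    if missing_cols:
        raise SchemaError(f"missing columns: {sorted(missing_cols)}")
    records = df.to_dict(orient="records")
    return _group_rows(records, start_row=2)  # row 1 is the header


def _rows_for_dataset(ds: SurvivalDataset) -> list[list[str]]:
    # The shared parameter fields: for fit type "both" the single
    # alpha_or_alpha_r slot holds the IR alpha_r (the richer fit).
    published = {}
    if ds.published_ir:
        published.update(
            {
                "alpha_or_alpha_r": ds.published_ir.get("alpha_r"),
                "beta": ds.published_ir.get("beta"),
                "alpha_s": ds.published_ir.get("alpha_s"),
                "d_c": ds.published_ir.get("d_c"),
            }
        )
    elif ds.published_lq:
        published.update(
            {
                "alpha_or_alpha_r": ds.published_lq.get("alpha"),
                "beta": ds.published_lq.get("beta"),
            }
        )
    param_cells = []
    for p in _PARAM_FIELDS:
        param_cells += _cells_from_estimate(
            published.get(p), _applicable(p, ds.fit_type)
        )
    rows = []
    for pt in ds.points:
        rows.append(
            [
                ds.meta.source,
                ds.meta.figure,
                ds.meta.cell_type,
                ds.meta.irradiation,
                ds.fit_type,
                _fmt(pt.dose),
                _fmt(pt.sf),
                _fmt(pt.whisker_min),
                _fmt(pt.whisker_max),
            ]
            + param_cells
        )
    return rows


def _write_canonical(datasets: Sequence[SurvivalDataset], stream) -> None:
    rows = []
    for ds in datasets:
        rows.extend(_rows_for_dataset(ds))
    df = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
    df.to_csv(stream, index=False)


# ---------------------------------------------------------------------------
# deposited-sheet XLSX

# Column letters -> canonical field names.  P and Y are unassigned in
# the upstream description and written as '-' placeholders.
_SHEET_LAYOUT = {
    "A": "source",
    "B": "dose",
    "C": "sf",
    "D": "whisker_min",
    "E": "whisker_max",
    "F": "figure",
    "G": "fit_type",
    "H": "alpha_or_alpha_r",
    "I": "alpha_or_alpha_r_se",
    "J": "alpha_or_alpha_r_ci_low",
    "K": "alpha_or_alpha_r_ci_high",
    "L": "beta",
    "M": "beta_se",
    "N": "beta_ci_low",
    "O": "beta_ci_high",
    "P": None,
    "Q": "alpha_s",
    "R": "alpha_s_se",
    "S": "alpha_s_ci_low",
    "T": "alpha_s_ci_high",
    "U": "d_c",
    "V": "d_c_se",
    "W": "d_c_ci_low",
    "X": "d_c_ci_high",
    "Y": None,
    "Z": "cell_type",
    "AA": "irradiation",
}


def _read_deposited(path_or_stream) -> list[SurvivalDataset]:
    from openpyxl import load_workbook

    wb = load_workbook(path_or_stream, read_only=True, data_only=True)
    ws = wb.worksheets[0]
    fields = list(_SHEET_LAYOUT.values())
    records = []
    carry: dict[str, str] = {}
    for row in ws.iter_rows(min_row=2, max_col=len(fields), values_only=True):
        if all(v is None or str(v).strip() == "" for v in row):
            carry = {}  # blank row separates dataset blocks
            continue
        rec = {}
        for field, value in zip(fields, row):
            if field is None:
                continue
            rec[field] = "" if value is None else str(value)
        # dataset-level cells may be written only on a block's first row
        for key in list(rec):
            if key in ("dose", "sf", "whisker_min", "whisker_max"):
                continue
            if rec[key] == "" and key in carry:
                rec[key] = carry[key]
        carry = {k: v for k, v in rec.items() if k not in _POINT_COLS}
        records.append(rec)
    wb.close()
    return _group_rows(records, start_row=2)


def _write_deposited(datasets: Sequence[SurvivalDataset], path_or_stream) -> None:
    from openpyxl import Workbook

    wb = Workbook()
    ws = wb.active
    ws.title = "datasets"
    header = [
        field if field is not None else letter
        for letter, field in _SHEET_LAYOUT.items()
    ]
    ws.append(header)
    canonical_index = {name: i for i, name in enumerate(CANONICAL_COLUMNS)}
    for ds in datasets:
        for row in _rows_for_dataset(ds):
            sheet_row = []
            for letter, field in _SHEET_LAYOUT.items():
                sheet_row.append("-" if field is None else row[canonical_index[field]])
            ws.append(sheet_row)
    wb.save(path_or_stream)


# ---------------------------------------------------------------------------
# public API


def read_database(path_or_stream, dialect: str = "canonical-long") -> list[SurvivalDataset]:
    """Read a survival database file into a list of datasets.

    Rows are grouped into datasets by (source, figure); point order is
    preserved as stored.  Schema violations raise :class:`SchemaError`
    naming the offending row; a partially valid file is never returned
    silently.
    """
    if dialect in ("canonical-long", "canonical", "csv"):
        if isinstance(path_or_stream, (str,)) or hasattr(path_or_stream, "__fspath__"):
            with open(path_or_stream, "r", encoding="utf-8", newline="") as fh:
                return _read_canonical(fh)
        return _read_canonical(path_or_stream)
    if dialect in ("deposited-sheet", "deposited", "xlsx"):
        return _read_deposited(path_or_stream)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_database(
    datasets: Sequence[SurvivalDataset],
    path_or_stream=None,
    dialect: str = "canonical-long",
):
    """Write datasets to a database file.

    With no target given and the canonical dialect, the CSV text is
    returned as a string.  ``read_database(write_database(x)) == x`` up
    to float formatting (shortest-repr round-trip is exact).
    """
    if dialect in ("canonical-long", "canonical", "csv"):
        if path_or_stream is None:
            buf = io.StringIO()
            _write_canonical(datasets, buf)
            return buf.getvalue()
        if isinstance(path_or_stream, str) or hasattr(path_or_stream, "__fspath__"):
            with open(path_or_stream, "w", encoding="utf-8", newline="") as fh:
                _write_canonical(datasets, fh)
            return None
        _write_canonical(datasets, path_or_stream)
        return None
    if dialect in ("deposited-sheet", "deposited", "xlsx"):
        if path_or_stream is None:
            raise ValueError("the deposited-sheet dialect requires a file target")
        _write_deposited(datasets, path_or_stream)
        return None
    raise ValueError(f"unknown dialect {dialect!r}")


_FILTER_FIELDS = ("cell_type", "irradiation", "source", "figure")


def filter_records(
    datasets: Iterable[SurvivalDataset],
    query: Mapping[str, str | Callable[[str], bool]],
) -> list[SurvivalDataset]:
    """Filter datasets by metadata fields.

    ``query`` maps a field name (``cell_type``, ``irradiation``,
    ``source`` or ``figure``) to either a substring (case-sensitive
    containment) or a predicate over the field text.  An empty query is
    the identity.
    """
    for field in query:
        if field not in _FILTER_FIELDS:
            raise KeyError(
                f"unknown filter field {field!r}; expected one of {_FILTER_FIELDS}"
            )
    out = []
    for ds in datasets:
        keep = True
        for field, pred in query.items():
            text = getattr(ds.meta, field)
            ok = pred(text) if callable(pred) else (str(pred) in text)
            if not ok:
                keep = False
                break
        if keep:
            out.append(ds)
    return out
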