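import io

import numpy as np
import pytest

from clonosurv import (
    DatasetMeta,
    ParamEstimate,
    SurvivalDataset,
    filter_records,
    read_database,
    write_database,
)
from clonosurv.dbio import (
    MISSING,
    NOT_APPLICABLE,
    SchemaError,
    parse_param_cell,
)
from clonosurv.synth import simulate_database


def _fixture_datasets():
    """Three hand-built datasets covering every sentinel/uncertainty kind."""
    pts = lambda: ([0.1, 0.5, 2.0, 4.0], [0.85, 0.7, 0.35, 0.1], [0.8, 0.65, 0.3, 0.08], [0.9, 0.75, 0.4, 0.12])
    ds_lq = SurvivalDataset.from_arrays(
        *pts(),
        meta=DatasetMeta("articleA", "fig2", "V79 hamster lung", "X-rays, 250 kV"),
        published_lq={
            "alpha": ParamEstimate.from_se(0.32, 0.11),
            "beta": ParamEstimate.bare(0.008),
        },
        fit_type="LQ",
    )
    ds_ir = SurvivalDataset.from_arrays(
        *pts(),
        meta=DatasetMeta("articleB", "fig1", "CHO ovary", "60Co gamma"),
        published_ir={
            "alpha_r": ParamEstimate.from_ci(0.18, 0.10, 0.50),
            "beta": ParamEstimate.from_se(0.14, 0.04),
            "alpha_s": ParamEstimate.from_se(1.86, 0.05),
            # d_c not reported -> 'X' cell
        },
        fit_type="IR",
    )
    ds_none = SurvivalDataset.from_arrays(
        *pts(),
        meta=DatasetMeta("articleC", "fig3", "V79 hamster lung", "4He2+ ions"),
        fit_type="none",
    )
    return [ds_lq, ds_ir, ds_none]


class TestParseParamCell:
    def test_sentinels_and_values(self):
        assert parse_param_cell("X") is MISSING
        assert parse_param_cell("-") is NOT_APPLICABLE
        est = parse_param_cell("0.32")
        assert est.value == 0.32
        assert est.uncertainty_kind == "missing"

    def test_garbage_rejected_with_location(self):
        with pytest.raises(SchemaError, match="row 7"):
            parse_param_cell("abc", location="row 7, beta")


class TestCanonicalRoundTrip:
    def test_values_and_sentinels_survive(self):
        original = _fixture_datasets()
        text = write_database(original)
        back = read_database(io.StringIO(text))
        assert len(back) == 3
        for a, b in zip(original, back):
            assert a.meta == b.meta
            assert a.fit_type == b.fit_type
            assert a.dose.tolist() == b.dose.tolist()
            assert a.sf.tolist() == b.sf.tolist()
            assert a.whisker_min.tolist() == b.whisker_min.tolist()
        # LQ published parameters
        lq = back[0].published_lq
        assert lq["alpha"].se == 0.11
        assert lq["beta"].uncertainty_kind == "missing"
        # IR with CI-only alpha_r and unreported d_c
        ir = back[1].published_ir
        assert ir["alpha_r"].uncertainty_kind == "CI"
        assert (ir["alpha_r"].ci_low, ir["alpha_r"].ci_high) == (0.10, 0.50)
        assert "d_c" not in ir
        assert back[2].published_lq is None and back[2].published_ir is None

    def test_ci_only_estimate_leaves_se_cell_x(self):
        text = write_database(_fixture_datasets())
        header, first_ir_row = None, None
        for line in text.splitlines():
            if header is None:
                header = line.split(",")
            elif line.startswith("articleB"):
                first_ir_row = line.split(",")
                break
        cells = dict(zip(header, first_ir_row))
        assert cells["alpha_or_alpha_r_se"] == "X"
        assert cells["alpha_or_alpha_r_ci_low"] == "0.1"
        assert cells["d_c"] == "X"
        # alpha_s has an SE, so its CI cells carry the 'X' sentinel
        assert cells["alpha_s_ci_low"] == "X"

    def test_empty_database_writes_header_only(self):
        text = write_database([])
        lines = [ln for ln in text.splitlines() if ln]
        assert len(lines) == 1

    def test_point_order_preserved(self):
        db = simulate_database(2, seed=3)
        back = read_database(io.StringIO(write_database(db)))
        for a, b in zip(db, back):
            assert a.dose.tolist() == b.dose.tolist()

    def test_whisker_order_violation_is_schema_error(self):
        text = write_database(_fixture_datasets())
        broken = text.replace("0.85,0.8,0.9", "0.85,0.88,0.9", 1)
        assert broken != text
        with pytest.raises(SchemaError, match="row"):
            read_database(io.StringIO(broken))


class TestDepositedRoundTrip:
    def test_xlsx_round_trip(self, tmp_path):
        original = _fixture_datasets()
        path = tmp_path / "db.xlsx"
        write_database(original, path, dialect="deposited")
        back = read_database(path, dialect="deposited")
        assert len(back) == 3
        for a, b in zip(original, back):
            assert a.meta == b.meta
            assert a.dose.tolist() == b.dose.tolist()
            assert a.sf.tolist() == b.sf.tolist()
        assert back[1].published_ir["alpha_s"].se == 0.05


class TestFilterRecords:
    def test_cell_line_substring(self):
        db = _fixture_datasets()
        hits = filter_records(db, {"cell_type": "V79"})
        assert len(hits) == 2

    def test_empty_query_is_identity(self):
        db = _fixture_datasets()
        assert filter_records(db, {}) == db

    def test_no_match_gives_empty_list(self):
        db = _fixture_datasets()
        assert filter_records(db, {"irradiation": "protons"}) == []

    def test_unknown_field_rejected(self):
        with pytest.raises(KeyError):
            filter_records(_fixture_datasets(), {"voltage": "250"})
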