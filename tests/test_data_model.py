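"""Fixture integrity, CSV round-trips and schema validation."""

import numpy as np
import pandas as pd
import pytest

from moringa_qc import (
    DetectionStatus,
    QuantTable,
    load_fixture,
    read_quant_table,
    read_replicate_table,
    write_quant_table,
)
from moringa_qc.data_model import DEFAULT_PANEL, MEDIA, unit_for_medium
from moringa_qc.errors import FixtureLookupError, SchemaError, ValidationError


class TestPanel:
    def test_ten_compounds_in_elution_order(self):
        assert DEFAULT_PANEL.ids == list(range(1, 11))
        rts = [c.retention_time_min for c in DEFAULT_PANEL.compounds]
        assert rts == sorted(rts)
        assert rts[0] == 1.4 and rts[-1] == 8.7

    def test_units_follow_medium(self):
        assert unit_for_medium("solvent") == "mg/L"
        for medium in MEDIA[1:]:
            assert unit_for_medium(medium) == "mg/kg"
        with pytest.raises(ValidationError):
            unit_for_medium("plasma")


class TestReplicateTable:
    def test_round_trip_identity(self, replicate_csv):
        table = read_replicate_table(replicate_csv)
        assert len(table) == 49  # 7 levels × 7 replicates
        assert (table.frame.groupby("level").size() == 7).all()
        assert set(table.units) == {"mg/L"}

    def test_missing_response_column_names_it(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"compound": [1], "medium": ["solvent"], "level": [1],
                      "replicate": [1], "day": [1]}).to_csv(path, index=False)
        with pytest.raises(SchemaError, match="response"):
            read_replicate_table(path)

    def test_negative_response_rejected_with_row(self, tmp_path):
        path = tmp_path / "neg.csv"
        pd.DataFrame({"compound": [1, 1], "medium": ["solvent"] * 2, "level": [1, 2],
                      "replicate": [1, 1], "day": [1, 1], "response": [5.0, -1.0]}).to_csv(path, index=False)
        with pytest.raises(ValidationError, match="1"):
            read_replicate_table(path)


class TestFixtures:
    def test_unknown_fixture_name(self):
        with pytest.raises(FixtureLookupError):
            load_fixture("table9")

    @pytest.mark.parametrize(
        "compound,medium,column,expected",
        [
            (1, "solvent", "slope", 5.6426),
            (1, "solvent", "intercept", 0.1675),
            (1, "porridge", "slope", 8.1535),
            (1, "teabag", "slope", 4.0215),
            (7, "seeds", "intercept", 12.643),
            (8, "solvent", "r_squared", 0.9999),
            (8, "porridge", "lod", 0.9),   # printed pair violating the 10/3 ratio, kept verbatim
            (8, "porridge", "loq", 0.4),
            (10, "teabag", "loq", 3.1),
        ],
    )
    def test_table1_cells_as_printed(self, table1, compound, medium, column, expected):
        row = table1[(table1.compound == compound) & (table1.medium == medium)]
        assert row[column].iloc[0] == pytest.approx(expected)

    def test_table1_shape_and_checksums(self, table1):
        """Regression guard over every numeric cell of the fitted-line table."""
        assert len(table1) == 60  # 10 compounds × 6 media
        assert table1.groupby("medium").size().eq(10).all()
        sums = table1[["slope", "intercept", "r_squared", "lod", "loq"]].sum()
        assert sums["slope"] == pytest.approx(475.0972, abs=1e-4)
        assert sums["intercept"] == pytest.approx(4.0748, abs=1e-4)
        assert sums["r_squared"] == pytest.approx(59.7568, abs=1e-4)
        assert sums["lod"] == pytest.approx(43.8, abs=1e-9)
        assert sums["loq"] == pytest.approx(141.7, abs=1e-9)

    @pytest.mark.parametrize(
        "compound,medium,level,column,expected",
        [
            (1, "leaves", 3, "recovery", 76.0),
            (1, "seeds", 3, "rsd_intra", 4.7),
            (1, "seeds", 3, "rsd_inter", 6.0),
            (5, "leaves", 3, "recovery", 113.0),
            (1, "seeds", 3, "recovery", 66.7),
            (2, "teabag", 3, "recovery", 69.7),
            (1, "solvent", 1, "rsd_intra", 1.1),
            (2, "solvent", 3, "rsd_inter", 0.05),
        ],
    )
    def test_table2_cells_as_printed(self, table2, compound, medium, level, column, expected):
        row = table2[(table2.compound == compound) & (table2.medium == medium) & (table2.level == level)]
        assert row[column].iloc[0] == pytest.approx(expected)

    def test_table2_layout(self, table2):
        assert len(table2) == 180  # 10 compounds × (3 solvent + 5 matrices × 3) levels
        assert table2.loc[table2.medium == "solvent", "recovery"].isna().all()
        assert table2.loc[table2.medium != "solvent", "recovery"].notna().all()

    def test_table2_uncertainty_metadata(self):
        u = load_fixture("table2_uncertainty")
        assert len(u) == 50
        assert u.u_expanded.min() == pytest.approx(0.3)   # lowest: compound 3, leaves
        assert u.u_expanded.max() == pytest.approx(10.7)  # compound 1, seeds
        row = u[(u.compound == 2) & (u.medium == "teabag")]
        assert row.u_expanded.iloc[0] == pytest.approx(9.8)

    def test_table3_cells_and_coding(self, table3):
        assert table3.values.shape == (32, 10)
        assert table3.values.loc["L3", 6] == pytest.approx(9.7)
        assert table3.values.loc["L4", 3] == pytest.approx(8.4)
        status = table3.status()
        assert status.loc["L1", 1] == DetectionStatus.NOT_DETECTED
        assert status.loc["L1", 2] == DetectionStatus.BELOW_LOQ
        assert status.loc["L1", 3] == DetectionStatus.QUANTIFIED
        # quantified cells are all at least the smallest printed LOQ band
        vals = table3.matrix()
        quantified = vals[(vals != 0.0) & (vals != 0.1)]
        assert quantified.min() >= 4.1


class TestQuantTableIO:
    def test_fixture_round_trip_bit_exact(self, table3, tmp_path):
        path = tmp_path / "t3.csv"
        write_quant_table(table3, path)
        again = read_quant_table(path)
        assert again == table3
        # and the raw CSV text preserves the coded sentinels
        text = path.read_text()
        assert ",0.1," in text and ",0.0," in text

    def test_empty_table_writes_header_only(self, tmp_path):
        empty = QuantTable(pd.DataFrame(columns=[1, 2], dtype=float))
        path = tmp_path / "empty.csv"
        write_quant_table(empty, path)
        lines = path.read_text().strip().splitlines()
        assert lines == ["sample,c1,c2"]

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValidationError):
            QuantTable(pd.DataFrame({1: [-0.5]}, index=["X1"]))
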