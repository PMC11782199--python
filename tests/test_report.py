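"""Report layer: table reproduction, family comparison, discrepancy report,
config handling and CSV formatting."""

import json

import pytest

from irrnet import (
    ReportConfig,
    comparison_series,
    discrepancy_report,
    reproduce_tables,
)
from irrnet.report import format_table_csv, write_report


class TestReportConfig:
    def test_defaults(self):
        cfg = ReportConfig()
        assert cfg.families == ("OT", "IS")
        assert cfg.n_values == (1, 2, 3, 4, 5)
        assert cfg.comparison_index == "IRDIF"

    def test_rejects_empty_or_invalid_n(self):
        with pytest.raises(ValueError):
            ReportConfig(n_values=())
        with pytest.raises(ValueError):
            ReportConfig(n_values=(0, 1))

    def test_from_yaml_with_cli_override(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("n_values: [1, 2]\ncomparison_index: AL\n")
        cfg = ReportConfig.from_file(path, comparison_index="IRF")
        assert cfg.n_values == (1, 2)
        assert cfg.comparison_index == "IRF"  # override wins


class TestReproduceTables:
    def test_ot_albertson_row(self):
        tables = reproduce_tables(ReportConfig())
        assert list(tables["OT"].loc["AL"]) == [144, 576, 1296, 2304, 3600]

    def test_is_irf_row(self):
        tables = reproduce_tables(ReportConfig())
        assert list(tables["IS"].loc["IRF"]) == [1200, 5100, 11700, 21000, 33000]

    def test_single_n_config(self):
        tables = reproduce_tables(ReportConfig(n_values=(1,)))
        assert tables["OT"].shape == (12, 1)
        assert tables["IS"].loc["IRDIF", 1] == 72


class TestComparisonSeries:
    def test_irdif_values_and_verdict(self):
        comp = comparison_series(ReportConfig())
        row1 = comp.table[comp.table["n"] == 1].iloc[0]
        assert (row1["value_1"], row1["value_2"]) == (54, 72)
        row5 = comp.table[comp.table["n"] == 5].iloc[0]
        assert (row5["value_1"], row5["value_2"]) == (1350, 1980)
        assert comp.verdict == "family_2_dominates"

    def test_difference_is_quadratic_and_positive(self):
        comp = comparison_series(ReportConfig())
        assert comp.differences == [27 * n * n - 9 * n for n in range(1, 6)]
        assert all(d > 0 for d in comp.differences)

    def test_equal_family_comparison_ties(self):
        comp = comparison_series(ReportConfig(families=("OT", "OT")))
        assert comp.verdict == "tie"
        assert comp.differences == [0] * 5


class TestDiscrepancyReport:
    def test_ot_table_has_no_discrepancies(self):
        assert discrepancy_report(families=["OT"]) == []

    def test_is_irga_row_flagged_as_convention(self):
        report = {(d.index_id, d.n): d for d in discrepancy_report(families=["IS"])}
        d = report[("IRGA", 1)]
        assert d.printed == 2.826768
        assert d.faithful == pytest.approx(2 * 2.826768, rel=1e-4)
        assert d.classification == "convention"
        assert all(report[("IRGA", n)].classification == "convention"
                   for n in range(1, 6))

    def test_is_irla_noise_flagged_as_rounding(self):
        report = {(d.index_id, d.n): d for d in discrepancy_report(families=["IS"])}
        d = report[("IRLA", 1)]
        assert d.printed == 32.000016
        assert d.faithful == 32
        assert d.classification == "rounding"

    def test_is_irb_n4_flagged_as_typo(self):
        report = {(d.index_id, d.n): d for d in discrepancy_report(families=["IS"])}
        d = report[("IRB", 4)]
        assert d.printed == 720.736120
        assert d.faithful == pytest.approx(720.606078, rel=1e-6)
        assert d.classification == "typo"

    def test_nothing_else_is_flagged(self):
        flagged = {(d.index_id, d.n) for d in discrepancy_report(families=["IS"])}
        expected = {("IRGA", n) for n in range(1, 6)}
        expected |= {("IRLA", n) for n in range(1, 6)}
        expected |= {("IRB", 4)}
        assert flagged == expected


class TestOutputs:
    def test_csv_format(self):
        tables = reproduce_tables(ReportConfig(n_values=(1, 2)))
        text = format_table_csv(tables["OT"])
        lines = text.strip().splitlines()
        assert lines[0] == "index,n=1,n=2"
        assert lines[1] == "IRDIF,54,216"  # integers printed plain
        assert lines[3].startswith("IRL,24.953299,")  # 6-decimal fixed point

    def test_write_report(self, tmp_path):
        cfg = ReportConfig(out_dir=str(tmp_path), n_values=(1, 2))
        written = write_report(cfg)
        assert (tmp_path / "table_OT.csv").exists()
        assert (tmp_path / "table_IS.csv").exists()
        assert (tmp_path / "comparison_IRDIF.csv").exists()
        doc = json.loads((tmp_path / "discrepancies.json").read_text())
        assert {d["classification"] for d in doc} <= {"rounding", "convention", "typo"}
        assert set(written) == {"table_OT", "table_IS", "comparison", "discrepancies"}
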