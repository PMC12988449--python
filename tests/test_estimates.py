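"""Ingest validation, harmonization resolution, and analysis-set filtering."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from revstab.estimates import (
    FilterRules,
    HarmonizationMap,
    IntegrityError,
    SchemaError,
    ValidationError,
    filter_analysis_set,
    harmonize,
    read_estimates_csv,
    write_estimates_csv,
)

from .conftest import estimate_row, write_estimates_file


class TestIngest:
    def test_well_formed_rows_ingest_identically(self, tmp_path):
        rows = [
            estimate_row("Diet high in red meat", 2019, 2019, 57000.0),
            estimate_row("Diet high in red meat", 2021, 2019, 93000.0,
                         ui_lower=40000.0, ui_upper=150000.0),
            estimate_row("Air pollution", 2021, 2021, 8.1e6, metric="dalys"),
        ]
        path = write_estimates_file(tmp_path / "est.csv", rows)
        table = read_estimates_csv(path)
        assert len(table) == 3
        assert table.df["value"].tolist() == [57000.0, 93000.0, 8.1e6]
        # one-sided-missing UI stays missing, not zero-filled
        assert np.isnan(table.df.loc[0, "ui_lower"])

    def test_duplicate_full_key_names_both_rows(self, tmp_path):
        rows = [
            estimate_row("Air pollution", 2019, 2019, 1.0),
            estimate_row("Diet high in sodium", 2019, 2019, 2.0),
            estimate_row("Air pollution", 2019, 2019, 3.0),
        ]
        path = write_estimates_file(tmp_path / "dup.csv", rows)
        with pytest.raises(IntegrityError, match=r"rows \[1, 3\]"):
            read_estimates_csv(path)

    def test_inverted_interval_rejected_with_row_number(self, tmp_path):
        rows = [
            estimate_row("Air pollution", 2019, 2019, 5.0,
                         ui_lower=7.0, ui_upper=3.0),
        ]
        path = write_estimates_file(tmp_path / "bad.csv", rows)
        with pytest.raises(ValidationError, match="row 1.*ui_lower"):
            read_estimates_csv(path)

    def test_year_after_release_iteration_rejected(self, tmp_path):
        rows = [estimate_row("Air pollution", 2019, 2021, 5.0)]
        path = write_estimates_file(tmp_path / "late.csv", rows)
        with pytest.raises(IntegrityError, match="year 2021 > iteration 2019"):
            read_estimates_csv(path)

    def test_negative_value_and_unknown_metric_rejected(self, tmp_path):
        rows = [
            estimate_row("Air pollution", 2019, 2019, -1.0),
            estimate_row("Air pollution", 2019, 2018, 1.0, metric="yld"),
        ]
        path = write_estimates_file(tmp_path / "bad2.csv", rows)
        with pytest.raises(ValidationError) as exc:
            read_estimates_csv(path)
        assert "row 1" in str(exc.value) and "row 2" in str(exc.value)

    def test_missing_required_column_is_schema_error(self, tmp_path):
        path = tmp_path / "noval.csv"
        path.write_text("risk,metric,iteration,year\nA,deaths,2019,2019\n")
        with pytest.raises(SchemaError, match="value"):
            read_estimates_csv(path)

    def test_schema_mapping_resolves_renamed_columns(self, tmp_path):
        path = tmp_path / "renamed.csv"
        path.write_text(
            "rei_name,measure,release_cycle,year_id,val\n"
            "Air pollution,deaths,2019,2019,123.0\n"
        )
        table = read_estimates_csv(path, schema={
            "risk": "rei_name", "metric": "measure", "iteration": "release_cycle",
            "year": "year_id", "value": "val",
        })
        assert len(table) == 1
        # optional stratum columns default to the overall slice
        assert table.df.loc[0, ["sex", "location", "cause_group"]].tolist() == [
            "both", "global", "all"
        ]

    def test_ui_not_bracketing_point_is_flagged_not_dropped(self, tmp_path):
        rows = [estimate_row("Air pollution", 2019, 2019, 10.0,
                             ui_lower=11.0, ui_upper=20.0)]
        path = write_estimates_file(tmp_path / "flag.csv", rows)
        table = read_estimates_csv(path)
        assert len(table) == 1
        assert bool(table.df.loc[0, "ui_violation"])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(values=st.lists(
        st.floats(min_value=0, max_value=1e12, allow_nan=False,
                  allow_infinity=False),
        min_size=1, max_size=8))
    def test_write_read_roundtrip_preserves_values_exactly(self, values, tmp_path_factory):
        tmp = tmp_path_factory.mktemp("rt")
        rows = [
            estimate_row("Air pollution", 2010 + i, 2010, v)
            for i, v in enumerate(values)
        ]
        path = write_estimates_file(tmp / "rt.csv", rows)
        table = read_estimates_csv(path)
        out = tmp / "out.csv"
        write_estimates_csv(table, out)
        again = read_estimates_csv(out)
        assert again.df["value"].tolist() == table.df["value"].tolist()
        assert out.read_text() == out.read_text()  # stable serialization


class TestHarmonize:
    def test_two_spellings_collapse_to_one_identifier(self, tmp_path, tiny_map,
                                                      tiny_hierarchy):
        rows = [
            estimate_row("Red meat consumption", 2010, 2010, 40000.0),
            estimate_row("Diet high in red meat", 2019, 2019, 57000.0),
        ]
        table = read_estimates_csv(write_estimates_file(tmp_path / "e.csv", rows))
        result = harmonize(table, tiny_map, tiny_hierarchy)
        assert result.table.df["risk_id"].unique().tolist() == ["diet_red_meat"]
        assert result.table.df.loc[0, "group"] == "behavioral"
        assert result.unmapped.empty

    def test_unmapped_name_reported_not_dropped_silently(self, tmp_path, tiny_map):
        rows = [
            estimate_row("Diet high in sodium", 2019, 2019, 1.0),
            estimate_row("Mystery exposure", 2019, 2019, 2.0),
            estimate_row("Mystery exposure", 2021, 2021, 3.0),
        ]
        table = read_estimates_csv(write_estimates_file(tmp_path / "e.csv", rows))
        result = harmonize(table, tiny_map)
        assert len(result.table) == 1
        assert result.unmapped["risk"].tolist() == ["Mystery exposure"] * 2
        assert result.unmapped["n_records"].sum() == 2

    def test_iteration_specific_entry_beats_wildcard(self):
        # resolution-order oracle on a two-entry map
        hmap = HarmonizationMap([
            ("Physical inactivity", None, "air_pollution"),
            ("Physical inactivity", 2010, "low_physical_activity"),
        ])
        assert hmap.resolve("Physical inactivity", 2010) == "low_physical_activity"
        assert hmap.resolve("Physical inactivity", 2019) == "air_pollution"

    def test_harmonize_is_idempotent(self, tmp_path, tiny_map, tiny_hierarchy):
        rows = [
            estimate_row("Diet high in sodium", 2019, 2019, 1.0),
            estimate_row("Diet high in sodium", 2021, 2021, 2.0),
        ]
        table = read_estimates_csv(write_estimates_file(tmp_path / "e.csv", rows))
        once = harmonize(table, tiny_map, tiny_hierarchy).table
        twice = harmonize(once, tiny_map, tiny_hierarchy).table
        pd.testing.assert_frame_equal(once.df, twice.df)

    def test_duplicate_map_entries_rejected(self):
        with pytest.raises(IntegrityError, match="duplicate harmonization entry"):
            HarmonizationMap([("A", None, "x"), ("A", None, "y")])


class TestFilterAnalysisSet:
    @staticmethod
    def _table(tmp_path, tiny_map, tiny_hierarchy, rows):
        table = read_estimates_csv(write_estimates_file(tmp_path / "f.csv", rows))
        return harmonize(table, tiny_map, tiny_hierarchy).table

    def test_single_iteration_risk_excluded_with_reason(self, tmp_path, tiny_map,
                                                        tiny_hierarchy):
        rows = [
            estimate_row("Air pollution", 2019, 2019, 1.0),
            estimate_row("Air pollution", 2021, 2021, 2.0),
            estimate_row("Diet high in sodium", 2019, 2019, 3.0),
        ]
        table = self._table(tmp_path, tiny_map, tiny_hierarchy, rows)
        result = filter_analysis_set(table)
        assert result.table.risk_ids == ["air_pollution"]
        ledger = result.ledger.set_index("risk_id")
        assert ledger.loc["diet_sodium", "reason"] == "single-iteration"

    def test_level4_and_named_exclusions_applied(self, tmp_path, tiny_map,
                                                 tiny_hierarchy):
        rows = []
        for risk in ("Air pollution", "Occupational exposure to asbestos",
                     "Childhood sexual abuse"):
            rows += [estimate_row(risk, 2019, 2019, 1.0),
                     estimate_row(risk, 2021, 2021, 2.0)]
        table = self._table(tmp_path, tiny_map, tiny_hierarchy, rows)
        result = filter_analysis_set(table)
        assert result.table.risk_ids == ["air_pollution"]
        reasons = dict(zip(result.ledger["risk_id"], result.ledger["reason"]))
        assert reasons["occ_asbestos"] == "excluded-level"
        assert reasons["childhood_sexual_abuse"] == "named-exclusion"

    def test_retained_count_matches_enumeration(self, tmp_path, tiny_hierarchy):
        # 10 synthetic risks: 3 single-iteration, 2 on the named list -> 5 retained
        from revstab.estimates import RiskDescriptor, RiskGroup, RiskHierarchy

        descs = [RiskDescriptor("all_risks", "All", 0, None, RiskGroup.ALL_RISKS),
                 RiskDescriptor("behavioral", "Behavioral", 1, "all_risks",
                                RiskGroup.BEHAVIORAL)]
        names = [f"r{i}" for i in range(10)]
        descs += [RiskDescriptor(n, n.upper(), 2, "behavioral",
                                 RiskGroup.BEHAVIORAL) for n in names]
        hierarchy = RiskHierarchy(descs)
        hmap = HarmonizationMap([(n.upper(), None, n) for n in names], hierarchy)
        rows = []
        for i, n in enumerate(names):
            rows.append(estimate_row(n.upper(), 2019, 2019, 1.0 + i))
            if i >= 3:  # first three stay single-iteration
                rows.append(estimate_row(n.upper(), 2021, 2021, 2.0 + i))
        table = read_estimates_csv(write_estimates_file(tmp_path / "ten.csv", rows))
        harm = harmonize(table, hmap, hierarchy).table
        rules = FilterRules(exclude_risk_ids=("r3", "r4"))
        result = filter_analysis_set(harm, rules)
        assert len(result.table.risk_ids) == 5
        assert sorted(result.ledger["risk_id"]) == ["r0", "r1", "r2", "r3", "r4"]

    def test_no_rules_bite_leaves_table_unchanged(self, tmp_path, tiny_map,
                                                  tiny_hierarchy):
        rows = [
            estimate_row("Air pollution", 2019, 2019, 1.0),
            estimate_row("Air pollution", 2021, 2021, 2.0),
        ]
        table = self._table(tmp_path, tiny_map, tiny_hierarchy, rows)
        result = filter_analysis_set(table, FilterRules(exclude_risk_ids=()))
        assert len(result.table) == len(table)
        assert result.ledger.empty

    def test_record_conservation_against_ledger(self, tmp_path, tiny_map,
                                                tiny_hierarchy):
        rows = []
        for risk, iters in (("Air pollution", (2019, 2021)),
                            ("Diet high in sodium", (2019,)),
                            ("Occupational exposure to asbestos", (2019, 2021)),
                            ("Childhood sexual abuse", (2019, 2021, 2023))):
            rows += [estimate_row(risk, it, it, 1.0 + it) for it in iters]
        table = self._table(tmp_path, tiny_map, tiny_hierarchy, rows)
        result = filter_analysis_set(table)
        assert len(table) == len(result.table) + result.n_excluded_records
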