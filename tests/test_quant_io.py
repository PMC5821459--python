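import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_table
from silacrnp.errors import DesignError, DomainError, FormatError
from silacrnp.quant_io import (
    LabelDesign,
    condition_fraction,
    filter_groups,
    heavy_fraction,
    merge_swap_pair,
    ratio_from_fraction,
    read_protein_groups,
    write_protein_groups,
)

DESIGN = LabelDesign(heavy="BSA", light="RNase")
SWAPPED = LabelDesign(heavy="RNase", light="BSA")


class TestReadProteinGroups:
    def test_parses_rows_and_preserves_missing_ratio(self, tsv_writer):
        path = tsv_writer(
            [
                ("GENEA", "1.0", "5", "", ""),
                ("GENEB", "2.0", "3", "", ""),
                ("GENEC", "", "4", "", ""),
            ]
        )
        table = read_protein_groups(path, DESIGN)
        assert len(table) == 3
        assert table.df["ratio_hl"].tolist()[:2] == [1.0, 2.0]
        assert np.isnan(table.df["ratio_hl"].iloc[2])

    def test_missing_ratio_column_is_a_format_error(self, tsv_writer):
        path = tsv_writer(
            [("GENEA", "1.0", "5")],
            header=["Gene names", "Intensity", "Razor + unique peptides"],
        )
        with pytest.raises(FormatError, match="Ratio H/L"):
            read_protein_groups(path, DESIGN)

    def test_plus_convention_flags(self, tsv_writer):
        path = tsv_writer(
            [("KRT1", "1.5", "10", "+", ""), ("REV_X", "0.5", "2", "", "+")]
        )
        table = read_protein_groups(path, DESIGN)
        assert table.df["is_contaminant"].tolist() == [True, False]
        assert table.df["is_reverse"].tolist() == [False, True]

    def test_unparsable_ratio_names_row(self, tsv_writer):
        path = tsv_writer([("GENEA", "abc", "5", "", "")])
        with pytest.raises(FormatError, match="row 0"):
            read_protein_groups(path, DESIGN)

    def test_zero_and_infinite_ratios_become_missing(self, tsv_writer):
        path = tsv_writer(
            [("GENEA", "0", "5", "", ""), ("GENEB", "inf", "5", "", "")]
        )
        table = read_protein_groups(path, DESIGN)
        assert table.df["ratio_hl"].isna().all()

    def test_ambiguous_group_collapsed_to_first_symbol(self, tsv_writer):
        path = tsv_writer([("AAA;BBB;CCC", "1.0", "5", "", "")])
        table = read_protein_groups(path, DESIGN)
        assert table.df["gene_symbol"].iloc[0] == "AAA"
        assert table.df["group_members"].iloc[0] == "AAA;BBB;CCC"

    def test_duplicate_symbols_keep_most_peptides(self, tsv_writer):
        path = tsv_writer(
            [("GENEA", "1.0", "2", "", ""), ("GENEA", "3.0", "9", "", "")]
        )
        table = read_protein_groups(path, DESIGN)
        assert len(table) == 1
        assert table.df["ratio_hl"].iloc[0] == 3.0

    def test_round_trip_write_read(self, tmp_path, tsv_writer):
        path = tsv_writer(
            [("GENEA", "1.5", "5", "", ""), ("KRT1", "0.8", "3", "+", "")]
        )
        table = read_protein_groups(path, DESIGN)
        out = tmp_path / "rt.tsv"
        write_protein_groups(table, out)
        again = read_protein_groups(out, DESIGN)
        pd.testing.assert_frame_equal(table.df, again.df)


class TestFilterGroups:
    def _six_records(self):
        return make_table(
            [
                ("CONT1", 1.0, 5, True, False),
                ("REV1", 1.0, 5, False, True),
                ("ONEPEP", 1.0, 1, False, False),
                ("GOOD1", 1.0, 2, False, False),
                ("GOOD2", 2.0, 3, False, False),
                ("GOOD3", 0.5, 10, False, False),
            ]
        )

    def test_three_stated_rules(self):
        filtered, log = filter_groups(self._six_records())
        assert sorted(filtered.df["gene_symbol"]) == ["GOOD1", "GOOD2", "GOOD3"]
        assert log["contaminant"] == ["CONT1"]
        assert log["reverse"] == ["REV1"]
        assert log["low_peptides"] == ["ONEPEP"]

    def test_min_peptides_one_keeps_four(self):
        filtered, _ = filter_groups(self._six_records(), min_peptides=1)
        assert len(filtered) == 4

    def test_all_valid_is_identity(self):
        table = make_table([("A", 1.0, 2, False, False), ("B", 2.0, 3, False, False)])
        filtered, log = filter_groups(table)
        pd.testing.assert_frame_equal(filtered.df, table.df)
        assert all(not v for v in log.values())

    def test_missing_ratio_removed(self):
        table = make_table([("A", np.nan, 5, False, False), ("B", 1.0, 5, False, False)])
        filtered, log = filter_groups(table)
        assert filtered.df["gene_symbol"].tolist() == ["B"]
        assert log["missing_ratio"] == ["A"]

    def test_reasons_partition_removed_set(self):
        table = self._six_records()
        filtered, log = filter_groups(table)
        removed = [g for reason in log.values() for g in reason]
        assert len(removed) == len(set(removed)) == len(table) - len(filtered)


class TestHeavyFraction:
    @pytest.mark.parametrize("r,h", [(1.0, 0.5), (3.0, 0.75), (0.25, 0.2)])
    def test_examples(self, r, h):
        assert heavy_fraction(r) == pytest.approx(h)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(DomainError):
            heavy_fraction(-1.0)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=200, deadline=None)
    def test_bijection_round_trip(self, r):
        # relative error grows like r*eps as h -> 1, so the bound is checked
        # over the ratio range SILAC quantification actually produces
        assert ratio_from_fraction(heavy_fraction(r)) == pytest.approx(
            r, rel=1e-12, abs=1e-12 * max(1.0, r * r)
        )

    @given(st.floats(min_value=1e-6, max_value=1e6),
           st.floats(min_value=1e-6, max_value=1e6))
    @settings(max_examples=100, deadline=None)
    def test_strictly_increasing(self, r1, r2):
        if r1 < r2:
            assert heavy_fraction(r1) < heavy_fraction(r2)


class TestConditionFraction:
    def test_symmetric_ratio_either_orientation(self):
        assert condition_fraction(1.0, DESIGN, "BSA") == 0.5
        assert condition_fraction(1.0, SWAPPED, "BSA") == 0.5

    def test_heavy_vs_light_complement(self):
        assert condition_fraction(3.0, DESIGN, "BSA") == pytest.approx(0.75)
        assert condition_fraction(3.0, DESIGN, "RNase") == pytest.approx(0.25)

    @given(st.floats(min_value=1e-4, max_value=1e4))
    @settings(max_examples=100, deadline=None)
    def test_conditions_sum_to_one(self, r):
        total = condition_fraction(r, DESIGN, "BSA") + condition_fraction(
            r, DESIGN, "RNase"
        )
        assert total == pytest.approx(1.0, abs=1e-15)

    def test_unknown_condition_rejected(self):
        with pytest.raises(DesignError):
            condition_fraction(1.0, DESIGN, "elution")


class TestMergeSwapPair:
    def test_symmetric_protein_lands_at_half_half(self):
        t1 = make_table([("A", 1.0, 5, False, False)], design=DESIGN)
        t2 = make_table([("A", 1.0, 5, False, False)], design=SWAPPED)
        coords = merge_swap_pair(t1, t2, "BSA")
        assert coords.df.iloc[0][["x", "y"]].tolist() == [0.5, 0.5]

    def test_one_sided_protein_excluded_and_logged(self):
        t1 = make_table(
            [("A", 1.0, 5, False, False), ("B", 2.0, 5, False, False)], design=DESIGN
        )
        t2 = make_table([("A", 1.0, 5, False, False)], design=SWAPPED)
        coords = merge_swap_pair(t1, t2, "BSA")
        assert coords.df["protein"].tolist() == ["A"]
        assert coords.dropped["only_in_mixture1"] == ["B"]

    def test_intersection_size(self):
        shared = [(f"S{i}", 1.0, 5, False, False) for i in range(7)]
        only1 = [(f"X{i}", 1.0, 5, False, False) for i in range(3)]
        only2 = [(f"Y{i}", 1.0, 5, False, False) for i in range(3)]
        t1 = make_table(shared + only1, design=DESIGN)
        t2 = make_table(shared + only2, design=SWAPPED)
        assert len(merge_swap_pair(t1, t2, "BSA")) == 7

    def test_identical_designs_rejected(self):
        t1 = make_table([("A", 1.0, 5, False, False)], design=DESIGN)
        t2 = make_table([("A", 1.0, 5, False, False)], design=DESIGN)
        with pytest.raises(DesignError):
            merge_swap_pair(t1, t2, "BSA")

    def test_swap_orientation_resolved(self):
        # r=3 in both mixtures: BSA-heavy mixture gives x=0.75,
        # RNase-heavy mixture gives y=1-0.75=0.25
        t1 = make_table([("A", 3.0, 5, False, False)], design=DESIGN)
        t2 = make_table([("A", 3.0, 5, False, False)], design=SWAPPED)
        coords = merge_swap_pair(t1, t2, "BSA")
        assert coords.df.iloc[0]["x"] == pytest.approx(0.75)
        assert coords.df.iloc[0]["y"] == pytest.approx(0.25)
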