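import numpy as np
import pandas as pd
import pytest

from conftest import make_table
from silacrnp.errors import DomainError
from silacrnp.mutants import (
    MutantExperiment,
    double_histogram,
    relative_recovery,
    require_replicates,
    shift_normalize,
    shifted_fraction_matrix,
    significance_stars,
)
from silacrnp.mutants import test_en_vs_rt as en_vs_rt_test
from silacrnp.mutants import test_vs_wt as vs_wt_test
from silacrnp.quant_io import LabelDesign

WT_EN = LabelDesign(heavy="WT", light="EN")


def _series(d):
    return pd.Series(d, dtype=float)


class TestShiftNormalize:
    def test_simple_shift(self):
        shifted, _ = shift_normalize(_series({"ORF2": 0.62, "A": 0.70}), "ORF2")
        assert shifted["A"] == pytest.approx(0.58)

    def test_bait_maps_to_half(self):
        shifted, _ = shift_normalize(_series({"ORF2": 0.62, "A": 0.70}), "ORF2")
        assert shifted["ORF2"] == pytest.approx(0.5, abs=1e-15)

    def test_zero_shift_identity(self):
        vals = _series({"ORF2": 0.5, "A": 0.3, "B": 0.9})
        shifted, out = shift_normalize(vals, "ORF2")
        pd.testing.assert_series_equal(shifted, vals)
        assert out == []

    def test_out_of_range_logged_not_clipped(self):
        shifted, out = shift_normalize(_series({"ORF2": 0.9, "A": 0.05}), "ORF2")
        assert shifted["A"] == pytest.approx(-0.35)
        assert out == ["A"]

    def test_differences_preserved(self):
        rng = np.random.default_rng(0)
        vals = _series({f"P{i}": v for i, v in enumerate(rng.uniform(0.1, 0.9, 20))})
        vals["ORF2"] = 0.66
        shifted, _ = shift_normalize(vals, "ORF2")
        np.testing.assert_allclose(
            shifted.to_numpy() - shifted.to_numpy()[0],
            vals.to_numpy() - vals.to_numpy()[0],
            atol=1e-15,
        )

    def test_missing_bait(self):
        with pytest.raises(DomainError):
            shift_normalize(_series({"A": 0.5}), "ORF2")


class TestRelativeRecovery:
    def test_same_ratio_as_bait_gives_one(self):
        rec = relative_recovery(_series({"ORF2": 2.0, "A": 2.0}), "ORF2")
        assert rec["A"] == pytest.approx(1.0)

    def test_enriched_in_mutant(self):
        rec = relative_recovery(_series({"ORF2": 2.0, "A": 1.0}), "ORF2")
        assert rec["A"] == pytest.approx(2.0)

    def test_depleted_in_mutant(self):
        rec = relative_recovery(_series({"ORF2": 1.0, "A": 4.0}), "ORF2")
        assert rec["A"] == pytest.approx(0.25)

    def test_scale_invariance(self):
        vals = _series({"ORF2": 1.3, "A": 0.4, "B": 5.0})
        base = relative_recovery(vals, "ORF2")
        scaled = relative_recovery(vals * 7.3, "ORF2")
        pd.testing.assert_series_equal(base, scaled)


class TestRequireReplicates:
    def _tables(self):
        rows = lambda genes: [(g, 1.0, 5, False, False) for g in genes]
        return [
            make_table(rows(["ORF2", "A", "B"]), design=WT_EN),
            make_table(rows(["ORF2", "A"]), design=WT_EN),
            make_table(rows(["ORF2", "B"]), design=WT_EN),
        ]

    def test_min_two(self):
        assert require_replicates(self._tables()) == ["A", "B", "ORF2"]

    def test_protein_in_one_replicate_dropped(self):
        tables = self._tables()
        tables[0].df.loc[len(tables[0].df)] = ["C", 1.0, 5, False, False, "C"]
        assert "C" not in require_replicates(tables)

    def test_min_one_is_union(self):
        tables = self._tables()
        assert len(require_replicates(tables, min_n=1)) == 3


class TestTestVsWt:
    def test_single_protein_q_equals_p(self):
        shifted = pd.DataFrame(
            {"rep1": [0.55], "rep2": [0.60], "rep3": [0.65]}, index=["A"]
        )
        out = vs_wt_test(shifted)
        assert out["p"].iloc[0] == pytest.approx(0.0741799, abs=1e-6)
        assert out["q"].iloc[0] == pytest.approx(out["p"].iloc[0])

    def test_degenerate_protein_flagged_and_outside_family(self):
        shifted = pd.DataFrame(
            {"rep1": [0.5, 0.55], "rep2": [0.5, 0.60], "rep3": [0.5, 0.65]},
            index=["FLAT", "A"],
        )
        out = vs_wt_test(shifted).set_index("protein")
        assert out.loc["FLAT", "degenerate"]
        assert np.isnan(out.loc["FLAT", "q"])
        assert out.loc["A", "q"] == pytest.approx(0.0741799, abs=1e-6)

    def test_null_fdr_control(self):
        rng = np.random.default_rng(8)
        shifted = pd.DataFrame(
            rng.normal(0.5, 0.05, (500, 3)),
            index=[f"P{i}" for i in range(500)],
            columns=["rep1", "rep2", "rep3"],
        )
        out = vs_wt_test(shifted)
        assert (out["q"] < 0.05).mean() <= 0.05


class TestEnVsRt:
    def test_identical_values_p_one(self):
        en = pd.DataFrame({"r1": [0.4], "r2": [0.5]}, index=["A"])
        out = en_vs_rt_test(en, en.copy())
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_separated_classes_significant(self):
        en = pd.DataFrame({"r1": [0.20], "r2": [0.21], "r3": [0.19]}, index=["A"])
        rt = pd.DataFrame({"r1": [0.80], "r2": [0.81], "r3": [0.79]}, index=["A"])
        assert en_vs_rt_test(en, rt)["q"].iloc[0] < 0.01

    def test_protein_in_one_experiment_excluded(self):
        en = pd.DataFrame({"r1": [0.4, 0.3], "r2": [0.5, 0.2]}, index=["A", "ONLY_EN"])
        rt = pd.DataFrame({"r1": [0.4], "r2": [0.5]}, index=["A"])
        assert en_vs_rt_test(en, rt)["protein"].tolist() == ["A"]


class TestDoubleHistogram:
    def test_all_equal_single_bin(self):
        vals = pd.Series([3.0] * 5, index=list("abcde"))
        hist = double_histogram(vals, vals)
        assert (hist["counts_en"] > 0).sum() == 1
        assert hist["counts_en"].max() == 5

    def test_crossing_protein_counted(self):
        en = pd.Series({"A": 0.4})
        rt = pd.Series({"A": 3.0})
        assert double_histogram(en, rt)["crisscross"] == 1

    def test_hand_binning(self):
        vals = [0.5, 1.5, 2.5, 3.0, 4.1, 5.9, 6.0, 7.7, 8.2, 9.9]
        s = pd.Series(vals, index=[f"P{i}" for i in range(10)])
        hist = double_histogram(s, s, bin_width=2.0)
        np.testing.assert_array_equal(hist["counts_en"][:5], [2, 2, 2, 2, 2])

    def test_identical_bins_for_both(self):
        en = pd.Series({"A": 0.1, "B": 9.0})
        rt = pd.Series({"A": 4.0, "B": 2.0})
        hist = double_histogram(en, rt)
        assert hist["counts_en"].sum() == hist["counts_rt"].sum() == 2


class TestEndToEndClassRecovery:
    def test_planted_sign_pattern_recovered(self):
        # cytoplasmic down in EN / up in RT, nuclear the reverse
        from silacrnp.synthetic import (
            CYTOPLASMIC_MODULE,
            NUCLEAR_MODULE,
            SyntheticDesign,
            simulate_mutant_experiment,
        )
        from silacrnp.quant_io import filter_groups

        design = SyntheticDesign(seed=123, n_background=50,
                                 mutant_delta=0.15, mutant_sigma=0.05)
        means = {}
        for mutant in ("EN", "RT"):
            reps, _ = simulate_mutant_experiment(design, mutant, n_replicates=3)
            exp = MutantExperiment(
                mutant, [filter_groups(r)[0] for r in reps], bait="ORF2"
            )
            means[mutant] = shifted_fraction_matrix(exp).mean(axis=1)
        planted = [p for p in CYTOPLASMIC_MODULE if p != "ORF2"] + list(NUCLEAR_MODULE)
        correct = 0
        for p in planted:
            en_sign = np.sign(means["EN"][p] - 0.5)
            rt_sign = np.sign(means["RT"][p] - 0.5)
            expected = (-1, 1) if p in CYTOPLASMIC_MODULE else (1, -1)
            correct += (en_sign, rt_sign) == expected
        assert correct / len(planted) >= 0.90


def test_significance_stars_convention():
    assert significance_stars(0.005) == "**"
    assert significance_stars(0.03) == "*"
    assert significance_stars(0.2) == ""
    assert significance_stars(float("nan")) == ""
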