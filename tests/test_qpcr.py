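import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from trpquant.qpcr import (
    QpcrError,
    categorize,
    expression_matrix,
    fold_change_vs_baseline,
    percent_of_trpm7,
    relative_expression,
    strain_contrast,
)
from trpquant.synthetic import simulate_ct_table


def make_ct(rows):
    return pd.DataFrame(rows, columns=["sample_id", "condition", "gene", "replicate", "ct"])


def sample_rows(genes_ct: dict, sample="S1", condition="E14.5", reps=1):
    return [(sample, condition, g, r, ct) for g, ct in genes_ct.items() for r in range(1, reps + 1)]


class TestRelativeExpression:
    def test_geometric_mean_hand_example(self):
        """Housekeepers at Ct 20 and 24.2 have geometric mean 22.0 exactly."""
        ct = make_ct(sample_rows({"Actb": 20.0, "Gapdh": 24.2, "Trpv2": 25.0}))
        res = relative_expression(ct, ["Actb", "Gapdh"]).set_index("gene")
        assert res.loc["Trpv2", "hk_geometric_mean_ct"] == pytest.approx(22.0)
        assert res.loc["Trpv2", "delta_ct"] == pytest.approx(3.0)
        assert res.loc["Trpv2", "rel_expression"] == pytest.approx(0.125)

    def test_one_cycle_doubling_law(self):
        ct = make_ct(sample_rows({"Actb": 20.0, "Gapdh": 20.0, "geneA": 20.0, "geneB": 21.0}))
        res = relative_expression(ct, ["Actb", "Gapdh"]).set_index("gene")
        assert res.loc["geneA", "rel_expression"] == pytest.approx(1.0)
        assert res.loc["geneB", "rel_expression"] == pytest.approx(0.5)

    def test_replicates_averaged_before_delta_ct(self):
        rows = [("S1", "E14.5", "Actb", r, ct) for r, ct in enumerate([19.9, 20.0, 20.1], 1)]
        rows += [("S1", "E14.5", "geneA", r, ct) for r, ct in enumerate([20.5, 21.0, 21.5], 1)]
        res = relative_expression(make_ct(rows), ["Actb"]).set_index("gene")
        assert res.loc["geneA", "delta_ct"] == pytest.approx(1.0)

    def test_detection_floor_yields_not_detected(self):
        ct = make_ct(sample_rows({"Actb": 20.0, "geneA": 41.0}))
        res = relative_expression(ct, ["Actb"]).set_index("gene")
        assert not res.loc["geneA", "detected"]
        assert np.isnan(res.loc["geneA", "rel_expression"])

    def test_missing_housekeeping_is_sample_error(self):
        ct = make_ct(sample_rows({"Actb": 20.0, "geneA": 25.0}))
        with pytest.raises(QpcrError, match="Gapdh"):
            relative_expression(ct, ["Actb", "Gapdh"])

    @settings(derandomize=True, max_examples=50)
    @given(shift=st.floats(-5.0, 5.0))
    def test_nearly_invariant_to_global_ct_shift(self, shift):
        """2^-dCt depends (almost) only on Ct differences within a sample.

        The geometric mean of the housekeeping Cts is not exactly
        translation-equivariant, so a global Ct shift perturbs dCt by a
        small curvature term (< 0.01 cycles for housekeepers 2 cycles
        apart and shifts of a few cycles); exact invariance holds when the
        housekeepers agree.
        """
        base = {"Actb": 20.0, "Gapdh": 22.0, "geneA": 27.0}
        res0 = relative_expression(make_ct(sample_rows(base)), ["Actb", "Gapdh"])
        shifted = {g: c + shift for g, c in base.items()}
        res1 = relative_expression(make_ct(sample_rows(shifted)), ["Actb", "Gapdh"])
        r0 = res0.set_index("gene").loc["geneA", "rel_expression"]
        r1 = res1.set_index("gene").loc["geneA", "rel_expression"]
        assert r1 == pytest.approx(r0, rel=1e-2)

    @settings(derandomize=True, max_examples=50)
    @given(shift=st.floats(-5.0, 5.0))
    def test_exactly_invariant_to_shift_with_agreeing_housekeepers(self, shift):
        base = {"Actb": 21.0, "Gapdh": 21.0, "geneA": 27.0}
        res0 = relative_expression(make_ct(sample_rows(base)), ["Actb", "Gapdh"])
        shifted = {g: c + shift for g, c in base.items()}
        res1 = relative_expression(make_ct(sample_rows(shifted)), ["Actb", "Gapdh"])
        r0 = res0.set_index("gene").loc["geneA", "rel_expression"]
        r1 = res1.set_index("gene").loc["geneA", "rel_expression"]
        assert r1 == pytest.approx(r0, rel=1e-9)


class TestPercentOfReference:
    def test_reference_gene_sits_at_100_percent(self):
        table = simulate_ct_table({"geneA": 0.25}, ct_noise_sd=0.0)
        res = percent_of_trpm7(relative_expression(table, ["Actb", "Gapdh"])).set_index("gene")
        assert res.loc["Trpm7", "percent_of_trpm7"] == pytest.approx(100.0)
        assert res.loc["geneA", "percent_of_trpm7"] == pytest.approx(25.0)

    def test_one_cycle_above_reference_is_50_percent(self):
        table = simulate_ct_table({"geneA": 0.5}, ct_noise_sd=0.0)
        res = percent_of_trpm7(relative_expression(table, ["Actb", "Gapdh"])).set_index("gene")
        assert res.loc["geneA", "percent_of_trpm7"] == pytest.approx(50.0, rel=1e-12)

    def test_round_trip_recovers_requested_fractions_exactly(self):
        fractions = {"a": 1.5, "b": 0.5, "c": 0.03, "d": 0.005}
        table = simulate_ct_table(fractions, ct_noise_sd=0.0)
        res = percent_of_trpm7(relative_expression(table, ["Actb", "Gapdh"])).set_index("gene")
        for gene, frac in fractions.items():
            assert res.loc[gene, "percent_of_trpm7"] == pytest.approx(100 * frac, rel=1e-12)

    def test_empty_scope_rejected(self):
        table = simulate_ct_table({"geneA": 0.5})
        res = relative_expression(table, ["Actb", "Gapdh"])
        with pytest.raises(QpcrError, match="scope"):
            percent_of_trpm7(res, reference_scope=[])


class TestCategorization:
    @pytest.mark.parametrize("percent, expected", [
        (150.0, "high"),            # above the reference channel
        (100.0, "moderate"),        # band edge: 5-100% inclusive
        (50.0, "moderate"),
        (5.0, "moderate"),
        (4.999, "low"),             # 1-5%, lower edge inclusive
        (1.0, "low"),
        (0.5, "below_detection"),   # < 1%
        (0.0, "below_detection"),
        (float("nan"), "not_detected"),
    ])
    def test_band_assignment(self, percent, expected):
        assert categorize(percent) == expected

    def test_negative_percent_rejected(self):
        with pytest.raises(QpcrError):
            categorize(-1.0)

    @settings(derandomize=True, max_examples=100)
    @given(a=st.floats(0.0, 500.0), b=st.floats(0.0, 500.0))
    def test_monotone_step_function(self, a, b):
        order = ["below_detection", "low", "moderate", "high"]
        lo, hi = sorted([a, b])
        assert order.index(categorize(lo)) <= order.index(categorize(hi))


class TestFoldChange:
    def _two_condition_results(self, delta_shift):
        rows = sample_rows({"Actb": 20.0, "Gapdh": 20.0, "geneA": 25.0}, sample="S1", condition="E10.5")
        rows += sample_rows({"Actb": 20.0, "Gapdh": 20.0, "geneA": 25.0 - delta_shift},
                            sample="S2", condition="E18.5")
        return relative_expression(make_ct(rows), ["Actb", "Gapdh"])

    def test_baseline_condition_yields_fold_one(self):
        out = fold_change_vs_baseline(self._two_condition_results(1.0), "E10.5")
        base = out.loc[(out["gene"] == "geneA") & (out["condition"] == "E10.5")]
        assert base["fold_change_vs_baseline"].iloc[0] == pytest.approx(1.0)

    def test_tenfold_law(self):
        """A 3.32193-cycle dCt decrease corresponds to a 10-fold increase."""
        out = fold_change_vs_baseline(self._two_condition_results(3.32193), "E10.5")
        fold = out.loc[(out["gene"] == "geneA") & (out["condition"] == "E18.5"),
                       "fold_change_vs_baseline"].iloc[0]
        assert fold == pytest.approx(10.0, abs=1e-3)

    def test_fifty_fold_design_recovered_at_zero_noise(self):
        t0 = simulate_ct_table({"geneA": 0.01}, ct_noise_sd=0.0, sample_id="S1", condition="E10.5")
        t1 = simulate_ct_table({"geneA": 0.5}, ct_noise_sd=0.0, sample_id="S2", condition="E18.5")
        res = relative_expression(pd.concat([t0, t1]), ["Actb", "Gapdh"])
        out = fold_change_vs_baseline(res, "E10.5")
        fold = out.loc[(out["gene"] == "geneA") & (out["condition"] == "E18.5"),
                       "fold_change_vs_baseline"].iloc[0]
        assert fold == pytest.approx(50.0, rel=1e-12)

    def test_missing_baseline_condition_rejected(self):
        with pytest.raises(QpcrError, match="baseline"):
            fold_change_vs_baseline(self._two_condition_results(1.0), "E99")


class TestStrainContrast:
    def _results(self, b6_ct, cd1_ct):
        rows = []
        for strain, gene_ct in [("B6", b6_ct), ("CD1", cd1_ct)]:
            for cond, ct in gene_ct.items():
                rows += [(f"{strain}_{cond}", cond, "Actb", 1, 20.0),
                         (f"{strain}_{cond}", cond, "Trpm4", 1, ct)]
        res = relative_expression(make_ct(rows), ["Actb"])
        res["strain"] = [s.split("_")[0] for s in res["sample_id"]]
        return res

    def test_identical_strains_zero_difference(self):
        res = self._results({"E12.5": 25.0, "E14.5": 26.0}, {"E12.5": 25.0, "E14.5": 26.0})
        out = strain_contrast(res, strain_a="B6", strain_b="CD1").set_index("gene")
        assert out.loc["Trpm4", "mean_percent_difference"] == pytest.approx(0.0)

    def test_uniform_twofold_is_plus_100_percent(self):
        res = self._results({"E12.5": 24.0, "E14.5": 25.0}, {"E12.5": 25.0, "E14.5": 26.0})
        out = strain_contrast(res, strain_a="B6", strain_b="CD1").set_index("gene")
        assert out.loc["Trpm4", "mean_percent_difference"] == pytest.approx(100.0)
        assert out.loc["Trpm4", "sem_percent_difference"] == pytest.approx(0.0)

    def test_minus_33_percent_design_recovered(self):
        # B6 expresses 2/3 of CD1: dCt higher by log2(1.5)
        res = self._results({"E12.5": 25.0 + np.log2(1.5)}, {"E12.5": 25.0})
        out = strain_contrast(res, strain_a="B6", strain_b="CD1").set_index("gene")
        assert out.loc["Trpm4", "mean_percent_difference"] == pytest.approx(-100.0 / 3.0, rel=1e-9)

    def test_no_shared_conditions_rejected(self):
        res = self._results({"E12.5": 25.0}, {"E14.5": 25.0})
        with pytest.raises(QpcrError, match="share"):
            strain_contrast(res, strain_a="B6", strain_b="CD1")


def test_expression_matrix_shape():
    t0 = simulate_ct_table({"geneA": 0.5, "geneB": 0.05}, condition="E10.5", sample_id="S1")
    t1 = simulate_ct_table({"geneA": 0.25, "geneB": 0.05}, condition="E18.5", sample_id="S2")
    res = percent_of_trpm7(relative_expression(pd.concat([t0, t1]), ["Actb", "Gapdh"]))
    mat = expression_matrix(res)
    assert set(mat.columns) == {"E10.5", "E18.5"}
    assert mat.loc["geneA", "E10.5"] == pytest.approx(50.0)
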