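import math

import numpy as np
import pandas as pd
import pytest

from splicequant import (
    DropletWell,
    SaturationError,
    SpliceForm,
    SpliceFormCountTable,
    concordance,
    control_normalize,
    ddpcr_concentration,
    ddpcr_normalized_expression,
    group_fold_change,
    harmonize_odds_ratios,
    pool_normalize,
    simulate_droplets,
)
from splicequant.quantify import NormalizedExpression


def table(per_sample):
    return SpliceFormCountTable.from_counts(per_sample)


class TestPoolNormalize:
    def test_uniform_pool(self):
        counts = table({"a": {"0-0": 60, "GUSB": 40}, "b": {"0-0": 30, "GUSB": 70}})
        out = pool_normalize(counts, {"a": "p1", "b": "p1"})
        # both totals 100 -> divisor 100
        assert out.df.set_index(["sample_id", "species"])["normalized_count"][
            ("a", "0-0")
        ] == pytest.approx(0.6)

    def test_mean_divisor(self):
        counts = table({"a": {"0-0": 100}, "b": {"0-0": 300}})
        out = pool_normalize(counts, {"a": "p1", "b": "p1"})
        vals = out.df.set_index("sample_id")["normalized_count"]
        assert vals["a"] == pytest.approx(100 / 200)
        assert vals["b"] == pytest.approx(300 / 200)

    def test_normalized_totals_sum_to_pool_size(self):
        counts = table(
            {
                "a": {"0-0": 120, "M-0": 30},
                "b": {"0-0": 50, "M-0": 10},
                "c": {"0-0": 500, "M-0": 100},
            }
        )
        out = pool_normalize(counts, {"a": "p1", "b": "p1", "c": "p2"})
        sums = out.df.groupby("sample_id")["normalized_count"].sum()
        assert sums["a"] + sums["b"] == pytest.approx(2.0)
        assert sums["c"] == pytest.approx(1.0)

    def test_missing_pool_assignment_is_error(self):
        counts = table({"a": {"0-0": 1}})
        with pytest.raises(ValueError, match="pool"):
            pool_normalize(counts, {})

    def test_zero_read_pool_is_error(self):
        counts = table({"a": {"0-0": 0}})
        with pytest.raises(ValueError, match="zero"):
            pool_normalize(counts, {"a": "p1"})


class TestControlNormalize:
    def test_simple_ratio(self):
        counts = table({"a": {"0-0": 50, "GUSB": 100}})
        expr = {e.target: e for e in control_normalize(counts)}
        assert expr["0-0"].value == pytest.approx(0.5)
        assert expr["0-0"].log2_value == pytest.approx(-1.0)

    def test_volume_fraction_rescaling(self):
        # control observed at 10% volume: 10 observed -> 100 effective
        counts = table({"a": {"0-0": 50, "GUSB": 10}})
        expr = {e.target: e
                for e in control_normalize(counts, control_volume_fraction=0.10)}
        assert expr["0-0"].value == pytest.approx(0.5)

    def test_zero_control_flagged_not_zero(self):
        counts = table({"a": {"0-0": 50, "GUSB": 0}})
        expr = control_normalize(counts)
        zero_ctrl = [e for e in expr if e.target == "0-0"][0]
        assert zero_ctrl.value is None
        assert zero_ctrl.flag == "undefined_control"

    def test_invariant_to_sample_scaling(self):
        a = table({"a": {"0-0": 50, "M-0": 20, "GUSB": 100}})
        b = table({"a": {"0-0": 500, "M-0": 200, "GUSB": 1000}})
        va = {e.target: e.value for e in control_normalize(a)}
        vb = {e.target: e.value for e in control_normalize(b)}
        assert va == pytest.approx(vb)


class TestDdpcr:
    def test_zero_positives_below_lod(self):
        est = ddpcr_concentration(DropletWell("w", "FAM", 0, 20000))
        assert est.concentration == 0.0
        assert est.below_lod

    def test_saturation_rejected(self):
        with pytest.raises(SaturationError):
            ddpcr_concentration(DropletWell("w", "FAM", 100, 100))

    def test_known_lambda(self):
        # negative fraction e^-1 => lambda = 1
        n = 20000
        n_neg = round(n * math.exp(-1))
        est = ddpcr_concentration(DropletWell("w", "FAM", n - n_neg, n))
        assert est.lam == pytest.approx(1.0, abs=3 * math.sqrt((math.e - 1) / n))
        assert est.concentration == pytest.approx(est.lam / 0.85e-3)

    def test_strictly_monotone_in_positives(self):
        concs = [
            ddpcr_concentration(DropletWell("w", "FAM", k, 1000)).concentration
            for k in range(0, 1000, 50)
        ]
        assert all(b > a for a, b in zip(concs, concs[1:]))

    @pytest.mark.parametrize("lam", [0.1, 1.0, 3.0])
    def test_simulation_recovery(self, lam):
        vol = 0.85
        conc = lam / (vol * 1e-3)
        n = 20000
        well = simulate_droplets(conc, vol, n, seed=int(lam * 10))
        est = ddpcr_concentration(well)
        se = math.sqrt((math.exp(lam) - 1) / n)
        assert est.lam == pytest.approx(lam, abs=3 * se)

    def test_dilution_scales_concentration(self):
        well = DropletWell("w", "FAM", 5000, 20000)
        a = ddpcr_concentration(well, reaction_dilution=1.0)
        b = ddpcr_concentration(well, reaction_dilution=10.0)
        assert b.concentration == pytest.approx(10 * a.concentration)


class TestDdpcrExpression:
    def test_identical_wells_ratio_one(self):
        w = DropletWell("w", "FAM", 5000, 20000)
        c = DropletWell("w", "VIC", 5000, 20000)
        expr = ddpcr_normalized_expression(w, c, sample_id="s")
        assert expr.value == pytest.approx(1.0)
        assert expr.log2_value == pytest.approx(0.0)

    def test_double_lambda_small_regime(self):
        n = 200000
        target = simulate_droplets(0.02 / 0.85e-3, 0.85, n, seed=1)
        control = simulate_droplets(0.01 / 0.85e-3, 0.85, n, seed=2)
        expr = ddpcr_normalized_expression(target, control)
        assert expr.value == pytest.approx(2.0, rel=0.1)

    def test_control_saturated_flagged(self):
        target = DropletWell("w", "FAM", 5000, 20000)
        control = DropletWell("w", "VIC", 20000, 20000)
        expr = ddpcr_normalized_expression(target, control)
        assert expr.value is None
        assert expr.flag == "control_saturated"

    def test_control_below_lod_flagged(self):
        target = DropletWell("w", "FAM", 5000, 20000)
        control = DropletWell("w", "VIC", 0, 20000)
        expr = ddpcr_normalized_expression(target, control)
        assert expr.value is None
        assert expr.flag == "control_below_lod"


def expr_list(values, target="M-L"):
    return [
        NormalizedExpression(sample_id=f"s{i}", target=target, value=v)
        for i, v in enumerate(values)
    ]


class TestFoldChange:
    def grouping(self, n_a, n_b):
        g = {f"s{i}": "A" for i in range(n_a)}
        g.update({f"s{i + len(g)}": "B" for i in range(n_b)})
        return g

    def test_identical_groups(self):
        expr = expr_list([2.0, 2.0, 2.0, 2.0])
        g = self.grouping(2, 2)
        assert group_fold_change(expr, g) == pytest.approx(1.0)

    def test_doubling(self):
        expr = expr_list([1.0, 3.0, 2.0, 6.0])
        g = self.grouping(2, 2)
        assert group_fold_change(expr, g, "geometric") == pytest.approx(2.0)
        assert group_fold_change(expr, g, "arithmetic") == pytest.approx(2.0)

    def test_hand_computed_example(self):
        expr = expr_list([1.0, 4.0, 2.0, 8.0])
        g = self.grouping(2, 2)
        assert group_fold_change(expr, g, "geometric") == pytest.approx(2.0)
        assert group_fold_change(expr, g, "arithmetic") == pytest.approx(2.0)

    def test_geometric_reciprocal_exact(self):
        expr = expr_list([1.3, 0.7, 2.9, 5.1, 0.2])
        g = {"s0": "A", "s1": "A", "s2": "B", "s3": "B", "s4": "B"}
        ab = group_fold_change(expr, g)
        swapped = {s: ("B" if lab == "A" else "A") for s, lab in g.items()}
        ba = group_fold_change(expr, swapped)
        assert ab * ba == pytest.approx(1.0, rel=1e-12)

    def test_empty_group_is_error(self):
        expr = expr_list([1.0, 2.0])
        with pytest.raises(ValueError, match="group"):
            group_fold_change(expr, {"s0": "A", "s1": "A"})

    def test_nonpositive_value_geometric_error(self):
        expr = expr_list([0.0, 2.0])
        with pytest.raises(ValueError, match="s0"):
            group_fold_change(expr, self.grouping(1, 1))


class TestConcordance:
    def test_perfect(self):
        rho, n = concordance([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)
        assert n == 4

    def test_reversed(self):
        rho, _ = concordance([1, 2, 3, 4], [4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        rho, _ = concordance([1, 2, 3, 4], [1, 3, 2, 4])
        assert rho == pytest.approx(0.8)

    def test_listwise_nan_drop(self):
        rho, n = concordance([1, 2, np.nan, 4, 5], [1, 2, 3, np.nan, 5])
        assert n == 3
        assert rho == pytest.approx(1.0)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match="3"):
            concordance([1, 2], [1, 2])


class TestHarmonizeOddsRatios:
    def test_single_study_flip(self):
        df = pd.DataFrame(
            [{"locus": "L1", "study": "pgc1", "tested_allele": "A",
              "other_allele": "G", "odds_ratio": 0.8}]
        )
        out = harmonize_odds_ratios(df)
        row = out.iloc[0]
        assert row.odds_ratio == pytest.approx(1.25)
        assert row.tested_allele == "G"
        assert row.other_allele == "A"

    def test_aligned_studies_unchanged(self):
        df = pd.DataFrame(
            [
                {"locus": "L1", "study": s, "tested_allele": "A",
                 "other_allele": "G", "odds_ratio": orr}
                for s, orr in [("pgc1", 1.10), ("pgc2", 1.12), ("pgc3", 1.14)]
            ]
        )
        out = harmonize_odds_ratios(df)
        assert list(out["odds_ratio"]) == [1.10, 1.12, 1.14]
        assert out["median_or"].iloc[0] == pytest.approx(1.12)

    def test_sorted_by_descending_median(self):
        rows = []
        for locus, orr in [("La", 1.05), ("Lb", 1.11), ("Lc", 1.08)]:
            rows.append({"locus": locus, "study": "pgc3", "tested_allele": "A",
                         "other_allele": "G", "odds_ratio": orr})
        out = harmonize_odds_ratios(pd.DataFrame(rows))
        assert list(out["locus"]) == ["Lb", "Lc", "La"]

    def test_opposite_allele_study_flipped(self):
        df = pd.DataFrame(
            [
                {"locus": "L1", "study": "pgc1", "tested_allele": "G",
                 "other_allele": "A", "odds_ratio": 0.9},
                {"locus": "L1", "study": "pgc3", "tested_allele": "A",
                 "other_allele": "G", "odds_ratio": 1.2},
            ]
        )
        out = harmonize_odds_ratios(df, study_order=["pgc1", "pgc3"])
        by_study = out.set_index("study")
        assert by_study.loc["pgc1", "odds_ratio"] == pytest.approx(1 / 0.9)
        assert by_study.loc["pgc1", "tested_allele"] == "A"
        assert (out["odds_ratio"] >= 1).all()

    def test_idempotent(self):
        df = pd.DataFrame(
            [
                {"locus": "L1", "study": "pgc1", "tested_allele": "G",
                 "other_allele": "A", "odds_ratio": 0.9},
                {"locus": "L1", "study": "pgc3", "tested_allele": "A",
                 "other_allele": "G", "odds_ratio": 1.2},
                {"locus": "L2", "study": "pgc1", "tested_allele": "C",
                 "other_allele": "T", "odds_ratio": 1.3},
                {"locus": "L2", "study": "pgc3", "tested_allele": "C",
                 "other_allele": "T", "odds_ratio": 0.95},
            ]
        )
        once = harmonize_odds_ratios(df)
        twice = harmonize_odds_ratios(once.drop(columns=["median_or"]))
        pd.testing.assert_frame_equal(once, twice)

    def test_irreconcilable_locus_excluded(self):
        df = pd.DataFrame(
            [
                {"locus": "L1", "study": "pgc1", "tested_allele": "C",
                 "other_allele": "T", "odds_ratio": 1.1},
                {"locus": "L1", "study": "pgc3", "tested_allele": "A",
                 "other_allele": "G", "odds_ratio": 1.2},
            ]
        )
        out = harmonize_odds_ratios(df)
        assert out.empty
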