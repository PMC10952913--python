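import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from decaylab import (AbundanceMatrix, SimulationConfig, attenuation_percent,
                      category_rpl_shift, compute_rpl, correlate_fold_changes,
                      fold_changes, generate_truth, quadrant_classify,
                      rpl_fold_changes, rrgd_classify,
                      simulate_polysome_course, to_abundance)
from decaylab.translation_rpl import ranksum_test


def paired_matrices(total, poly, conditions=None, timepoints=None):
    total = np.atleast_2d(np.asarray(total, float))
    poly = np.atleast_2d(np.asarray(poly, float))
    n_samples = total.shape[1]
    samples_t = [f"t{i}" for i in range(n_samples)]
    samples_p = [f"p{i}" for i in range(n_samples)]
    def sheet(samples):
        return pd.DataFrame({
            "condition": conditions or ["HL"] * n_samples,
            "treatment": "mock",
            "timepoint_min": timepoints or [30.0] * n_samples,
            "batch": 1, "replicate": range(1, n_samples + 1),
        }, index=pd.Index(samples, name="sample_id"))
    at = AbundanceMatrix(pd.DataFrame(total, columns=samples_t), "RPKM")
    ap = AbundanceMatrix(pd.DataFrame(poly, columns=samples_p), "RPKM")
    return at, ap, sheet(samples_t), sheet(samples_p)


class TestComputeRPL:
    def test_simple_ratio(self):
        at, ap, st_, sp = paired_matrices([[10.0]], [[20.0]])
        rpl = compute_rpl(at, ap, st_, sp)
        assert rpl["rpl"].iloc[0] == pytest.approx(2.0)

    def test_equal_matrices_give_unity(self):
        vals = np.random.default_rng(0).uniform(1, 100, (5, 3))
        at, ap, st_, sp = paired_matrices(vals, vals,
                                          timepoints=[0.0, 30.0, 60.0])
        rpl = compute_rpl(at, ap, st_, sp)
        assert np.allclose(rpl["rpl"], 1.0)

    def test_zero_total_omitted_for_that_replicate(self):
        at, ap, st_, sp = paired_matrices([[0.0, 5.0]], [[3.0, 10.0]],
                                          timepoints=[30.0, 60.0])
        rpl = compute_rpl(at, ap, st_, sp)
        assert len(rpl) == 1 and rpl["timepoint_min"].iloc[0] == 60.0

    def test_unpairable_samples_listed_in_error(self):
        at, ap, st_, sp = paired_matrices([[1.0, 2.0]], [[1.0, 2.0]],
                                          timepoints=[30.0, 60.0])
        sp = sp.iloc[:1]
        with pytest.raises(ValueError, match="unpairable"):
            compute_rpl(at, ap, st_, sp)

    def test_simulation_recovery(self):
        """Replicate-mean RPL tracks the generator's true RPL within 10%
        at low dispersion."""
        cfg = SimulationConfig(n_genes=200, seed=21, nb_dispersion=0.01,
                               batch_sd=0.0, n_replicates=4)
        truth = generate_truth(cfg)
        total, poly = simulate_polysome_course(truth, cfg)
        rpl = compute_rpl(to_abundance(total, "CPM"), to_abundance(poly, "CPM"),
                          total.sample_sheet, poly.sample_sheet)
        late = rpl[(rpl["condition"] == "HL") & (rpl["timepoint_min"] == 60.0)]
        est = late.groupby("gene_id")["rpl"].mean()
        true = truth.rpl[("HL", 60.0)].loc[est.index]
        rel = np.abs(est / true - 1.0)
        assert np.median(rel) < 0.10


class TestQuadrantClassify:
    def test_all_unchanged(self):
        fc = pd.Series(1.0, index=[f"g{i}" for i in range(10)])
        q = quadrant_classify(fc, fc)
        assert q.proportions.loc["unchanged", "unchanged"] == 1.0
        assert q.frac_changed_total == 0.0

    def test_hand_built_grid_proportions(self):
        """20 genes with hand-set fold changes land in enumerated cells."""
        genes = [f"g{i}" for i in range(20)]
        fc_total = pd.Series([2.0] * 4 + [1.0] * 12 + [0.5] * 4, index=genes)
        fc_rpl = pd.Series([2.0] * 2 + [1.0] * 16 + [0.5] * 2, index=genes)
        q = quadrant_classify(fc_total, fc_rpl, threshold=1.5)
        assert q.proportions.loc["up", "up"] == pytest.approx(2 / 20)
        assert q.proportions.loc["up", "unchanged"] == pytest.approx(2 / 20)
        assert q.proportions.loc["unchanged", "unchanged"] == pytest.approx(12 / 20)
        assert q.proportions.loc["down", "down"] == pytest.approx(2 / 20)
        assert q.proportions.loc["down", "unchanged"] == pytest.approx(2 / 20)
        assert q.frac_changed_total == pytest.approx(8 / 20)
        assert q.frac_changed_rpl == pytest.approx(4 / 20)

    def test_marginals_consistent_with_grid(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(500)]
        fc_t = pd.Series(np.exp(rng.normal(0, 0.5, 500)), index=genes)
        fc_r = pd.Series(np.exp(rng.normal(0, 0.5, 500)), index=genes)
        q = quadrant_classify(fc_t, fc_r)
        assert q.proportions.to_numpy().sum() == pytest.approx(1.0)
        changed_rpl = q.proportions[["up", "down"]].to_numpy().sum()
        assert q.frac_changed_rpl == pytest.approx(changed_rpl)


class TestRRGDClassify:
    def build_series(self, profiles):
        cols = pd.MultiIndex.from_tuples(
            [("HL", 0.0), ("HL", 30.0), ("HL", 60.0), ("REC", 30.0)],
            names=["condition", "timepoint_min"])
        return pd.DataFrame(profiles, columns=cols,
                            index=[f"g{i}" for i in range(len(profiles))])

    @pytest.mark.parametrize("profile,expected", [
        ((1, 5, 5, 5), "cat1"),   # stays up through HL and REC
        ((1, 5, 5, 1), "cat2"),   # declines only during recovery
        ((1, 5, 2, 1), "cat3"),   # declines after 30 min HL
        ((1, 2, 2, 2), "none"),   # induced < 3-fold
    ])
    def test_category_rules(self, profile, expected):
        series = self.build_series([profile])
        assert rrgd_classify(series).iloc[0] == expected

    def test_categories_exclusive_and_exhaustive(self):
        rng = np.random.default_rng(2)
        profiles = rng.uniform(0.5, 10, (200, 4))
        series = self.build_series(profiles)
        cats = rrgd_classify(series)
        fc30 = (series[("HL", 30.0)] + 0.01) / (series[("HL", 0.0)] + 0.01)
        assert set(cats.unique()) <= {"none", "cat1", "cat2", "cat3"}
        assert (cats[fc30 >= 3.0] != "none").all()
        assert (cats[fc30 < 3.0] == "none").all()

    def test_missing_timepoints_rejected(self):
        cols = pd.MultiIndex.from_tuples([("HL", 0.0), ("HL", 30.0)],
                                         names=["condition", "timepoint_min"])
        with pytest.raises(ValueError, match="timepoint"):
            rrgd_classify(pd.DataFrame([[1.0, 5.0]], columns=cols))

    def test_simulated_categories_recovered(self):
        # a realistic (few-percent) RRGD fraction: with many induced genes
        # the shrinking relative-abundance scale damps measured induction
        # below the 3-fold call for genes near the boundary
        cfg = SimulationConfig(n_genes=600, seed=22, nb_dispersion=0.01,
                               frac_rrgd=0.05, batch_sd=0.0)
        truth = generate_truth(cfg)
        total, _ = simulate_polysome_course(truth, cfg)
        cpm = to_abundance(total, "CPM")
        states = [("HL", 0.0), ("HL", 30.0), ("HL", 60.0), ("REC", 30.0)]
        series = pd.concat(
            {s: fold_changes(cpm, total.sample_sheet, s, ("HL", 0.0))
             for s in states}, axis=1)
        series.columns = pd.MultiIndex.from_tuples(
            series.columns, names=["condition", "timepoint_min"])
        cats = rrgd_classify(series)
        true_cats = truth.gene_info()["rrgd_category"]
        rrgd_true = true_cats[true_cats != "none"]
        agreement = (cats.loc[rrgd_true.index] == rrgd_true).mean()
        assert agreement > 0.8


class TestRankSum:
    def test_identical_groups(self):
        x = np.arange(10.0)
        p = ranksum_test(x, x)
        assert p > 0.9

    def test_large_shift_significant(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 50)
        p = ranksum_test(a, a + 100)
        assert p < 0.001

    def test_small_sample_matches_permutation_enumeration(self):
        """Exact permutation oracle: enumerate all C(8,4) group splits of
        the rank-sum statistic."""
        x = np.array([1.2, 3.4, 5.1, 2.2])
        y = np.array([6.7, 8.1, 4.9, 9.3])
        pooled = np.concatenate([x, y])
        obs_u = sum((xi > yj) for xi in x for yj in y)  # U statistic
        n = len(x)
        count = 0
        total = 0
        for idx in itertools.combinations(range(len(pooled)), n):
            xs = pooled[list(idx)]
            ys = np.delete(pooled, list(idx))
            u = sum((a > b) for a in xs for b in ys)
            nm = len(xs) * len(ys)
            if abs(u - nm / 2) >= abs(obs_u - nm / 2):
                count += 1
            total += 1
        p_exact = count / total
        assert ranksum_test(x, y) == pytest.approx(p_exact, rel=0.10)

    def test_category_shift_detected(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(100)]
        fc = pd.Series(np.r_[rng.normal(1, 0.1, 50), rng.normal(3, 0.1, 50)],
                       index=genes)
        cats = pd.Series(["cat1"] * 50 + ["cat2"] * 50, index=genes)
        out = category_rpl_shift(fc, cats)
        row = out.iloc[0]
        assert row["p_value"] < 0.001
        assert row["median_b"] > row["median_a"]

    def test_small_group_skipped(self):
        fc = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        cats = pd.Series(["cat1", "cat1", "cat2"], index=fc.index)
        out = category_rpl_shift(fc, cats, min_group=2)
        assert out["skipped"].iloc[0]


class TestAttenuation:
    @pytest.mark.parametrize("control,treated,digits,expected", [
        (375.0, 4.5, 1, 98.8),   # strong block of a 375-fold induction
        (32.0, 8.0, 0, 75.0),    # inhibition after 60 min of incubation
        (32.0, 3.8, 0, 88.0),    # after 10 min
        (32.0, 1.5, 0, 95.0),    # after 30 min
        (7.0, 7.0, 1, 0.0),
    ])
    def test_printed_arithmetic(self, control, treated, digits, expected):
        assert attenuation_percent(control, treated, digits) == expected

    def test_nonpositive_control_is_error(self):
        with pytest.raises(ValueError):
            attenuation_percent(0.0, 1.0)

    @given(st.floats(0.1, 100), st.floats(0.0, 100), st.floats(0.01, 50))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_scale_invariance(self, a, b, k):
        assert attenuation_percent(k * a, k * b, None) == pytest.approx(
            attenuation_percent(a, b, None), abs=1e-6)


class TestCorrelation:
    def test_identical_fold_changes(self):
        fc = pd.Series([0.5, 1.0, 2.0, 4.0], index=list("abcd"))
        assert correlate_fold_changes(fc, fc) == pytest.approx(1.0)

    def test_independent_fold_changes_near_zero(self):
        rng = np.random.default_rng(5)
        idx = [f"g{i}" for i in range(1000)]
        a = pd.Series(np.exp(rng.normal(0, 1, 1000)), index=idx)
        b = pd.Series(np.exp(rng.normal(0, 1, 1000)), index=idx)
        assert abs(correlate_fold_changes(a, b)) < 0.1

    def test_coupling_pattern_high_low_recovering(self):
        """Total vs polysome fold-change correlation is high early in
        stress, drops late when RPL decouples, and recovers during REC."""
        cfg = SimulationConfig(n_genes=400, seed=23, nb_dispersion=0.01,
                               frac_rrgd=0.15, batch_sd=0.0)
        truth = generate_truth(cfg)
        total, poly = simulate_polysome_course(truth, cfg)
        ct = to_abundance(total, "CPM")
        cp = to_abundance(poly, "CPM")
        def corr(num, den):
            ft = fold_changes(ct, total.sample_sheet, num, den)
            fp = fold_changes(cp, poly.sample_sheet, num, den)
            return correlate_fold_changes(ft, fp)
        early = corr(("HL", 30.0), ("HL", 0.0))
        late = corr(("HL", 60.0), ("HL", 30.0))
        rec = corr(("REC", 30.0), ("REC", 7.5))
        assert early > 0.9
        assert late < early - 0.2
        assert rec > late
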