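import itertools
import math

import numpy as np
import pytest
from scipy import stats

from micronet import (OtuTable, wilcoxon_rank_sum, bh_adjust,
                      differential_abundance, fold_change, tumor_volume,
                      fit_growth_curve, compare_growth_curves,
                      generate_tumor_series, SyntheticParams,
                      generate_two_group_community)


class TestWilcoxonRankSum:
    def test_identical_groups_p_one(self):
        x = np.array([1.0, 2.0, 3.0])
        _, p = wilcoxon_rank_sum(x, x)
        assert p == pytest.approx(1.0)

    def test_exact_small_sample(self):
        _, p = wilcoxon_rank_sum(np.array([1.0, 2.0]), np.array([3.0, 4.0]))
        assert p == pytest.approx(2.0 / 6.0)

    def test_exact_equals_enumeration_all_splits(self):
        """Exact p equals full enumeration for every split of 1..8."""
        values = np.arange(1.0, 9.0)
        for nx_ in (2, 3, 4):
            for idx in itertools.combinations(range(8), nx_):
                x = values[list(idx)]
                y = values[[i for i in range(8) if i not in idx]]
                w, p = wilcoxon_rank_sum(x, y)
                # independent enumeration oracle
                sums = [sum(c) for c in itertools.combinations(range(1, 9), nx_)]
                mean = nx_ * 9 / 2.0
                expected = np.mean([abs(s - mean) >= abs(w - mean) - 1e-9
                                    for s in sums])
                assert p == pytest.approx(min(expected, 1.0), abs=1e-12)

    def test_large_sample_close_to_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=9)
            y = rng.normal(0.5, 1.0, size=9)
            _, p = wilcoxon_rank_sum(x, y)
            ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="asymptotic").pvalue
            assert abs(p - ref) < 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum(np.array([]), np.array([1.0]))


class TestBhAdjust:
    def test_single_p(self):
        assert bh_adjust(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_step_up_by_hand(self):
        q = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_q_at_least_p_and_matches_hand_stepup(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=25)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-15)
        # independent step-up implementation
        order = np.argsort(p)
        m = p.size
        ranked = p[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(ranked, 1.0)
        assert np.allclose(q, expected, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.5]))


class TestDifferentialAbundance:
    @staticmethod
    def table_with_means(mean_ctrl, mean_treat, n=9, seed=0):
        """Two-group percent-composition table with OTU0 at the given means."""
        rng = np.random.default_rng(seed)
        other = 100.0 - mean_ctrl
        counts = np.zeros((2, 2 * n), dtype=np.int64)
        depth = 10_000
        counts[0, :n] = np.round(depth * mean_ctrl / 100)
        counts[1, :n] = depth - counts[0, :n]
        counts[0, n:] = np.round(depth * mean_treat / 100)
        counts[1, n:] = depth - counts[0, n:]
        table = OtuTable(["otu_a", "otu_b"],
                         [f"s{j}" for j in range(2 * n)], counts)
        labels = ["ctl"] * n + ["trt"] * n
        return table, labels

    def test_fold_change_from_printed_means(self):
        # group means 2.26 vs 3.50 percent -> fold change ~ 1.549
        assert fold_change(3.50, 2.26) == pytest.approx(3.50 / 2.26)
        assert fold_change(3.50, 2.26) == pytest.approx(1.549, abs=1e-3)
        # 1.11 vs 0.02 percent -> 55.5-fold
        assert fold_change(1.11, 0.02) == pytest.approx(55.5)
        assert math.isnan(fold_change(1.0, 0.0))

    def test_record_fold_change_and_direction(self):
        table, labels = self.table_with_means(2.26, 3.50)
        df = differential_abundance(table, labels, control_group="ctl")
        rec = df[df["otu_id"] == "otu_a"].iloc[0]
        assert rec["fold_change"] == pytest.approx(3.50 / 2.26, rel=1e-3)
        assert rec["direction"] == "up"

    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(10, 100, size=(5, 6))
        counts = np.hstack([counts, counts])
        table = OtuTable([f"o{i}" for i in range(5)],
                         [f"s{j}" for j in range(12)], counts)
        df = differential_abundance(table, ["a"] * 6 + ["b"] * 6)
        assert not df["significant"].any()

    def test_shifted_module_flagged_and_little_else(self):
        """A rare module boosted in the treatment arm is flagged, with at
        most stray false positives, in >= 90% of seeds."""
        clean = 0
        for seed in range(10):
            params = SyntheticParams(n_samples=9, module_sizes=(5, 10),
                                     n_background=85, loading=0.5, noise_sd=0.3,
                                     dropout=0.0, seed=seed)
            pair = generate_two_group_community(params, shifted_module=0, shift=2.5)
            ctrl, _, truth = pair["control"]
            treat, _, _ = pair["treatment"]
            merged = OtuTable(ctrl.otu_ids, ctrl.sample_ids + treat.sample_ids,
                              np.hstack([ctrl.counts, treat.counts]), ctrl.lineages)
            labels = ["ctl"] * 9 + ["trt"] * 9
            df = differential_abundance(merged, labels, control_group="ctl")
            shifted = {ctrl.otu_ids[i] for i in np.flatnonzero(truth.module_of == 0)}
            hits = set(df[df["significant"]]["otu_id"])
            assert len(hits & shifted) >= 4
            assert len(hits - shifted) <= 2
            clean += hits == shifted
        assert clean >= 7

    def test_three_groups_rejected(self):
        table, _ = self.table_with_means(1.0, 2.0)
        with pytest.raises(ValueError):
            differential_abundance(table, ["a"] * 6 + ["b"] * 6 + ["c"] * 6)


class TestTumorVolume:
    @pytest.mark.parametrize("l,w,expected", [
        (1.0, 1.0, 0.523),
        (1.0, 0.0, 0.0),
        (2.0, 1.5, 2.3535),
    ])
    def test_formula(self, l, w, expected):
        assert tumor_volume(l, w) == pytest.approx(expected)

    def test_swapped_axes_warn_and_fix(self, caplog):
        v = tumor_volume(1.0, 2.0)
        assert v == pytest.approx(tumor_volume(2.0, 1.0))


class TestGrowthCurves:
    def test_exact_recovery(self):
        t = np.arange(8, dtype=float)
        v = 0.1 * np.exp(0.3 * t)
        v0, k, rss = fit_growth_curve(t, v)
        assert v0 == pytest.approx(0.1, abs=1e-6)
        assert k == pytest.approx(0.3, abs=1e-6)
        assert rss == pytest.approx(0.0, abs=1e-12)

    def test_flat_data(self):
        t = np.arange(5, dtype=float)
        v = np.full(5, 0.2)
        _, k, _ = fit_growth_curve(t, v)
        assert k == pytest.approx(0.0, abs=1e-9)

    def test_noisy_recovery_within_tolerance(self):
        df = generate_tumor_series(10, 8, v0=0.1, growth_rate=0.3,
                                   noise_sd=0.02, seed=3)
        v0, k, _ = fit_growth_curve(df["week"], df["volume_cm3"])
        assert abs(v0 - 0.1) < 0.05
        assert abs(k - 0.3) < 0.1

    def test_copy_of_itself_f_zero(self):
        df = generate_tumor_series(6, 8, 0.1, 0.3, 0.02, seed=4)
        f, _, _, p = compare_growth_curves(df["week"], df["volume_cm3"],
                                           df["week"], df["volume_cm3"])
        assert f == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_power_for_distinct_growth_rates(self):
        a = generate_tumor_series(8, 8, 0.1, 0.45, 0.01, seed=5)
        b = generate_tumor_series(8, 8, 0.1, 0.15, 0.01, seed=6)
        _, _, _, p = compare_growth_curves(a["week"], a["volume_cm3"],
                                           b["week"], b["volume_cm3"])
        assert p < 0.01

    def test_null_p_roughly_uniform(self):
        """Same-parameter groups: comparison p spread over (0,1), not
        concentrated near 0."""
        ps = []
        for seed in range(20):
            a = generate_tumor_series(6, 8, 0.1, 0.3, 0.03, seed=100 + seed)
            b = generate_tumor_series(6, 8, 0.1, 0.3, 0.03, seed=200 + seed)
            ps.append(compare_growth_curves(a["week"], a["volume_cm3"],
                                            b["week"], b["volume_cm3"])[3])
        ps = np.array(ps)
        assert (ps < 0.05).mean() <= 0.2
        assert ps.mean() > 0.2

    def test_non_positive_volume_rejected(self):
        with pytest.raises(ValueError):
            fit_growth_curve(np.arange(4.0), np.array([1.0, 2.0, -1.0, 3.0]))
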