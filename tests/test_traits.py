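import numpy as np
import pytest
from scipy import stats

from micronet import (Partition, SyntheticParams, generate_community,
                      module_eigengene, module_trait_correlation,
                      otu_significance, mantel_test, pearson_with_t_pvalue,
                      relative_abundance)
from tests.conftest import abundance_from


class TestModuleEigengene:
    def test_identical_profiles(self):
        base = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        ab = abundance_from(np.vstack([base, base, base]))
        eig, ve = module_eigengene(ab, ["o0", "o1", "o2"])
        assert ve == pytest.approx(1.0)
        z = (base - base.mean()) / base.std()
        assert np.allclose(eig, z, atol=1e-9)

    def test_anti_correlated_pair(self):
        base = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        ab = abundance_from(np.vstack([base, -base]))
        eig, ve = module_eigengene(ab, ["o0", "o1"])
        assert ve == pytest.approx(1.0)
        # orientation tie broken toward the lexicographically first member
        assert np.corrcoef(eig, base)[0, 1] > 0

    def test_two_member_eigengene_is_oriented_mean(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=(2, 10))
        ab = abundance_from(np.vstack([a, b]))
        eig, _ = module_eigengene(ab, ["o0", "o1"])
        za = (a - a.mean()) / a.std()
        zb = (b - b.mean()) / b.std()
        mean = za + zb
        mean /= mean.std()
        assert np.allclose(np.abs(np.corrcoef(eig, mean)[0, 1]), 1.0, atol=1e-9)

    def test_recovers_latent_factor(self):
        """|corr(eigengene, true factor)| >= 0.9 over 10 seeds."""
        for seed in range(10):
            params = SyntheticParams(n_samples=30, module_sizes=(20,),
                                     n_background=20, loading=1.0, noise_sd=0.3,
                                     dropout=0.0, seed=seed)
            table, _, truth = generate_community(params)
            ab = relative_abundance(table)
            members = [table.otu_ids[i] for i in np.flatnonzero(truth.module_of == 0)]
            eig, _ = module_eigengene(ab, members)
            assert abs(np.corrcoef(eig, truth.factors[0])[0, 1]) >= 0.9

    def test_constant_member_rejected(self):
        ab = abundance_from(np.array([[1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4.0]]))
        with pytest.raises(ValueError):
            module_eigengene(ab, ["o0", "o1"])


class TestModuleTraitCorrelation:
    def test_t_pvalue_matches_reference_r08_n9(self):
        # r = 0.8 at n = 9 -> t = 3.528, two-tailed p ~ 0.0097
        rng = np.random.default_rng(0)
        x = rng.normal(size=9)
        # construct y with exact sample correlation 0.8
        y0 = rng.normal(size=9)
        xs = (x - x.mean()) / x.std()
        resid = y0 - y0.mean() - (y0 - y0.mean()) @ xs / (xs @ xs) * xs
        resid /= resid.std()
        y = 0.8 * xs + np.sqrt(1 - 0.64) * resid
        r, p = pearson_with_t_pvalue(x, y)
        assert r == pytest.approx(0.8, abs=1e-12)
        assert p == pytest.approx(0.0097, abs=5e-4)
        ref = stats.pearsonr(x, y)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_trait_equal_to_eigengene(self):
        base = np.linspace(0, 1, 6)
        ab = abundance_from(np.vstack([base, base * 2 + 0.1]))
        part = Partition({"o0": 1, "o1": 1}, 0.0)
        eig, _ = module_eigengene(ab, ["o0", "o1"])
        res = module_trait_correlation(ab, part, eig)
        assert res[0].r == pytest.approx(1.0, abs=1e-9)
        assert res[0].p < 1e-8

    def test_independent_formula_oracle(self):
        rng = np.random.default_rng(6)
        ab = abundance_from(rng.normal(size=(6, 12)))
        part = Partition({f"o{i}": 1 + i // 3 for i in range(6)}, 0.0)
        trait = rng.normal(size=12)
        for res in module_trait_correlation(ab, part, trait):
            r_ref = stats.pearsonr(res.eigengene, trait)
            assert res.r == pytest.approx(r_ref.statistic, abs=1e-12)
            assert res.p == pytest.approx(r_ref.pvalue, abs=1e-12)

    def test_linked_module_wins(self):
        """The trait-linked module attains the largest |r| in >= 9/10 seeds
        at coupling beta = 1.5, n = 30."""
        wins = 0
        for seed in range(10):
            params = SyntheticParams(n_samples=30, module_sizes=(15, 15, 15),
                                     n_background=30, loading=1.5, noise_sd=0.5,
                                     dropout=0.0, trait_coupling=1.5,
                                     trait_module=1, seed=seed)
            table, traits, truth = generate_community(params)
            ab = relative_abundance(table)
            labels = {}
            for i, oid in enumerate(table.otu_ids):
                labels[oid] = int(truth.module_of[i]) + 1 if truth.module_of[i] >= 0 else 4
            part = Partition(labels, 0.0)
            res = module_trait_correlation(ab, part, traits.values)
            by_mod = {x.module: abs(x.r) for x in res}
            wins += max(by_mod, key=by_mod.get) == 2
        assert wins >= 9


class TestOtuSignificance:
    def test_profile_equal_to_trait(self):
        trait = np.array([1.0, 2.0, 5.0, 3.0])
        ab = abundance_from(np.vstack([trait, trait * 0 + [0, 1, 0, -1]]))
        sig = otu_significance(ab, trait)
        assert sig["o0"] == pytest.approx(1.0)

    def test_orthogonal_profile(self):
        trait = np.array([1.0, -1.0, 1.0, -1.0])
        profile = np.array([1.0, 1.0, -1.0, -1.0])
        ab = abundance_from(profile[None, :])
        assert otu_significance(ab, trait)["o0"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(7)
        ab = abundance_from(rng.normal(size=(8, 9)))
        trait = rng.normal(size=9)
        sig = otu_significance(ab, trait)
        for i in range(8):
            r = np.corrcoef(ab.values[i], trait)[0, 1]
            assert sig[f"o{i}"] == pytest.approx(r * r, abs=1e-12)

    def test_zero_variance_gets_zero(self):
        ab = abundance_from(np.array([[1.0, 1.0, 1.0, 1.0]]))
        assert otu_significance(ab, np.array([1.0, 2, 3, 4]))["o0"] == 0.0


class TestMantel:
    @staticmethod
    def random_distance(rng, n):
        x = rng.normal(size=(n, 3))
        return np.linalg.norm(x[:, None] - x[None, :], axis=-1)

    def test_identical_matrices(self):
        rng = np.random.default_rng(1)
        d = self.random_distance(rng, 8)
        res = mantel_test(d, d, n_perm=199, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 200)

    def test_skbio_oracle_agreement(self):
        from skbio.stats.distance import DistanceMatrix, mantel as skbio_mantel
        rng = np.random.default_rng(2)
        d1 = self.random_distance(rng, 10)
        d2 = self.random_distance(rng, 10)
        res = mantel_test(d1, d2, n_perm=199, seed=0)
        r_ref, _, _ = skbio_mantel(DistanceMatrix(d1), DistanceMatrix(d2),
                                   method="pearson", permutations=0)
        assert res.r == pytest.approx(r_ref, abs=1e-12)

    def test_exact_enumeration_n4(self):
        """At n = 4 the permutation p matches exhaustive enumeration."""
        from itertools import permutations
        rng = np.random.default_rng(3)
        d1 = self.random_distance(rng, 4)
        d2 = self.random_distance(rng, 4)
        tri = np.tril_indices(4, k=-1)

        def corr(a, b):
            va, vb = a[tri], b[tri]
            return np.corrcoef(va, vb)[0, 1]

        r_obs = corr(d1, d2)
        perms = [corr(d1, d2[np.ix_(p, p)]) for p in permutations(range(4))]
        exact = np.mean([rp >= r_obs - 1e-12 for rp in perms])
        res = mantel_test(d1, d2, n_perm=5000, seed=1)
        assert res.p == pytest.approx(exact, abs=0.02)

    def test_asymmetric_rejected(self):
        d = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError):
            mantel_test(d, d.T)

    def test_type_i_error_calibrated(self):
        """Null rejection rate near 5% (199 permutations, 400 trials)."""
        rng = np.random.default_rng(10)
        rejections = 0
        trials = 400
        for _ in range(trials):
            d1 = self.random_distance(rng, 10)
            d2 = self.random_distance(rng, 10)
            res = mantel_test(d1, d2, n_perm=199, seed=int(rng.integers(2**31)))
            rejections += res.p <= 0.05
        assert 0.02 <= rejections / trials <= 0.08
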