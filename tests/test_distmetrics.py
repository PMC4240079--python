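import numpy as np
import pytest

from ribodist.distfit import EmpiricalDistribution, histogram
from ribodist.distmetrics import (
    DistanceMatrix,
    comparison_set,
    distinctness_all,
    distinctness_test,
    energy_distance,
    hellinger_distance,
    js_distance,
    pairwise_histogram_distances,
    probability_rows,
)
from ribodist.profile_io import SENSE_CODONS


def two_bin(p0):
    return EmpiricalDistribution(np.array([0.0, 1.0, 2.0]), np.array([p0, 1 - p0]), 10)


class TestHistogramMetrics:
    def test_identity_gives_zero(self):
        p = two_bin(0.3)
        assert js_distance(p, p) == 0.0
        assert hellinger_distance(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_give_one(self):
        p, q = two_bin(1.0), two_bin(0.0)
        assert js_distance(p, q) == pytest.approx(1.0)
        assert hellinger_distance(p, q) == pytest.approx(1.0)

    def test_js_hand_derived_value(self):
        # 0.5*KL(p||m) + 0.5*KL(q||m) with m=(0.7,0.3), then sqrt
        assert js_distance(two_bin(0.5), two_bin(0.9)) == pytest.approx(0.38313, abs=1e-5)

    def test_hellinger_hand_derived_value(self):
        # sqrt(1 - sqrt(0.5))
        assert hellinger_distance(two_bin(1.0), two_bin(0.5)) == pytest.approx(
            np.sqrt(1 - np.sqrt(0.5)), abs=1e-9
        )

    def test_mismatched_bins_abort(self):
        p = two_bin(0.5)
        q = EmpiricalDistribution(np.array([0.0, 0.5, 1.0]), np.array([0.5, 0.5]), 10)
        with pytest.raises(ValueError):
            js_distance(p, q)
        with pytest.raises(ValueError):
            hellinger_distance(p, q)

    def test_axioms_on_random_pairs(self, rng):
        for _ in range(200):
            a = rng.dirichlet(np.ones(8))
            b = rng.dirichlet(np.ones(8))
            edges = np.arange(9.0)
            p = EmpiricalDistribution(edges, a, 10)
            q = EmpiricalDistribution(edges, b, 10)
            for d in (js_distance, hellinger_distance):
                assert d(p, q) >= 0
                assert d(p, q) == pytest.approx(d(q, p), abs=1e-12)
                # sqrt amplifies rounding: 1 - BC ~ 1e-16 -> d ~ 1e-8
                assert d(p, p) == pytest.approx(0.0, abs=1e-6)


class TestEnergyDistance:
    def test_identical_multisets_give_zero(self):
        assert energy_distance([1.0, 2.0, 3.0], [3.0, 1.0, 2.0]) == pytest.approx(0.0)

    def test_point_masses_hand_value(self):
        assert energy_distance([0.0], [1.0]) == pytest.approx(np.sqrt(2.0))

    def test_matches_brute_force_pairwise_oracle(self, rng):
        def brute(x, y):
            x, y = np.asarray(x), np.asarray(y)
            exy = np.abs(x[:, None] - y[None, :]).mean()
            exx = np.abs(x[:, None] - x[None, :]).mean()
            eyy = np.abs(y[:, None] - y[None, :]).mean()
            return np.sqrt(2 * exy - exx - eyy)

        for _ in range(20):
            x = rng.uniform(0, 3, 10)
            y = rng.uniform(0, 3, 10)
            assert energy_distance(x, y) == pytest.approx(brute(x, y), abs=1e-9)

    def test_scales_with_sqrt_of_common_factor(self, rng):
        x = rng.uniform(0, 1, 50)
        y = rng.uniform(0, 2, 50)
        d1 = energy_distance(x, y)
        d2 = energy_distance(2 * x, 2 * y)
        assert d2 == pytest.approx(np.sqrt(2) * d1, rel=1e-9)

    def test_empty_aborts(self):
        with pytest.raises(ValueError):
            energy_distance([], [1.0])

    def test_binned_resampled_converges_to_sample_value(self, rng):
        x = rng.lognormal(0, 0.4, 4000)
        y = rng.lognormal(0.3, 0.4, 4000)
        target = energy_distance(x, y)
        errs = []
        for bw in (1.0, 0.2, 0.05):
            hx, hy = histogram(x, bin_width=bw), histogram(y, bin_width=bw)
            mids = (hx.bin_edges[:-2] + hx.bin_edges[1:-1]) / 2
            rx = np.repeat(mids, np.round(hx.probabilities[:-1] * x.size).astype(int))
            ry = np.repeat(mids, np.round(hy.probabilities[:-1] * y.size).astype(int))
            errs.append(abs(energy_distance(rx, ry) - target))
        assert errs[1] < errs[0] and errs[2] < errs[0]
        assert errs[2] < 0.005


class TestPairwiseVectorized:
    def test_matches_scalar_implementations(self, rng):
        sets = [rng.lognormal(0, 0.4, 300) for _ in range(6)]
        P = probability_rows(sets)
        hists = [histogram(s) for s in sets]
        for metric, scalar in (("js", js_distance), ("hellinger", hellinger_distance)):
            D = pairwise_histogram_distances(P, metric)
            for i in range(6):
                for j in range(6):
                    assert D[i, j] == pytest.approx(scalar(hists[i], hists[j]), abs=1e-7)

    def test_js_hellinger_rank_agreement_with_direct_oracle(self, rng):
        # dense-bin recomputation from first principles as the oracle
        from scipy.stats import spearmanr

        pairs = []
        for _ in range(100):
            a = rng.dirichlet(np.ones(30))
            b = rng.dirichlet(np.ones(30))
            pairs.append((a, b))
        D_js = [
            pairwise_histogram_distances(np.vstack([a, b]), "js")[0, 1] for a, b in pairs
        ]

        def direct_js(a, b):
            m = (a + b) / 2
            def kl(p, q):
                mask = p > 0
                return np.sum(p[mask] * np.log2(p[mask] / q[mask]))
            return np.sqrt(0.5 * kl(a, m) + 0.5 * kl(b, m))

        oracle = [direct_js(a, b) for a, b in pairs]
        np.testing.assert_allclose(D_js, oracle, atol=1e-9)
        r, _ = spearmanr(D_js, [np.sqrt(1 - np.sum(np.sqrt(a * b))) for a, b in pairs])
        assert r >= 0.99


class TestDistanceMatrix:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]), "js")
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.5, 1.0], [1.0, 0.0]]), "js")


class TestComparisonSets:
    def test_synonymous_set(self):
        syn = comparison_set("GCT", "synonymous", SENSE_CODONS)
        assert syn == ["GCA", "GCC", "GCG"]

    def test_same_composition_is_anagrams(self):
        comp = comparison_set("GCT", "same_composition", SENSE_CODONS)
        assert comp == sorted(c for c in SENSE_CODONS if sorted(c) == ["C", "G", "T"] and c != "GCT")

    def test_codon_without_synonym_gives_empty_result(self, rng):
        by_gene = {
            f"g{i}": {"ATG": rng.lognormal(0, 0.3, 20), "GCT": rng.lognormal(0, 0.3, 20)}
            for i in range(10)
        }
        res = distinctness_test(by_gene, "ATG", restrict="synonymous", n_partitions=5)
        assert np.isnan(res.p_value) and res.comparison_codons == []


class TestDistinctness:
    def make_null(self, rng, codons=10, genes=30, n=25):
        return {
            f"g{i}": {c: rng.lognormal(0, 0.4, n) for c in SENSE_CODONS[:codons]}
            for i in range(genes)
        }

    def test_null_codon_not_distinct(self, rng):
        by_gene = self.make_null(rng)
        res = distinctness_test(by_gene, "AAA", metric="js", n_partitions=40, seed=1)
        assert res.p_value > 0.01

    @pytest.mark.parametrize("metric", ["js", "hellinger", "energy"])
    def test_planted_codon_detected_by_every_metric(self, rng, metric):
        by_gene = self.make_null(rng, codons=8, genes=30, n=40)
        for g in by_gene:
            by_gene[g]["AAC"] = rng.lognormal(0.4, 0.3, 40)
        res = distinctness_test(by_gene, "AAC", metric=metric, n_partitions=40, seed=2)
        assert res.p_value < 0.01

    def test_all_codons_version_matches_single_codon_pvalues(self, rng):
        by_gene = self.make_null(rng, codons=5, genes=20, n=20)
        allres = distinctness_all(by_gene, metric="hellinger", n_partitions=30, seed=7)
        single = distinctness_test(by_gene, "AAA", metric="hellinger", n_partitions=30, seed=7)
        assert allres["AAA"].p_value == pytest.approx(single.p_value)
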