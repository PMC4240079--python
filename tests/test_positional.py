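import numpy as np
import pytest

from ribodist.nfc_core import CodonSampleSet
from ribodist.positional import (
    MeanDistanceVector,
    boundary_on_mean_rc,
    detect_boundary,
    mean_distance_vector,
    mean_rc_profile,
    window_sample_sets,
)
from ribodist.profile_io import GeneProfile
from ribodist.nfc_core import NfcProfile
from ribodist.tasep import positional_shift_generator
from tests.conftest import lognormal_pairs


def make_vector(values, window=50, end="5p"):
    values = np.asarray(values, float)
    return MeanDistanceVector(
        np.arange(1, values.size + 1), values, np.zeros(values.size), "hellinger", window, end
    )


class TestWindowSampleSets:
    def test_window_count_matches_span_arithmetic(self):
        pairs = lognormal_pairs(5, 250, seed=0)
        sets = window_sample_sets(pairs, span=200, window=50, step=1)
        assert len(sets) == 151

    def test_3p_windows_anchored_from_stop_inward(self):
        # one gene: first half GCT, second half AAA; 3' window 1 sees only AAA
        g = GeneProfile("g", ["GCT"] * 30 + ["AAA"] * 30, np.full(60, 5.0))
        n = NfcProfile("g", np.ones(60), np.ones(60, bool))
        sets = window_sample_sets([(g, n)], end="3p", span=40, window=20, split_half=False)
        assert set(sets[0].samples) == {"AAA"}
        assert sets[0].samples["AAA"].size == 20

    def test_short_genes_skipped_per_window(self):
        pairs = lognormal_pairs(3, 100, seed=1) + lognormal_pairs(3, 300, seed=2)
        sets = window_sample_sets(pairs, span=200, window=50, split_half=False)
        # windows beyond position 100 only contain the long genes
        assert sets[-1].total == sum(1 for _ in range(3)) * 50 * 3 / 3  # 3 long genes x 50 codons
        assert sets[0].total == 6 * 50

    def test_split_half_partitions_every_position(self):
        pairs = lognormal_pairs(4, 120, seed=3)
        sets = window_sample_sets(pairs, span=100, window=40, seed=5)
        ws = sets[0]
        assert ws.half_b is not None
        total = sum(v.size for v in ws.samples.values()) + sum(v.size for v in ws.half_b.values())
        assert total == 4 * 40

    def test_equalize_rc_reproducible_and_equal(self):
        pairs = lognormal_pairs(30, 200, seed=4)
        a = window_sample_sets(pairs, span=150, window=50, equalize_rc=True, seed=11)
        b = window_sample_sets(pairs, span=150, window=50, equalize_rc=True, seed=11)
        for c in a[0].samples:
            counts = {ws.samples[c].size for ws in a if c in ws.samples}
            assert len(counts) == 1
            np.testing.assert_array_equal(a[3].samples[c], b[3].samples[c])


class TestMeanDistanceVector:
    def test_single_codon_vector_equals_its_column_means(self, rng):
        sets = [
            CodonSampleSet({"GCT": rng.lognormal(0, 0.4, 400)}, region=f"window=({s},10)@5p")
            for s in range(1, 9)
        ]
        v = mean_distance_vector(sets, metric="hellinger")
        from ribodist.distmetrics import pairwise_histogram_distances, probability_rows

        D = pairwise_histogram_distances(probability_rows([ws.samples["GCT"] for ws in sets]), "hellinger")
        off = ~np.eye(8, dtype=bool)
        expected = np.array([D[off[:, k], k].mean() for k in range(8)])
        np.testing.assert_allclose(v.means, expected, atol=1e-12)

    def test_planted_early_windows_are_elevated(self, rng):
        early = [
            CodonSampleSet({"GCT": rng.lognormal(0.3, 0.4, 2000)}, region=f"window=({s},10)@5p")
            for s in range(1, 11)
        ]
        late = [
            CodonSampleSet({"GCT": rng.lognormal(0.0, 0.4, 2000)}, region=f"window=({s},10)@5p")
            for s in range(11, 41)
        ]
        v = mean_distance_vector(early + late, metric="js")
        assert v.means[:10].min() > v.means[10:].max()

    def test_unknown_metric_aborts(self, rng):
        sets = [CodonSampleSet({"GCT": rng.uniform(0, 2, 50)}) for _ in range(3)]
        with pytest.raises(ValueError):
            mean_distance_vector(sets, metric="wasserstein")


class TestDetectBoundary:
    def test_constant_vector_boundary_at_first_position(self):
        est = detect_boundary(make_vector(np.ones(100)))
        assert est.found and est.boundary == 1

    def test_step_vector_recovers_planted_change(self, rng):
        values = np.concatenate([np.full(30, 10.0), np.ones(121)]) + rng.normal(0, 1e-3, 151)
        est = detect_boundary(make_vector(values))
        # the scan window mixes high/low entries across the step, so the first
        # balanced window starts up to scan/2 positions before the step
        assert est.found and abs(est.boundary - 30) <= 5

    def test_null_vector_boundary_within_first_scan_positions(self, rng):
        hits = 0
        for _ in range(100):
            est = detect_boundary(make_vector(1 + rng.normal(0, 0.01, 151)))
            hits += est.found and est.boundary <= 10
        assert hits >= 90

    def test_all_significant_flags_none_found(self):
        # valley-shaped vector at a permissive alpha: every scan window ranks
        # apart from the rest, so no boundary exists in the scanned range
        v = (np.arange(1, 17) - 8.5) ** 2
        est = detect_boundary(make_vector(v), scan=10, alpha=0.25)
        assert not est.found and est.boundary is None


class TestPipelineRecovery:
    def test_shift_region_within_window_length_is_localized(self):
        hits = []
        for seed in range(3):
            pairs = positional_shift_generator(
                shift_len=30, delta_mu=0.3, n_genes=500, gene_length=400, seed=700 + seed
            )
            sets = window_sample_sets(pairs, span=200, window=50, seed=seed)
            v = mean_distance_vector(sets, metric="hellinger")
            est = detect_boundary(v)
            hits.append(est.boundary)
        assert all(abs(b - 30) <= 10 for b in hits)

    def test_boundary_robust_to_metric_choice(self):
        pairs = positional_shift_generator(
            shift_len=30, delta_mu=0.4, n_genes=400, gene_length=250, seed=42
        )
        sets = window_sample_sets(pairs, span=120, window=40, step=2, seed=0)
        bounds = {}
        for m in ("js", "hellinger", "energy"):
            v = mean_distance_vector(sets, metric=m)
            bounds[m] = detect_boundary(v).boundary
        assert max(bounds.values()) - min(bounds.values()) <= 10


class TestMeanRcBoundary:
    def test_uniform_rc_boundary_at_one(self):
        genes = [GeneProfile(f"g{i}", ["GCT"] * 250, np.full(250, 8.0)) for i in range(20)]
        est = boundary_on_mean_rc(genes, span=200)
        assert est.boundary == 1

    def test_5p_ramp_localized(self, rng):
        genes = []
        for i in range(300):
            rc = np.full(250, 10.0)
            rc[:40] *= 2.0
            rc += rng.normal(0, 1.0, 250)
            genes.append(GeneProfile(f"g{i}", ["GCT"] * 250, np.clip(rc, 0, None)))
        est = boundary_on_mean_rc(genes, span=200)
        assert abs(est.boundary - 40) <= 5

    def test_shape_shift_invisible_to_mean_rc_but_seen_by_distribution_scan(self, rng):
        # mean-preserving variance change over the first 40 codons
        n_genes, L = 400, 250
        pairs = []
        for i in range(n_genes):
            sig = np.full(L, 0.25)
            sig[:40] = 0.75
            nfc = rng.lognormal(-sig**2 / 2, sig)  # mean 1 at every position
            gp = GeneProfile(f"g{i}", list(np.array(["GCT", "AAA", "TTC", "GGA"])[rng.integers(0, 4, L)]), nfc * 10)
            pairs.append((gp, NfcProfile(gp.gene_id, nfc, np.ones(L, bool))))
        rc_est = boundary_on_mean_rc([g for g, _ in pairs], span=200)
        assert rc_est.boundary <= 5
        sets = window_sample_sets(pairs, span=120, window=40, seed=1)
        v = mean_distance_vector(sets, metric="hellinger")
        dist_est = detect_boundary(v)
        assert dist_est.boundary is None or dist_est.boundary > 20

    def test_3p_mean_profile_mirrored(self):
        g = GeneProfile("g", ["GCT"] * 210, np.arange(210, dtype=float))
        prof = mean_rc_profile([g], end="3p", span=200)
        assert prof[0] == 209.0 and prof[-1] == 10.0
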