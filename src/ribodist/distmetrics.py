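"""Distances between NFC distributions and the codon-distinctness test.

Three metrics, chosen for their different principles: the Jensen-Shannon
distance (relative-entropy based, log base 2, metric form sqrt(JSD)) and the
Hellinger distance operate on shared-bin histograms; the energy distance
operates directly on the raw samples, never forming a probability function.
All three are 0 for identical inputs and grow as the inputs diverge; JS and
Hellinger live in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import jensenshannon

from ribodist.distfit import EmpiricalDistribution, histogram
from ribodist.profile_io import SENSE_CODONS

logger = logging.getLogger(__name__)

METRICS = ("js", "hellinger", "energy")

#: standard genetic code, for the `synonymous` restriction
_GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D",
    "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R",
    "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R",
    "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


@dataclass
class DistanceMatrix:
    """Labeled symmetric non-negative distance matrix for one metric."""

    labels: list[str]
    values: np.ndarray
    metric: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if np.any(np.abs(np.diag(self.values)) > 1e-12):
            raise ValueError("diagonal must be 0")
        if np.any(np.abs(self.values - self.values.T) > 1e-12):
            raise ValueError("matrix must be symmetric")
        if np.any(self.values < 0):
            raise ValueError("distances must be >= 0")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def _check_bins(p: EmpiricalDistribution, q: EmpiricalDistribution) -> None:
    if p.bin_edges.size != q.bin_edges.size or not np.array_equal(p.bin_edges, q.bin_edges):
        raise ValueError("distributions must share identical bin edges")


def js_distance(p: EmpiricalDistribution, q: EmpiricalDistribution) -> float:
    """Jensen-Shannon distance: sqrt of the base-2 JS divergence, in [0, 1]."""
    _check_bins(p, q)
    d = jensenshannon(p.probabilities, q.probabilities, base=2)
    return float(0.0 if np.isnan(d) else min(d, 1.0))


def hellinger_distance(p: EmpiricalDistribution, q: EmpiricalDistribution) -> float:
    """Hellinger distance sqrt(1 - sum_i sqrt(p_i q_i)), in [0, 1]."""
    _check_bins(p, q)
    bc = float(np.sum(np.sqrt(p.probabilities * q.probabilities)))
    return float(np.sqrt(max(0.0, 1.0 - bc)))


def energy_distance(x, y, max_samples: int = 20_000, seed: int = 0, rng=None) -> float:
    """Energy distance sqrt(2 E|X-Y| - E|X-X'| - E|Y-Y'|) on raw samples.

    When the pair count exceeds 4e8, each side is subsampled (seeded) to at
    most ``max_samples``; exact otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("energy_distance requires non-empty samples")
    if x.size * y.size > 4e8:
        if rng is None:
            rng = np.random.default_rng(seed)
        if x.size > max_samples:
            x = rng.choice(x, size=max_samples, replace=False)
        if y.size > max_samples:
            y = rng.choice(y, size=max_samples, replace=False)
        logger.info("energy_distance: subsampled to %d/%d samples", x.size, y.size)
    return float(stats.energy_distance(x, y))


def histogram_distance(p, q, metric: str) -> float:
    if metric == "js":
        return js_distance(p, q)
    if metric == "hellinger":
        return hellinger_distance(p, q)
    raise ValueError(f"unknown histogram metric {metric!r}")


# ---------------------------------------------------------------------------
# vectorized pairwise helpers (used by positional and distinctness code paths)
# ---------------------------------------------------------------------------

def _entropy2(P: np.ndarray) -> np.ndarray:
    """Row-wise base-2 entropy with 0 log 0 = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(P > 0, P * np.log2(P), 0.0)
    return -t.sum(axis=-1)


def pairwise_histogram_distances(P: np.ndarray, metric: str, Q: np.ndarray | None = None) -> np.ndarray:
    """All-pairs JS/Hellinger distances between rows of probability matrices.

    ``P`` is (n1, bins); with ``Q`` (n2, bins) the cross matrix (n1, n2) is
    returned, otherwise the symmetric (n1, n1) self matrix.
    """
    P = np.asarray(P, dtype=float)
    sym = Q is None
    Q = P if sym else np.asarray(Q, dtype=float)
    if metric == "hellinger":
        G = np.sqrt(P) @ np.sqrt(Q).T
        D = np.sqrt(np.clip(1.0 - G, 0.0, None))
    elif metric == "js":
        Hp = _entropy2(P)
        Hq = _entropy2(Q)
        D = np.empty((P.shape[0], Q.shape[0]))
        for i in range(P.shape[0]):
            M = (P[i][None, :] + Q) / 2.0
            jsd = _entropy2(M) - (Hp[i] + Hq) / 2.0
            D[i] = np.sqrt(np.clip(jsd, 0.0, 1.0))
    else:
        raise ValueError(f"unknown histogram metric {metric!r}")
    if sym:
        D = (D + D.T) / 2.0
        np.fill_diagonal(D, 0.0)
    return D


def probability_rows(sample_arrays, bin_width: float = 0.05, upper: float = 5.0) -> np.ndarray:
    """Stack per-set histograms (shared fixed edges) into a probability matrix."""
    rows = [histogram(x, bin_width=bin_width, upper=upper).probabilities for x in sample_arrays]
    return np.vstack(rows)


# ---------------------------------------------------------------------------
# codon-distinctness test
# ---------------------------------------------------------------------------

@dataclass
class DistinctnessResult:
    """Outcome of the gene-partition distinctness test for one codon."""

    codon: str
    metric: str
    p_value: float
    self_distances: np.ndarray
    cross_distances: np.ndarray  # (n_partitions, n_comparison_codons), NaN = absent
    comparison_codons: list[str]
    n_partitions: int

    @property
    def distinct(self) -> bool:
        return bool(np.isfinite(self.p_value) and self.p_value < 0.01)


def comparison_set(codon: str, restrict: str, candidates) -> list[str]:
    """Comparison codons under a restriction: all, synonymous, same_composition."""
    pool = [c for c in candidates if c != codon]
    if restrict == "all":
        return sorted(pool)
    if restrict == "synonymous":
        aa = _GENETIC_CODE[codon]
        return sorted(c for c in pool if _GENETIC_CODE[c] == aa)
    if restrict == "same_composition":
        comp = sorted(codon)
        return sorted(c for c in pool if sorted(c) == comp)
    raise ValueError("restrict must be 'all', 'synonymous' or 'same_composition'")


def _pool_half(samples_by_gene, genes, codons) -> dict[str, np.ndarray]:
    out = {}
    for c in codons:
        parts = [samples_by_gene[g][c] for g in genes if c in samples_by_gene[g]]
        if parts:
            x = np.concatenate(parts)
            if x.size:
                out[c] = x
    return out


def _partitions(genes, n_partitions, codon, samples_by_gene, rng, max_redraws=100):
    """Yield (half1, half2) gene splits with `codon` present in both halves."""
    genes = sorted(genes)
    n = len(genes)
    if n < 2:
        raise ValueError("distinctness test requires >= 2 genes")
    for _ in range(n_partitions):
        for attempt in range(max_redraws):
            perm = rng.permutation(n)
            h1 = [genes[i] for i in perm[: n // 2]]
            h2 = [genes[i] for i in perm[n // 2 :]]
            ok1 = any(codon in samples_by_gene[g] and samples_by_gene[g][codon].size for g in h1)
            ok2 = any(codon in samples_by_gene[g] and samples_by_gene[g][codon].size for g in h2)
            if ok1 and ok2:
                if attempt:
                    logger.info("distinctness: redrew partition %d time(s) for %s", attempt, codon)
                yield h1, h2
                break
        else:
            raise ValueError(f"codon {codon} cannot be placed in both halves of any partition")


def distinctness_test(
    samples_by_gene: dict,
    codon: str,
    metric: str = "js",
    n_partitions: int = 100,
    restrict: str = "all",
    seed: int = 0,
    bin_width: float = 0.05,
    upper: float = 5.0,
) -> DistinctnessResult:
    """Test whether one codon's NFC distribution is distinct from others'.

    Genes are split into two equal halves ``n_partitions`` times.  Per
    partition the self-distance d(c@half1, c@half2) is compared with the
    cross-distances d(c@half1, c'@half2) for every comparison codon c' in the
    restriction set.  The returned p-value is the fraction of
    (partition, c') pairs with self >= cross — a one-sided empirical test
    that the codon is closer to itself than to other codons; p < 0.01 is
    declared distinct.

    ``samples_by_gene`` maps gene_id -> {codon -> NFC sample array} (see
    :func:`samples_per_gene`).
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    present = sorted({c for g in samples_by_gene.values() for c in g})
    if codon not in present:
        raise ValueError(f"codon {codon} absent from the data")
    comp = comparison_set(codon, restrict, present)
    if not comp:
        logger.info("distinctness: empty %s comparison set for %s", restrict, codon)
        return DistinctnessResult(codon, metric, float("nan"), np.empty(0), np.empty((0, 0)), [], n_partitions)
    rng = np.random.default_rng(seed)
    needed = [codon] + comp
    selfs = np.empty(n_partitions)
    crosses = np.full((n_partitions, len(comp)), np.nan)
    for k, (h1, h2) in enumerate(_partitions(samples_by_gene.keys(), n_partitions, codon, samples_by_gene, rng)):
        pool1 = _pool_half(samples_by_gene, h1, [codon])
        pool2 = _pool_half(samples_by_gene, h2, needed)
        if metric == "energy":
            selfs[k] = energy_distance(pool1[codon], pool2[codon], rng=rng)
            for j, c in enumerate(comp):
                if c in pool2:
                    crosses[k, j] = energy_distance(pool1[codon], pool2[c], rng=rng)
        else:
            p1 = histogram(pool1[codon], bin_width, upper)
            p2 = histogram(pool2[codon], bin_width, upper)
            selfs[k] = histogram_distance(p1, p2, metric)
            for j, c in enumerate(comp):
                if c in pool2:
                    crosses[k, j] = histogram_distance(p1, histogram(pool2[c], bin_width, upper), metric)
    valid = np.isfinite(crosses)
    self_b = np.broadcast_to(selfs[:, None], crosses.shape)
    p = float(np.mean(self_b[valid] >= crosses[valid]))
    return DistinctnessResult(codon, metric, p, selfs, crosses, comp, n_partitions)


def distinctness_all(
    samples_by_gene: dict,
    metric: str = "js",
    n_partitions: int = 100,
    restrict: str = "all",
    seed: int = 0,
    bin_width: float = 0.05,
    upper: float = 5.0,
) -> dict[str, DistinctnessResult]:
    """Distinctness test for every present codon, sharing the partitions.

    Histogram metrics are vectorized across codons (one pooled histogram
    matrix per half per partition); the energy metric falls back to
    per-codon :func:`distinctness_test` calls.
    """
    present = sorted({c for g in samples_by_gene.values() for c in g})
    if metric == "energy":
        return {
            c: distinctness_test(samples_by_gene, c, metric, n_partitions, restrict, seed, bin_width, upper)
            for c in present
        }
    rng = np.random.default_rng(seed)
    genes = sorted(samples_by_gene)
    n = len(genes)
    idx = {c: i for i, c in enumerate(present)}
    selfs = np.full((n_partitions, len(present)), np.nan)
    crosses = np.full((n_partitions, len(present), len(present)), np.nan)
    for k in range(n_partitions):
        perm = rng.permutation(n)
        h1 = [genes[i] for i in perm[: n // 2]]
        h2 = [genes[i] for i in perm[n // 2 :]]
        pool1 = _pool_half(samples_by_gene, h1, present)
        pool2 = _pool_half(samples_by_gene, h2, present)
        both = [c for c in present if c in pool1 and c in pool2]
        P1 = probability_rows([pool1[c] for c in both], bin_width, upper)
        P2 = probability_rows([pool2[c] for c in both], bin_width, upper)
        D = pairwise_histogram_distances(P1, metric, P2)
        rows = np.array([idx[c] for c in both])
        selfs[k, rows] = np.diag(D)
        crosses[np.ix_([k], rows, rows)] = D[None, :, :]
    out = {}
    for c in present:
        comp = comparison_set(c, restrict, present)
        if not comp:
            out[c] = DistinctnessResult(c, metric, float("nan"), np.empty(0), np.empty((0, 0)), [], n_partitions)
            continue
        cols = np.array([idx[x] for x in comp])
        cr = crosses[:, idx[c], cols]
        sf = selfs[:, idx[c]]
        valid = np.isfinite(cr) & np.isfinite(sf)[:, None]
        sf_b = np.broadcast_to(sf[:, None], cr.shape)
        p = float(np.mean(sf_b[valid] >= cr[valid]))
        out[c] = DistinctnessResult(c, metric, p, sf, cr, comp, n_partitions)
    return out


def samples_per_gene(pairs, region: tuple[int, int] | None = None) -> dict:
    """Build the ``gene_id -> {codon -> samples}`` map the distinctness test eats.

    ``pairs`` are (GeneProfile, NfcProfile); ``region`` restricts positions as
    in :func:`ribodist.nfc_core.pool_by_codon`.
    """
    from ribodist.nfc_core import pool_by_codon

    out = {}
    for gene, nfcp in pairs:
        css = pool_by_codon([(gene, nfcp)], region=region)
        if css.samples:
            out[gene.gene_id] = css.samples
    return out
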