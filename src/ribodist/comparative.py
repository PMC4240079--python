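"""Cross-organism comparison of NFC distributions.

Per codon, the distance between two organisms' pooled NFC distributions is
computed; averaging over codons yields an organism-by-organism distance
matrix, which is clustered with neighbor joining.  A rank-sum test asks
whether same-domain organism pairs (prokaryote/prokaryote or
eukaryote/eukaryote) are closer than cross-domain pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu

from ribodist.distmetrics import (
    DistanceMatrix,
    energy_distance,
    pairwise_histogram_distances,
    probability_rows,
)

logger = logging.getLogger(__name__)


def per_codon_matrices(
    organisms: dict,
    metric: str = "hellinger",
    bin_width: float = 0.05,
    upper: float = 5.0,
    seed: int = 0,
) -> tuple[list[str], dict[str, np.ndarray]]:
    """Organism-by-organism distance matrix for each shared codon.

    ``organisms`` maps label -> CodonSampleSet.  Codons missing from any
    organism are dropped (logged).  Returns the sorted label list and a
    ``codon -> matrix`` dict.
    """
    labels = sorted(organisms)
    if len(labels) < 2:
        raise ValueError("need >= 2 organisms")
    shared = set.intersection(*(set(organisms[o].samples) for o in labels))
    dropped = set.union(*(set(organisms[o].samples) for o in labels)) - shared
    if dropped:
        logger.info("cross-organism: %d codons missing somewhere dropped", len(dropped))
    if not shared:
        raise ValueError("no codon shared by all organisms")
    rng = np.random.default_rng(seed)
    out = {}
    for c in sorted(shared):
        arrs = [organisms[o].samples[c] for o in labels]
        if metric == "energy":
            D = np.zeros((len(labels), len(labels)))
            for i in range(len(labels)):
                for j in range(i + 1, len(labels)):
                    D[i, j] = D[j, i] = energy_distance(arrs[i], arrs[j], rng=rng)
        else:
            P = probability_rows(arrs, bin_width, upper)
            D = pairwise_histogram_distances(P, metric)
        out[c] = D
    return labels, out


def cross_organism_matrix(
    organisms: dict,
    metric: str = "hellinger",
    bin_width: float = 0.05,
    upper: float = 5.0,
    seed: int = 0,
) -> DistanceMatrix:
    """Mean over codons of the per-codon organism distance matrices."""
    labels, mats = per_codon_matrices(organisms, metric, bin_width, upper, seed)
    avg = np.mean([mats[c] for c in mats], axis=0)
    avg = (avg + avg.T) / 2.0
    np.fill_diagonal(avg, 0.0)
    return DistanceMatrix(labels, avg, metric)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("newick", "label")

    def __init__(self, newick: str, label: str):
        self.newick = newick  # newick fragment without trailing length
        self.label = label  # smallest leaf label in the subtree (tie-break key)


def neighbor_joining(d: DistanceMatrix, precision: int = 6) -> str:
    """Classic neighbor joining; returns an unrooted Newick tree string.

    The final three clusters are joined at a trifurcating root.  Q-matrix
    ties are broken by the lexicographically smallest pair of subtree labels.
    Negative branch lengths are clamped to 0 with the deficit moved to the
    sister branch (standard practice, logged).
    """
    if len(d.labels) < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    nodes = [_Node(lbl, lbl) for lbl in d.labels]
    D = d.values.astype(float).copy()
    n_clamped = 0

    def fmt(x: float) -> str:
        return f"{max(x, 0.0):.{precision}g}"

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        pairs = {tuple(sorted((int(i), int(j)))) for i, j in ties}
        i, j = min(pairs, key=lambda ij: tuple(sorted((nodes[ij[0]].label, nodes[ij[1]].label))))
        li = D[i, j] / 2 + (r[i] - r[j]) / (2 * (n - 2))
        lj = D[i, j] - li
        if li < 0:
            lj, li, n_clamped = D[i, j], 0.0, n_clamped + 1
        elif lj < 0:
            li, lj, n_clamped = D[i, j], 0.0, n_clamped + 1
        new = _Node(
            f"({nodes[i].newick}:{fmt(li)},{nodes[j].newick}:{fmt(lj)})",
            min(nodes[i].label, nodes[j].label),
        )
        dk = (D[i, :] + D[j, :] - D[i, j]) / 2
        keep = [k for k in range(n) if k not in (i, j)]
        D2 = np.empty((n - 1, n - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dk[keep]
        D2[-1, -1] = 0.0
        nodes = [nodes[k] for k in keep] + [new]
        D = D2

    (a, b, c) = range(3)
    la = (D[a, b] + D[a, c] - D[b, c]) / 2
    lb = (D[a, b] + D[b, c] - D[a, c]) / 2
    lc = (D[a, c] + D[b, c] - D[a, b]) / 2
    n_clamped += sum(x < 0 for x in (la, lb, lc))
    if n_clamped:
        logger.info("neighbor_joining: clamped %d negative branch length(s)", n_clamped)
    parts = sorted(zip((nodes[a], nodes[b], nodes[c]), (la, lb, lc)), key=lambda t: t[0].label)
    inner = ",".join(f"{nd.newick}:{fmt(L)}" for nd, L in parts)
    return f"({inner});"


def domain_similarity_test(
    d: DistanceMatrix, domains: dict[str, str], per_codon: dict[str, np.ndarray] | None = None
) -> tuple[float, float]:
    """One-sided rank-sum test that intra-domain distances are smaller.

    ``domains`` maps organism label -> domain (e.g. "prokaryote" /
    "eukaryote").  With ``per_codon`` matrices the test pools per-codon
    organism-pair distances (codons x pairs observations); otherwise it uses
    the averaged matrix's pairs.  Returns (Mann-Whitney U, p).
    """
    labels = d.labels
    doms = [domains[l] for l in labels]
    if len(set(doms)) < 2:
        raise ValueError("both domains must be represented")
    intra_idx, inter_idx = [], []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            (intra_idx if doms[i] == doms[j] else inter_idx).append((i, j))
    if not intra_idx:
        raise ValueError("no intra-domain organism pair exists")
    mats = list(per_codon.values()) if per_codon else [d.values]
    intra = np.array([m[i, j] for m in mats for i, j in intra_idx])
    inter = np.array([m[i, j] for m in mats for i, j in inter_idx])
    if np.ptp(np.concatenate([intra, inter])) == 0:
        return float(len(intra) * len(inter) / 2), 1.0  # no signal at all
    res = mannwhitneyu(intra, inter, alternative="less")
    return float(res.statistic), float(res.pvalue)
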