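"""Positional conservation of NFC distributions along the ORF.

Pipeline: pool per-codon NFC samples in 50-codon sliding windows over the
first/last ``span`` codons, compute the all-pairs window distance matrix per
codon, average the matrices over codons, average each column — the *mean
distance vector* — then scan it with a length-10 window and a two-sample
Wilcoxon rank-sum test to find where NFC distributions stop differing from
the rest of the ORF.  A parallel scan on the position-wise mean raw RC
profile separates distribution-shape changes from plain coverage ramps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu

from ribodist.distmetrics import energy_distance, pairwise_histogram_distances, probability_rows
from ribodist.nfc_core import CodonSampleSet
from ribodist.profile_io import CODON_TO_INDEX, SENSE_CODONS

logger = logging.getLogger(__name__)


@dataclass
class MeanDistanceVector:
    """Per-window mean distance to all other windows, averaged over codons."""

    start_positions: np.ndarray  # window start codon index, 1-based from the anchored end
    means: np.ndarray
    stds: np.ndarray
    metric: str
    window: int
    end: str

    def __post_init__(self):
        self.start_positions = np.asarray(self.start_positions, dtype=int)
        self.means = np.asarray(self.means, dtype=float)
        self.stds = np.asarray(self.stds, dtype=float)
        if not (self.start_positions.size == self.means.size == self.stds.size):
            raise ValueError("misaligned mean distance vector")
        if np.any(self.means < 0):
            raise ValueError("distances must be >= 0")


@dataclass
class BoundaryEstimate:
    """Wilcoxon-scan boundary: first scan window indistinguishable from the rest."""

    end: str
    boundary: int | None
    p_values: np.ndarray
    scan: int
    alpha: float
    found: bool


def window_sample_sets(
    pairs,
    end: str = "5p",
    span: int = 200,
    window: int = 50,
    step: int = 1,
    equalize_rc: bool = False,
    seed: int = 0,
    split_half: bool = True,
) -> list[CodonSampleSet]:
    """Per-codon NFC sample sets for each sliding window near one ORF end.

    Windows are anchored at positions 1 .. span-window+1 (1-based) from the
    chosen end; for the 3' end positions are counted from the stop codon
    inward (mirror order).  Genes shorter than a given window are skipped for
    that window.  With ``equalize_rc``, every codon is subsampled (seeded) to
    its minimum across-window count; codons absent from some window are
    dropped everywhere and marked absent.

    ``split_half`` assigns every (gene, position) once to half A or half B
    (seeded) and fills each window set's ``half_b``.  Overlapping windows
    share positions, so a distance between their plain sample sets is pulled
    down by the shared sampling noise; computing each pairwise distance as
    half A of one window against half B of the other gives every window pair
    — self-pairs included — the same noise floor instead.
    """
    if end not in ("5p", "3p"):
        raise ValueError("end must be '5p' or '3p'")
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no gene profiles supplied")
    G = len(pairs)
    # gene-by-position matrices over the first `span` positions from the end:
    # codon id (-1 = stop/excluded/beyond gene) and NFC value
    C = np.full((G, span), -1, dtype=np.int16)
    X = np.zeros((G, span))
    n_short = 0
    for gi, (gene, nfcp) in enumerate(pairs):
        J = gene.length
        k = min(span, J)
        if J < span:
            n_short += 1
        if end == "5p":
            codons = gene.codons[:k]
            nfc = nfcp.nfc[:k]
            pooled = nfcp.pooled[:k]
        else:
            codons = gene.codons[J - k :][::-1]
            nfc = nfcp.nfc[J - k :][::-1]
            pooled = nfcp.pooled[J - k :][::-1]
        ids = np.array([CODON_TO_INDEX.get(c, -1) for c in codons], dtype=np.int16)
        ids[~pooled] = -1
        C[gi, :k] = ids
        X[gi, :k] = np.where(pooled, np.nan_to_num(nfc), 0.0)
    if n_short:
        logger.info("window_sample_sets: %d genes shorter than span=%d", n_short, span)

    rng = np.random.default_rng(seed)
    halfmask = rng.random((G, span)) < 0.5 if split_half else None

    def bucket(cb, xb):
        keep = cb >= 0
        cb, xb = cb[keep], xb[keep]
        order = np.argsort(cb, kind="stable")
        cb, xb = cb[order], xb[order]
        bounds = np.searchsorted(cb, np.arange(62))
        return {
            SENSE_CODONS[ci]: xb[bounds[ci] : bounds[ci + 1]]
            for ci in range(61)
            if bounds[ci + 1] > bounds[ci]
        }

    starts = list(range(1, span - window + 2, step))
    sets: list[CodonSampleSet] = []
    for s in starts:
        cb = C[:, s - 1 : s + window - 1]
        xb = X[:, s - 1 : s + window - 1]
        if split_half:
            hm = halfmask[:, s - 1 : s + window - 1]
            samples = bucket(np.where(hm, cb, -1).ravel(), xb.ravel())
            other = bucket(np.where(hm, -1, cb).ravel(), xb.ravel())
        else:
            samples = bucket(cb.ravel(), xb.ravel())
            other = None
        sets.append(
            CodonSampleSet(samples, region=f"window=({s},{window})@{end}", n_genes=G, half_b=other)
        )

    if equalize_rc:
        halves = ["samples"] + (["half_b"] if split_half else [])
        for attr in halves:
            mins = {}
            for c in SENSE_CODONS:
                counts = [
                    getattr(ws, attr)[c].size if c in getattr(ws, attr) else 0 for ws in sets
                ]
                mins[c] = min(counts)
            dropped = [
                c for c, m in mins.items() if m == 0 and any(c in getattr(ws, attr) for ws in sets)
            ]
            if dropped:
                logger.info(
                    "window_sample_sets: %d codons absent from some window dropped under equalize_rc",
                    len(dropped),
                )
            for ws in sets:
                eq = {}
                for c, x in getattr(ws, attr).items():
                    m = mins[c]
                    if m == 0:
                        continue
                    eq[c] = x[rng.choice(x.size, size=m, replace=False)] if x.size > m else x
                setattr(ws, attr, eq)
    return sets


def mean_distance_vector(
    window_sets: list[CodonSampleSet],
    metric: str = "hellinger",
    bin_width: float = 0.05,
    upper: float = 5.0,
    end: str = "5p",
    seed: int = 0,
) -> MeanDistanceVector:
    """Average per-codon all-pairs window distance matrices into one vector.

    For each codon present anywhere, the (windows x windows) distance matrix
    is computed (entries where the codon is absent from either window are
    skipped); matrices are averaged entry-wise over codons, then each column
    (diagonal excluded) is averaged to give the vector, with the column
    standard deviation retained.
    """
    W = len(window_sets)
    if W < 2:
        raise ValueError("need >= 2 windows")
    if metric not in ("js", "hellinger", "energy"):
        raise ValueError(f"unknown metric {metric!r}")
    split = all(ws.half_b is not None for ws in window_sets)
    codons = sorted({c for ws in window_sets for c in ws.samples})
    sums = np.zeros((W, W))
    counts = np.zeros((W, W))
    rng = np.random.default_rng(seed)
    for c in codons:
        if split:
            present = np.array(
                [c in ws.samples and c in ws.half_b for ws in window_sets]
            )
        else:
            present = np.array([c in ws.samples for ws in window_sets])
        pid = np.flatnonzero(present)
        if pid.size < 2:
            continue
        arrs_a = [window_sets[i].samples[c] for i in pid]
        arrs_b = [window_sets[i].half_b[c] for i in pid] if split else arrs_a
        if metric == "energy":
            D = np.zeros((pid.size, pid.size))
            for a in range(pid.size):
                for b in range(pid.size):
                    if not split and b <= a:
                        continue
                    D[a, b] = energy_distance(arrs_a[a], arrs_b[b], rng=rng)
            if not split:
                D = D + D.T
        else:
            Pa = probability_rows(arrs_a, bin_width, upper)
            if split:
                Pb = probability_rows(arrs_b, bin_width, upper)
                D = pairwise_histogram_distances(Pa, metric, Pb)
            else:
                D = pairwise_histogram_distances(Pa, metric)
        if split:
            D = (D + D.T) / 2.0  # d(A_i,B_j) and d(A_j,B_i) estimate the same thing
        sums[np.ix_(pid, pid)] += D
        counts[np.ix_(pid, pid)] += 1
    with np.errstate(invalid="ignore"):
        avg = sums / counts
    try:
        starts_arr = np.array([int(ws.region.split("(")[1].split(",")[0]) for ws in window_sets])
        win_len = int(window_sets[0].region.split(",")[1].split(")")[0])
    except (IndexError, ValueError):
        starts_arr = np.arange(1, W + 1)
        win_len = 1
    off = ~np.eye(W, dtype=bool)
    means = np.empty(W)
    stds = np.empty(W)
    for k in range(W):
        col = avg[off[:, k], k]
        col = col[np.isfinite(col)]
        if col.size == 0:
            raise ValueError(f"window {k + 1} shares no codon with any other window")
        means[k] = col.mean()
        stds[k] = col.std()
    return MeanDistanceVector(starts_arr, means, stds, metric, win_len, end)


def _rank_scan(values: np.ndarray, positions: np.ndarray, scan: int, alpha: float, end: str) -> BoundaryEstimate:
    """Slide a length-`scan` window along `values`; the boundary is the start
    position of the first window whose two-sided rank-sum test against all
    remaining entries gives p > alpha.

    The test treats the vector's entries as exchangeable under the null.
    Entries of a mean distance vector built from heavily overlapping windows
    are *not* independent (neighbors share most of their samples), so at low
    sample counts the scan is approximate; see the package methods notes.
    """
    n = values.size
    if n <= scan + 5:
        raise ValueError("vector too short for the scan")
    pvals = np.empty(n - scan + 1)
    boundary = None
    found = False
    for k in range(n - scan + 1):
        inside = values[k : k + scan]
        outside = np.concatenate([values[:k], values[k + scan :]])
        if np.ptp(np.concatenate([inside, outside])) == 0:
            p = 1.0  # constant input: no evidence of any difference
        else:
            p = float(mannwhitneyu(inside, outside, alternative="two-sided").pvalue)
        pvals[k] = p
        if not found and p > alpha:
            boundary = int(positions[k])
            found = True
    if not found:
        logger.info("rank scan: every window significantly different (no boundary found)")
    return BoundaryEstimate(end, boundary, pvals, scan, alpha, found)


def detect_boundary(v: MeanDistanceVector, scan: int = 10, alpha: float = 0.05) -> BoundaryEstimate:
    """Locate where the mean distance vector stops differing from the rest."""
    return _rank_scan(v.means, v.start_positions, scan, alpha, v.end)


def mean_rc_profile(profiles, end: str = "5p", span: int = 200) -> np.ndarray:
    """Position-wise mean raw RC over genes of length >= span, from one end."""
    if end not in ("5p", "3p"):
        raise ValueError("end must be '5p' or '3p'")
    rows = []
    for p in profiles:
        if p.length >= span:
            rows.append(p.rc[:span] if end == "5p" else p.rc[-span:][::-1])
    if not rows:
        raise ValueError(f"no gene of length >= {span}")
    return np.vstack(rows).mean(axis=0)


def boundary_on_mean_rc(
    profiles, end: str = "5p", span: int = 200, scan: int = 10, alpha: float = 0.05
) -> BoundaryEstimate:
    """Run the same Wilcoxon scan directly on the averaged RC profile.

    Contrasting this boundary with :func:`detect_boundary`'s separates a
    coverage ramp (visible in mean RC) from a change in distribution *shape*
    (visible only in the NFC-distribution distances).
    """
    v = mean_rc_profile(profiles, end=end, span=span)
    return _rank_scan(v, np.arange(1, span + 1), scan, alpha, end)
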