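"""tRNA adaptation index (tAI) weights and feature/tRNA-proxy correlations.

The tAI assigns every sense codon a relative adaptiveness weight from the
genomic tRNA gene copy numbers: each codon's absolute weight W is the sum of
the copy numbers of the tRNAs that can read it, discounted by a selective
constraint s for each wobble pairing; w = W / max(W), and codons with W = 0
receive the geometric mean of the nonzero weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from ribodist.profile_io import SENSE_CODONS, STOP_CODONS, TrnaTable

logger = logging.getLogger(__name__)

#: published optimized wobble selective constraints (dos Reis et al. set);
#: keys name the codon:anticodon wobble pairing being discounted
DOS_REIS_S = {
    "WC": 0.0,      # Watson-Crick third-position pairing
    "G:U": 0.41,    # anticodon G34 reading a codon ending U
    "I:C": 0.28,    # inosine (from A34) reading a codon ending C
    "I:A": 0.9999,  # inosine reading a codon ending A
    "U:G": 0.68,    # anticodon U34 reading a codon ending G
}


@dataclass
class TaiWeights:
    """Relative adaptiveness weight per sense codon, max-normalized to 1."""

    weights: dict[str, float]
    s_values: dict[str, float]
    organism: str = "unknown"

    def __post_init__(self):
        w = np.array([self.weights[c] for c in SENSE_CODONS])
        if abs(w.max() - 1.0) > 1e-9 or np.any(w <= 0):
            raise ValueError("weights must be in (0, 1] with max exactly 1")


def compute_tai_weights(table: TrnaTable, s_values: dict[str, float] | None = None) -> TaiWeights:
    """Compute tAI relative adaptiveness weights from a tRNA copy-number table.

    Per four-codon box (third base varying over T/C/A/G), with t(c) the copy
    number of the tRNA whose anticodon Watson-Crick-matches codon c:

        W(..T) = (1-s_WC) t(..T) + (1-s_GU) t(..C)
        W(..C) = (1-s_WC) t(..C) + (1-s_IC) t(..T)
        W(..A) = (1-s_WC) t(..A) + (1-s_IA) t(..T)
        W(..G) = (1-s_WC) t(..G) + (1-s_UG) t(..A)

    Contributions referencing stop codons are zero (those tRNAs do not
    exist).  Doubling every copy number leaves the weights unchanged.
    """
    s = dict(DOS_REIS_S)
    if s_values:
        s.update(s_values)
    t = {c: float(table.copies.get(c, 0)) for c in SENSE_CODONS}
    for stop in STOP_CODONS:
        t[stop] = 0.0
    W = {}
    for c in SENSE_CODONS:
        box = c[:2]
        third = c[2]
        if third == "T":
            W[c] = (1 - s["WC"]) * t[box + "T"] + (1 - s["G:U"]) * t[box + "C"]
        elif third == "C":
            W[c] = (1 - s["WC"]) * t[box + "C"] + (1 - s["I:C"]) * t[box + "T"]
        elif third == "A":
            W[c] = (1 - s["WC"]) * t[box + "A"] + (1 - s["I:A"]) * t[box + "T"]
        else:
            W[c] = (1 - s["WC"]) * t[box + "G"] + (1 - s["U:G"]) * t[box + "A"]
    wmax = max(W.values())
    if wmax <= 0:
        raise ValueError("all-zero tRNA table: tAI undefined")
    w = {c: W[c] / wmax for c in SENSE_CODONS}
    nonzero = [x for x in w.values() if x > 0]
    if len(nonzero) < len(w):
        gm = float(np.exp(np.mean(np.log(nonzero))))
        n0 = 0
        for c in w:
            if w[c] == 0:
                w[c] = gm
                n0 += 1
        logger.info("compute_tai_weights: %d zero-weight codons set to geometric mean %.4g", n0, gm)
    return TaiWeights(w, s, organism=table.organism)


@dataclass
class CorrelationResult:
    """Spearman correlation of an NFC feature with a tRNA-level proxy."""

    feature: str
    r: float
    p: float
    n: int


def correlate_features(
    features: dict[str, float],
    proxy: dict[str, float],
    feature_name: str = "feature",
    exclude: tuple[str, ...] = (),
) -> CorrelationResult:
    """Spearman rank correlation between per-codon feature and proxy values.

    Codons missing either value are dropped (counted); ``exclude`` removes
    codons explicitly (e.g. ATG/TGG whose tAI weights are degenerate
    singletons).  A constant proxy gives an undefined correlation (NaN,
    flagged by a warning).
    """
    codons = sorted((set(features) & set(proxy)) - set(exclude))
    n_dropped = len(set(features) | set(proxy)) - len(codons)
    if n_dropped:
        logger.info("correlate_features: %d codons lacked a value and were dropped", n_dropped)
    if len(codons) < 10:
        raise ValueError(f"need >= 10 codons with both values, got {len(codons)}")
    x = np.array([features[c] for c in codons])
    y = np.array([proxy[c] for c in codons])
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        logger.warning("correlate_features: constant input, correlation undefined")
        return CorrelationResult(feature_name, float("nan"), float("nan"), len(codons))
    r, p = spearmanr(x, y)
    return CorrelationResult(feature_name, float(r), float(p), len(codons))
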