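"""NFC normalization and per-codon pooling.

The normalized footprint count of codon j in a gene is

    NFC_j = RC_j / mean(RC)

with the mean taken over the gene's *included* codons: positions outside the
first and last ``exclude_terminal`` codons whose RC is at least ``min_rc``.
Because mRNA level m and initiation rate B scale every RC in a gene equally
(RC_j proportional to m*B*T_j), the within-gene mean normalization cancels
both, leaving NFC_j proportional to T_j / mean(T): a within-gene relative
decoding time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ribodist.profile_io import CODON_TO_INDEX, GeneProfile, SENSE_CODONS

logger = logging.getLogger(__name__)


@dataclass
class NfcProfile:
    """Per-codon NFC values for one gene, with the inclusion mask.

    ``nfc`` is aligned to the gene's codons; excluded positions carry NaN
    (or 0 under the low-RC-as-zero sensitivity option).  ``included`` marks
    positions that entered the per-gene mean; ``pooled`` marks positions
    eligible for per-codon pooling (identical to ``included`` by default).
    """

    gene_id: str
    nfc: np.ndarray
    included: np.ndarray
    pooled: np.ndarray = None

    def __post_init__(self):
        self.nfc = np.asarray(self.nfc, dtype=float)
        self.included = np.asarray(self.included, dtype=bool)
        if self.pooled is None:
            self.pooled = self.included.copy()
        self.pooled = np.asarray(self.pooled, dtype=bool)
        if not (self.nfc.size == self.included.size == self.pooled.size):
            raise ValueError(f"gene {self.gene_id}: misaligned NFC arrays")


@dataclass
class CodonSampleSet:
    """Pooled NFC samples keyed by sense codon.

    The object every distance/fit operation consumes.  ``samples`` maps each
    *present* sense codon to a 1-D array of NFC values pooled across genes.
    """

    samples: dict[str, np.ndarray]
    organism: str | None = None
    region: str = "all"
    n_genes: int = 0
    #: optional second half of a global sample split (see positional module):
    #: when present, `samples` is half A and `half_b` is half B
    half_b: dict[str, np.ndarray] | None = None

    def __post_init__(self):
        for c, x in list(self.samples.items()):
            if c not in CODON_TO_INDEX:
                raise ValueError(f"non-sense codon {c!r} in sample set")
            x = np.asarray(x, dtype=float)
            if np.any(x < 0):
                raise ValueError(f"negative NFC sample for codon {c}")
            self.samples[c] = x

    @property
    def codons(self) -> list[str]:
        return sorted(self.samples)

    def counts(self) -> dict[str, int]:
        return {c: x.size for c, x in self.samples.items()}

    @property
    def total(self) -> int:
        return sum(x.size for x in self.samples.values())


def compute_nfc(
    profile: GeneProfile,
    exclude_terminal: int = 20,
    min_rc: float = 1.0,
    low_rc_as_zero: bool = False,
) -> NfcProfile | None:
    """Normalize one gene's RC profile to NFC.

    Included positions are those in ``[exclude_terminal+1, J-exclude_terminal]``
    (1-based, inclusive) with ``rc >= min_rc``; the mean is computed over them
    and NFC_j = RC_j / mean for each included j.  Returns ``None`` (gene
    dropped, logged) when the gene is shorter than ``2*exclude_terminal + 1``
    codons or no codon survives the filters.

    ``low_rc_as_zero`` is a sensitivity option: inner positions below
    ``min_rc`` stay out of the mean but enter pooling with NFC 0.
    """
    J = profile.length
    if J <= 2 * exclude_terminal:
        logger.info("gene %s dropped: %d codons too short for terminal exclusion", profile.gene_id, J)
        return None
    inner = np.zeros(J, dtype=bool)
    inner[exclude_terminal : J - exclude_terminal] = True
    included = inner & (profile.rc >= min_rc)
    if not included.any():
        logger.info("gene %s dropped: no codon passes the RC >= %g filter", profile.gene_id, min_rc)
        return None
    mean_rc = profile.rc[included].mean()
    nfc = np.full(J, np.nan)
    nfc[included] = profile.rc[included] / mean_rc
    pooled = included.copy()
    if low_rc_as_zero:
        low = inner & ~included
        nfc[low] = 0.0
        pooled |= low
    return NfcProfile(profile.gene_id, nfc, included, pooled)


def compute_nfc_profiles(
    profiles, exclude_terminal: int = 20, min_rc: float = 1.0, low_rc_as_zero: bool = False
) -> list[tuple[GeneProfile, NfcProfile]]:
    """Normalize a collection of genes, dropping (and counting) failures."""
    out = []
    for p in profiles:
        n = compute_nfc(p, exclude_terminal, min_rc, low_rc_as_zero)
        if n is not None:
            out.append((p, n))
    n_dropped = len(list(profiles)) - len(out)
    if n_dropped:
        logger.info("compute_nfc_profiles: %d of %d genes dropped", n_dropped, len(out) + n_dropped)
    return out


def _window_positions(J: int, window: tuple[int, int], end: str) -> tuple[int, int]:
    """1-based inclusive (lo, hi) codon positions for a (start, length) window."""
    start, length = window
    if end == "5p":
        return start, start + length - 1
    if end == "3p":
        # position counted from the stop codon inward: i' = J - i + 1
        return J - start - length + 2, J - start + 1
    raise ValueError("end must be '5p' or '3p'")


def pool_by_codon(
    pairs,
    region: tuple[int, int] | None = None,
    window: tuple[int, int] | None = None,
    end: str = "5p",
    organism: str | None = None,
) -> CodonSampleSet:
    """Pool NFC samples per sense codon over a configurable ORF region.

    ``pairs`` is an iterable of ``(GeneProfile, NfcProfile)``.  With neither
    ``region`` nor ``window``, all pooled positions contribute.  ``region``
    = (start_offset_5p, end_offset_3p) keeps positions
    ``start_offset_5p+1 .. J-end_offset_3p``; ``window`` = (start, length)
    keeps a fixed-length window anchored at the given ``end``.  Genes too
    short for the requested region are skipped with a log entry.
    """
    if region is not None and window is not None:
        raise ValueError("give at most one of region= and window=")
    samples: dict[str, list[np.ndarray]] = {c: [] for c in SENSE_CODONS}
    n_genes = 0
    n_skipped = 0
    for gene, nfcp in pairs:
        J = gene.length
        if region is not None:
            lo, hi = region[0] + 1, J - region[1]
        elif window is not None:
            lo, hi = _window_positions(J, window, end)
        else:
            lo, hi = 1, J
        if lo < 1 or hi > J or lo > hi:
            n_skipped += 1
            continue
        mask = nfcp.pooled.copy()
        mask[: lo - 1] = False
        mask[hi:] = False
        if not mask.any():
            continue
        n_genes += 1
        idx = np.flatnonzero(mask)
        for j in idx:
            c = gene.codons[j]
            if c in CODON_TO_INDEX:
                samples[c].append(nfcp.nfc[j])
    if n_skipped:
        logger.info("pool_by_codon: %d genes shorter than the requested region", n_skipped)
    desc = (
        f"region={region}" if region is not None
        else f"window={window}@{end}" if window is not None
        else "all"
    )
    out = {c: np.asarray(v, dtype=float) for c, v in samples.items() if len(v)}
    return CodonSampleSet(out, organism=organism, region=desc, n_genes=n_genes)


def subsample_equal(samples: CodonSampleSet, n: int, seed: int = 0, rng=None) -> CodonSampleSet:
    """Draw exactly ``n`` samples per present codon, without replacement.

    ``n`` above the smallest codon count is lowered to that count (logged);
    ``n`` below 10 triggers a warning (distribution estimates get unstable).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    counts = samples.counts()
    if not counts:
        raise ValueError("empty sample set")
    m = min(counts.values())
    if n > m:
        logger.info("subsample_equal: n lowered from %d to min codon count %d", n, m)
        n = m
    if n < 10:
        logger.warning("subsample_equal: n=%d is very small; estimates will be unstable", n)
    out = {}
    for c in sorted(samples.samples):
        x = samples.samples[c]
        out[c] = x[rng.choice(x.size, size=n, replace=False)]
    return CodonSampleSet(out, organism=samples.organism, region=samples.region, n_genes=samples.n_genes)
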