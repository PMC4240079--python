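"""Readers/writers for ORF sequences, footprint-count profiles and tRNA tables.

File dialects
-------------
* ORF sequences: FASTA of nucleotide coding sequences (DNA or RNA alphabet),
  in frame from the start codon, length divisible by 3.
* RC profiles: TSV with a header line ``gene_id<TAB>codon_index<TAB>rc``;
  ``codon_index`` is 1-based from the start codon, missing indices mean RC 0.
* tRNA tables: TSV with header ``codon<TAB>copies`` covering the 61 sense
  codons (missing codons are taken as 0 copies, with a warning).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

BASES = "ACGT"
ALL_CODONS = tuple(a + b + c for a in BASES for b in BASES for c in BASES)
STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)
#: stable integer index of each sense codon, used for vectorized pooling
CODON_TO_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}

_CODON_RE = re.compile(r"^[ACGT]{3}$")


@dataclass
class GeneProfile:
    """One ORF: its codon sequence and the raw footprint count per codon.

    Codon indices are 1-based from the start codon throughout the package.
    RC values are non-negative reals (weighted multi-mapping upstream may
    produce fractional counts).
    """

    gene_id: str
    codons: list[str]
    rc: np.ndarray

    def __post_init__(self):
        self.codons = [str(c).upper() for c in self.codons]
        self.rc = np.asarray(self.rc, dtype=float)
        if self.rc.ndim != 1 or self.rc.size != len(self.codons):
            raise ValueError(
                f"gene {self.gene_id}: rc length {self.rc.size} != "
                f"{len(self.codons)} codons"
            )
        if len(self.codons) < 1:
            raise ValueError(f"gene {self.gene_id}: empty profile")
        if np.any(self.rc < 0) or not np.all(np.isfinite(self.rc)):
            raise ValueError(f"gene {self.gene_id}: rc values must be finite and >= 0")
        for c in self.codons:
            if not _CODON_RE.match(c):
                raise ValueError(f"gene {self.gene_id}: invalid codon {c!r}")

    @property
    def length(self) -> int:
        """Number of codons J."""
        return len(self.codons)


@dataclass
class TrnaTable:
    """tRNA gene copy number per sense codon for one organism.

    ``copies[c]`` is the genomic copy number of the tRNA whose anticodon is
    the Watson–Crick partner of codon ``c``.
    """

    copies: dict[str, int]
    organism: str = "unknown"

    def __post_init__(self):
        keys = set(self.copies)
        missing = set(SENSE_CODONS) - keys
        extra = keys - set(SENSE_CODONS)
        if extra:
            raise ValueError(f"tRNA table has non-sense-codon keys: {sorted(extra)}")
        for c in missing:
            self.copies[c] = 0
        for c, n in self.copies.items():
            if n < 0:
                raise ValueError(f"tRNA table: negative copy number for {c}")


def _to_codons(seq: str, gene_id: str) -> list[str]:
    s = str(seq).upper().replace("U", "T")
    if len(s) % 3 != 0:
        raise ValueError(f"gene {gene_id}: sequence length {len(s)} not divisible by 3")
    if not re.fullmatch(r"[ACGT]*", s):
        bad = sorted(set(s) - set(BASES))
        raise ValueError(f"gene {gene_id}: non-ACGTU characters {bad}")
    return [s[i : i + 3] for i in range(0, len(s), 3)]


def read_orfs(path, on_error: str = "raise") -> dict[str, list[str]]:
    """Read ORF nucleotide sequences from FASTA into ``gene_id -> codon list``.

    Sequences are upper-cased, U is mapped to T, and split into codons in
    frame from position 1.  ``on_error`` is ``"raise"`` (abort on a bad
    record) or ``"skip"`` (drop the record with a log entry).
    """
    if on_error not in ("raise", "skip"):
        raise ValueError("on_error must be 'raise' or 'skip'")
    orfs: dict[str, list[str]] = {}
    n_skipped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            orfs[rec.id] = _to_codons(str(rec.seq), rec.id)
        except ValueError:
            if on_error == "raise":
                raise
            n_skipped += 1
            logger.warning("skipping malformed ORF record %s", rec.id)
    if n_skipped:
        logger.info("read_orfs: skipped %d malformed records", n_skipped)
    return orfs


def read_rc_profiles(path, orfs: dict[str, list[str]]) -> list[GeneProfile]:
    """Read an RC profile TSV and join with ORF sequences into GeneProfiles.

    Rows are ``gene_id, codon_index (1-based), rc``; missing indices mean
    RC 0, so sparse files are fine.  Genes present in only one of the two
    inputs are dropped with a log entry.  Negative RC values or a codon
    index beyond the ORF length abort with the gene named.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    required = {"gene_id", "codon_index", "rc"}
    if not required.issubset(df.columns):
        raise ValueError(f"profile TSV must have columns {sorted(required)}")
    if (df["rc"] < 0).any():
        bad = df.loc[df["rc"] < 0, "gene_id"].iloc[0]
        raise ValueError(f"negative rc value in gene {bad}")

    profiles: list[GeneProfile] = []
    seen = set()
    for gene_id, sub in df.groupby("gene_id", sort=True):
        seen.add(gene_id)
        if gene_id not in orfs:
            logger.warning("gene %s in profile TSV but not in ORF FASTA; dropped", gene_id)
            continue
        codons = orfs[gene_id]
        J = len(codons)
        idx = sub["codon_index"].to_numpy(dtype=int)
        if idx.min() < 1 or idx.max() > J:
            raise ValueError(
                f"gene {gene_id}: codon_index out of range 1..{J} "
                f"(found {idx.min()}..{idx.max()})"
            )
        rc = np.zeros(J)
        rc[idx - 1] = sub["rc"].to_numpy(dtype=float)
        profiles.append(GeneProfile(gene_id, codons, rc))
    only_fasta = set(orfs) - seen
    if only_fasta:
        logger.info(
            "read_rc_profiles: %d ORFs had no profile rows and were dropped",
            len(only_fasta),
        )
    return profiles


def write_rc_profiles(profiles, path, included=None) -> None:
    """Write GeneProfiles to the TSV profile dialect.

    When ``included`` (a mapping ``gene_id -> bool mask``) is given an extra
    ``included`` column is emitted, which is how NFC profiles are exported.
    """
    rows = []
    for p in profiles:
        for j in range(p.length):
            row = {"gene_id": p.gene_id, "codon_index": j + 1, "rc": p.rc[j]}
            if included is not None:
                row["included"] = int(bool(included[p.gene_id][j]))
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_trna_table(path, organism: str = "unknown") -> TrnaTable:
    """Read a ``codon<TAB>copies`` TSV into a :class:`TrnaTable`.

    Missing sense codons are set to 0 copies with a warning; duplicated codon
    rows abort.
    """
    df = pd.read_csv(path, sep="\t", dtype={"codon": str})
    if not {"codon", "copies"}.issubset(df.columns):
        raise ValueError("tRNA table TSV must have columns codon, copies")
    codons = df["codon"].str.upper().str.replace("U", "T")
    dup = codons[codons.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate codon rows in tRNA table: {sorted(set(dup))}")
    copies = dict(zip(codons, df["copies"].astype(int)))
    missing = set(SENSE_CODONS) - set(copies)
    if missing:
        logger.warning(
            "tRNA table missing %d sense codons (set to 0): %s",
            len(missing),
            sorted(missing),
        )
    return TrnaTable(copies={c: copies.get(c, 0) for c in SENSE_CODONS}, organism=organism)
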