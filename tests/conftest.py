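import numpy as np
import pytest

from ribodist.profile_io import SENSE_CODONS, GeneProfile
from ribodist.nfc_core import NfcProfile


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n{seq}\n")
    return path


def write_profile_tsv(path, rows):
    with open(path, "w") as fh:
        fh.write("gene_id\tcodon_index\trc\n")
        for gene_id, idx, rc in rows:
            fh.write(f"{gene_id}\t{idx}\t{rc}\n")
    return path


def write_trna_tsv(path, copies):
    with open(path, "w") as fh:
        fh.write("codon\tcopies\n")
        for codon, n in copies.items():
            fh.write(f"{codon}\t{n}\n")
    return path


def lognormal_pairs(n_genes, gene_length, mu=0.0, sigma=0.4, seed=0):
    """Synthetic (GeneProfile, NfcProfile) pairs with iid log-normal NFC."""
    rng = np.random.default_rng(seed)
    body = np.array(SENSE_CODONS)
    out = []
    for g in range(n_genes):
        codons = list(body[rng.integers(0, 61, size=gene_length)])
        nfc = rng.lognormal(mu, sigma, size=gene_length)
        nfc /= nfc.mean()
        gp = GeneProfile(f"g{g}", codons, nfc * 10)
        out.append((gp, NfcProfile(gp.gene_id, nfc, np.ones(gene_length, bool))))
    return out
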