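"""Continuous-time TASEP translation simulator and synthetic-data generators.

The simulator is a kinetic Monte Carlo (Gillespie) realization of the totally
asymmetric simple exclusion process with extended particles: a ribosome whose
P-site sits at codon j hops to j+1 at rate 1/T_j, but only when the codon
l positions downstream is not covered by the next ribosome's footprint;
initiation occurs at rate B while the first l codons are free.  Sporadic
translational pauses multiply a decoding event's mean dwell by a constant
factor with small probability.  RC output is the time-integrated P-site
occupancy after a burn-in, scaled to read-count-like magnitudes (an optional
snapshot mode emulates finite-read sampling instead).

Simple parametric log-normal generators provide unit-level fixtures for the
distribution and positional machinery.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from ribodist.nfc_core import CodonSampleSet, NfcProfile
from ribodist.profile_io import GeneProfile, SENSE_CODONS

logger = logging.getLogger(__name__)


@dataclass
class TasepConfig:
    """Simulator parameterization.

    Defaults define the package's standard synthetic study conditions:
    50 genes of 300 codons, per-codon mean decoding times T_j log-uniform
    over one order of magnitude [1, 10] (arbitrary time units), footprint
    l = 10 codons, initiation rate B = 0.003 (about half the maximal
    sustainable current through the slowest codon, giving a realistic ~12%
    footprint coverage with visible traffic jams), pauses with probability
    0.01 per decoding event and a 10-fold dwell multiplier.  RC is extracted
    by default as 1000 snapshot draws of ribosome positions (footprint
    sampling, ~10 reads per codon, zeros possible — which is what the
    RC < 1 analysis filter exists for); ``mode="expected"`` switches to the
    noise-free time-integrated occupancy.
    """

    n_genes: int = 50
    gene_length: int = 300
    codon_times: dict[str, float] | None = None
    initiation_rate: float = 0.003
    mrna_copies: int = 1
    ribosome_size: int = 10
    pause_prob: float = 0.01
    pause_factor: float = 10.0
    horizon: float = 40_000.0
    burn_in: float = 4_000.0
    coverage: float = 5_000.0
    mode: str = "snapshot"  # "snapshot" (finite-read sampling) or "expected" (time-integrated occupancy)
    n_snapshots: int = 1_000
    seed: int = 0

    def __post_init__(self):
        if self.initiation_rate <= 0 or self.coverage <= 0:
            raise ValueError("rates and coverage must be > 0")
        if self.codon_times is not None and any(t <= 0 for t in self.codon_times.values()):
            raise ValueError("codon decoding times must be > 0")
        if self.ribosome_size < 1:
            raise ValueError("ribosome footprint must cover >= 1 codon")
        if not 0 <= self.pause_prob <= 1:
            raise ValueError("pause_prob must be in [0, 1]")
        if self.pause_factor <= 0:
            raise ValueError("pause_factor must be > 0")
        if self.horizon <= self.burn_in:
            raise ValueError("horizon must exceed burn_in")
        if self.mrna_copies < 1 or self.n_genes < 1 or self.gene_length < 1:
            raise ValueError("counts must be >= 1")
        if self.mode not in ("expected", "snapshot"):
            raise ValueError("mode must be 'expected' or 'snapshot'")


@dataclass
class TasepResult:
    """Simulated GeneProfiles plus the generating truth."""

    profiles: list[GeneProfile]
    codon_times: dict[str, float]
    config: TasepConfig


def default_codon_times(rng) -> dict[str, float]:
    """Log-uniform mean decoding times over [1, 10] for the 61 sense codons."""
    return {c: float(10 ** rng.uniform(0.0, 1.0)) for c in SENSE_CODONS}


def simulate_gene(
    codon_sequence,
    config: TasepConfig,
    rng,
    codon_times: dict[str, float] | None = None,
    debug: bool = False,
) -> np.ndarray:
    """Simulate one mRNA lattice and return its RC vector.

    ``codon_times`` overrides ``config.codon_times``; codons missing from the
    map (e.g. the stop codon) dwell for the geometric mean of the sense-codon
    times.  With ``debug`` the hard-core exclusion invariant is asserted at
    every event.
    """
    tmap = codon_times if codon_times is not None else config.codon_times
    if tmap is None:
        raise ValueError("no codon decoding times supplied")
    ell = config.ribosome_size
    L = len(codon_sequence)
    if L <= ell:
        raise ValueError(f"gene of {L} codons not longer than the footprint ({ell})")
    default_t = math.exp(np.mean([math.log(t) for t in tmap.values()]))
    T = np.array([tmap.get(c, default_t) for c in codon_sequence], dtype=float)
    B = config.initiation_rate
    horizon, burn_in = config.horizon, config.burn_in

    def draw_teff(j: int) -> float:
        t = T[j]
        if config.pause_prob and rng.random() < config.pause_prob:
            t *= config.pause_factor
        return t

    occ = np.zeros(L)
    pos: list[int] = []  # ascending P-site codon indices (0-based)
    teff: list[float] = []
    arr: list[float] = []
    t = 0.0
    n_completed = 0

    snap_times = None
    snap_counts = None
    if config.mode == "snapshot":
        snap_times = np.sort(rng.uniform(burn_in, horizon, size=config.n_snapshots))
        snap_counts = np.zeros(L)
        snap_ptr = 0

    def accrue(j: int, a: float, b: float) -> None:
        lo, hi = max(a, burn_in), min(b, horizon)
        if hi > lo:
            occ[j] += hi - lo

    while True:
        R = len(pos)
        rates = []
        total = 0.0
        for i in range(R):
            movable = (i == R - 1) or (pos[i + 1] - pos[i] > ell)
            rate = 1.0 / teff[i] if movable else 0.0
            rates.append(rate)
            total += rate
        init_ok = R == 0 or pos[0] >= ell
        if init_ok:
            total += B
        if total <= 0:
            raise RuntimeError("stalled simulation: no enabled event")
        dt = rng.exponential(1.0 / total)
        tnew = t + dt
        if snap_times is not None:
            while snap_ptr < snap_times.size and snap_times[snap_ptr] < min(tnew, horizon):
                for p in pos:
                    snap_counts[p] += 1
                snap_ptr += 1
        if tnew >= horizon:
            break
        t = tnew
        u = rng.random() * total
        acc = 0.0
        chosen = None
        for i in range(R):
            acc += rates[i]
            if u < acc:
                chosen = i
                break
        if chosen is None:
            # initiation
            pos.insert(0, 0)
            teff.insert(0, draw_teff(0))
            arr.insert(0, t)
        else:
            j = pos[chosen]
            accrue(j, arr[chosen], t)
            if j == L - 1:  # termination
                pos.pop(chosen)
                teff.pop(chosen)
                arr.pop(chosen)
                n_completed += 1
            else:
                pos[chosen] = j + 1
                teff[chosen] = draw_teff(j + 1)
                arr[chosen] = t
        if debug:
            for a, b in zip(pos, pos[1:]):
                # footprints [a, a+l-1] and [b, b+l-1] are disjoint iff b-a >= l
                assert b - a >= ell, "ribosome footprints overlap"

    for i in range(len(pos)):
        accrue(pos[i], arr[i], horizon)
    if n_completed == 0:
        raise RuntimeError(
            f"horizon {horizon} too short: no ribosome completed elongation "
            f"(B={B}, L={L})"
        )

    m = config.mrna_copies
    if config.mode == "snapshot":
        return snap_counts * m
    return occ / (horizon - burn_in) * config.coverage * m


def generate_dataset(config: TasepConfig) -> TasepResult:
    """Simulate ``n_genes`` random-sequence genes under one decoding-time map.

    Sequences are ATG + uniform random sense codons + TAA; the same seeded
    T_j map (log-uniform over [1, 10] unless supplied) is shared by all
    genes and returned as the truth.
    """
    rng = np.random.default_rng(config.seed)
    tmap = config.codon_times if config.codon_times is not None else default_codon_times(rng)
    profiles = []
    body = np.array(SENSE_CODONS)
    for g in range(config.n_genes):
        mid = list(body[rng.integers(0, 61, size=config.gene_length - 2)])
        codons = ["ATG"] + mid + ["TAA"]
        rc = simulate_gene(codons, config, rng, codon_times=tmap)
        profiles.append(GeneProfile(f"sim{g + 1:04d}", codons, rc))
    return TasepResult(profiles, tmap, replace(config, codon_times=dict(tmap)))


def parametric_nfc_generator(params: dict, n_per_codon: int, seed: int = 0) -> CodonSampleSet:
    """Log-normal NFC draws per codon: ``params[codon] = (mu, sigma)``."""
    if n_per_codon < 1:
        raise ValueError("n_per_codon must be >= 1")
    rng = np.random.default_rng(seed)
    samples = {}
    for c in sorted(params):
        mu, sigma = params[c]
        if sigma <= 0:
            raise ValueError(f"sigma must be > 0 (codon {c})")
        samples[c] = rng.lognormal(mu, sigma, size=n_per_codon)
    return CodonSampleSet(samples, region="parametric", n_genes=0)


def positional_shift_generator(
    mu: float = 0.0,
    sigma: float = 0.4,
    shift_len: int = 76,
    delta_mu: float = 0.3,
    n_genes: int = 500,
    gene_length: int = 400,
    seed: int = 0,
    end: str = "5p",
) -> list[tuple[GeneProfile, NfcProfile]]:
    """Synthetic profiles with a planted NFC-distribution shift near one end.

    The ``shift_len`` codons nearest the chosen end draw NFC from
    log-normal(mu + delta_mu, sigma), the rest from log-normal(mu, sigma);
    each gene is renormalized to mean NFC 1.  RC is set to 10x NFC so the
    mean-RC scan sees the same positional structure the NFC values carry.
    """
    if shift_len >= gene_length / 2:
        raise ValueError("shift region must cover less than half the gene")
    if end not in ("5p", "3p"):
        raise ValueError("end must be '5p' or '3p'")
    rng = np.random.default_rng(seed)
    body = np.array(SENSE_CODONS)
    mus = np.full(gene_length, mu)
    if shift_len > 0:
        if end == "5p":
            mus[:shift_len] += delta_mu
        else:
            mus[-shift_len:] += delta_mu
    out = []
    for g in range(n_genes):
        codons = list(body[rng.integers(0, 61, size=gene_length)])
        nfc = rng.lognormal(mus, sigma)
        nfc /= nfc.mean()
        gp = GeneProfile(f"shift{g + 1:04d}", codons, nfc * 10.0)
        np_ = NfcProfile(gp.gene_id, nfc, np.ones(gene_length, dtype=bool))
        out.append((gp, np_))
    return out
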