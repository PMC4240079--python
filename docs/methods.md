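# Methods notes

This note documents the models, estimators and numerical choices behind
`ribodist`, what the synthetic-data generator does and does not emulate, and
the known limitations of each procedure.

## NFC normalization

For a gene of J codons with footprint read counts RC_j, the normalized
footprint count is NFC_j = RC_j / mean(RC), with the mean taken over
*included* codons: positions outside the first and last `exclude_terminal`
codons (default 20, where coverage is systematically atypical) whose RC is at
least `min_rc` (default 1; sub-read positions would bias the mean and carry
no usable signal). Under the proportionality RC_j ∝ m·B·T_j (mRNA level m,
initiation rate B, decoding time T_j), the within-gene mean cancels m and B
exactly, so NFC_j estimates T_j / mean(T).

Choices:

- Positions failing the RC filter are excluded from **both** the mean and the
  pooling. Whether they should re-enter pooling as NFC = 0 is a genuinely
  open choice; `low_rc_as_zero=True` enables it for sensitivity analysis
  (default off, since a zero is a statement about sampling depth, not speed).
- Genes shorter than 2·`exclude_terminal`+1 codons, or with no surviving
  position, are dropped and counted.
- When a sliding window restricts pooling (positional analysis), the per-gene
  mean is still computed once over the full inner region: normalization is a
  property of the gene, windows only select which positions are pooled.
- Stop codons stay in `GeneProfile` but are never pooled; tRNA-based analyses
  are undefined for them.

## Distribution characterization

Histograms use uniform 0.05-wide bins on [0, 5] plus one overflow bin; the
**mode** is the midpoint of the tallest finite bin (ties go to the lowest
bin). The bin width is a compromise between resolution and stability at a
few hundred samples per codon and is configurable everywhere it appears.

Thirteen candidate families are fitted by maximum likelihood: beta,
Birnbaum–Saunders, extreme value, generalized extreme value, inverse
Gaussian, logistic, log-logistic, log-normal, Nakagami, normal, Rayleigh,
Rician, and t location-scale. The registry is extensible
(`distfit.register_family`). Log-normal, normal and Rayleigh use closed-form
MLEs; the rest use scipy's numeric MLE with location pinned at 0 for
positive-support families. The beta family requires support [0, 1], so
samples are scaled by 1/max and the log-likelihood is Jacobian-corrected by
−n·log(max) to stay comparable. Selection is by raw maximized
log-likelihood with no parameter-count penalty — faithful to a plain
maximum-likelihood criterion rather than statistically ideal; note the
likelihoods are only comparable when every family saw the same samples
(positive-support families drop zeros, which is logged). Optimizer failures
and degenerate (constant) samples are recorded as failed fits, not errors.

Log-normal features, in closed form from the fitted (μ, σ): mean
e^(μ+σ²/2), median e^μ, skewness (e^(σ²)+2)·√(e^(σ²)−1).

## Distances and the distinctness test

Jensen–Shannon (base-2 logarithm, metric form √JSD) and Hellinger distances
operate on shared-bin histograms and live in [0, 1]; the energy distance
√(2E|X−Y| − E|X−X′| − E|Y−Y′|) operates on raw samples (subsampled to
20 000 per side, seeded, when pair counts would exceed 4·10⁸). The base and
√ convention for JS were chosen so all three report on a comparable scale.

The distinctness test splits genes into two equal halves (⌊n/2⌋/⌈n/2⌉ for
odd n), 100 times by default. Per partition, the self-distance
d(c@half1, c@half2) is compared against cross-distances d(c@half1, c′@half2)
for every comparison codon c′ (all others, synonymous only, or
nucleotide-composition anagrams). The reported p is the fraction of
(partition, c′) pairs with self ≥ cross — a one-sided empirical exceedance
test that a codon is closer to itself than to other codons; p < 0.01 is
declared distinct. This p-value construction is this package's own
definition of the test; partitions in which the codon is missing from a half
are redrawn (logged).

## Positional analysis

Per-codon NFC distributions are computed in 50-codon windows sliding one
codon at a time over the first/last 200 codons (151 windows per end; 3′
windows are counted from the stop codon inward). For each codon the
all-pairs window distance matrix is computed; matrices are averaged over
codons, then each column (diagonal excluded) is averaged into the **mean
distance vector**, whose k-th entry is the average distance between window
k's distributions and all other windows'.

Because step-1 windows overlap by 49/50 codons, two overlapping windows share
most of their samples, which systematically shrinks their estimated distance
and inflates the column means of edge windows. The package therefore splits
samples once per (gene, position) into two halves (seeded) and computes every
pairwise distance as half-A of one window versus half-B of the other,
symmetrized; every entry — self-pairs included — then carries the same
sampling-noise floor. The paper-literal plain mode is available
(`split_half=False`) and is appropriate when sample counts are large enough
that the floor is negligible.

The boundary scan slides a length-10 window along the vector and compares the
values inside against all remaining entries with a two-sided Mann–Whitney
rank-sum test; the boundary is the start position of the first window with
p > 0.05 (constant input returns p = 1, where scipy's statistic degenerates).
A parallel scan on the position-wise mean raw RC profile distinguishes a
plain coverage ramp from a change in distribution shape.

Known limitations, measured on planted data and relevant to interpreting
boundaries at modest data sizes:

- The rank test assumes exchangeable vector entries. Entries of a step-1
  sliding-window vector are strongly correlated (neighboring windows share
  samples and reference windows), so at a few hundred genes the scan's null
  behavior is approximate: smooth noise excursions can delay the stop. At
  the data sizes of real multi-thousand-gene datasets the noise floor is far
  below the signal and this effect is negligible.
- A sharp, uniform shift region longer than the window length cannot be
  localized to ±10 codons: the 50-codon windows smear the step across 50
  start positions, mixture windows fall *below* the baseline columns in the
  all-pairs average (baseline windows still "see" the distant shifted head),
  and the rank test against all remaining entries saturates near the
  vector's ~30th percentile. Planted steps of length 30 are recovered
  within ±10; lengths 60 and 90 are reported near 45, at any gene count.
  Real positional effects decay gradually rather than stepping, which is the
  regime the scan behaves well in.

## Cross-organism comparison

Per shared codon, an organism × organism distance matrix is computed from
the pooled NFC samples; matrices are averaged over codons. Neighbor joining
is implemented directly: Q-matrix ties are broken by the lexicographically
smallest pair of subtree labels, negative branch lengths are clamped to zero
with the deficit moved to the sister branch (logged), and the final three
clusters join at a trifurcating root; Newick output carries 6-significant-
digit branch lengths. The domain test pools per-codon organism-pair
distances and applies a one-sided rank-sum test that intra-domain pairs are
closer than inter-domain pairs.

## tAI weights

Standard wobble bookkeeping with the published optimized selective
constraints (s_G:U = 0.41, s_I:C = 0.28, s_I:A = 0.9999, s_U:G = 0.68;
Watson–Crick s = 0), overridable per call. With t(c) the copy number of the
tRNA whose anticodon Watson–Crick-matches codon c, each four-codon box
contributes W(..T) = t(..T) + 0.59·t(..C), W(..C) = t(..C) + 0.72·t(..T),
W(..A) = t(..A) + 0.0001·t(..T), W(..G) = t(..G) + 0.32·t(..A); terms
referencing stop codons are zero. Weights are w = W/max(W); zero weights are
replaced by the geometric mean of the nonzero ones. Feature–proxy
correlations are Spearman over codons present in both inputs, with an
optional exclusion list (e.g. ATG/TGG, whose weights are degenerate
singletons).

## TASEP simulator

Continuous-time kinetic Monte Carlo (Gillespie) dynamics of extended
particles on a codon lattice: a ribosome whose P-site is at codon j advances
at rate 1/T_j when the codon ℓ positions downstream is free of the next
ribosome's footprint; initiation occurs at rate B while codons 1..ℓ are
free; exponential dwells make the process memoryless. With probability
`pause_prob` a decoding event's mean dwell is multiplied by `pause_factor`
(a memoryless model of sporadic translational pauses). Hard-core exclusion
is asserted at every event in debug mode.

Standard study conditions (the `TasepConfig` defaults):

| parameter | default | rationale |
|---|---|---|
| genes × length | 50 × 300 codons | hundreds-of-codons genes at a desk-scale gene count |
| T_j | log-uniform on [1, 10] (arbitrary time units) | codon decoding times spanning one order of magnitude |
| footprint ℓ | 10 codons | ~30 nt ribosome footprint |
| initiation B | 0.003 | ≈ half the maximal sustainable current through the slowest codon, 1/(T_max(1+√ℓ)²) ≈ 0.006 — "moderate": ~12% footprint coverage with visible jams |
| pauses | prob 0.01, factor 10 | sporadic long dwells |
| horizon / burn-in | 40 000 / 4 000 | ≈ 110 ribosome transits after discarding the fill-up transient |
| RC mode | 1000 snapshots | see below |
| mRNA copies m | 1 | multiplies RC linearly |

RC extraction defaults to **snapshot sampling**: ribosome P-site positions
are counted at 1000 seeded time points in (burn-in, horizon), giving
integer-valued RC with a mean around 10 reads per codon and occasional
zeros. This is the regime real ribo-seq lives in, and it is what makes the
RC < 1 analysis filter meaningful; the noise-free time-integrated occupancy
(`mode="expected"`, scaled by `coverage`) is available when the ensemble
average itself is wanted. mRNA copies multiply the RC of a single simulated
lattice rather than sharing one lattice at rate m·B, so doubling m doubles
expected RC exactly and leaves NFC unchanged.

What the generator emulates: codon-specific decoding times, coverage
proportional to initiation rate and mRNA level, ribosome traffic jams,
sporadic pauses, finite sequencing depth, and (via
`positional_shift_generator`) positionally shifted NFC distributions near
ORF ends. What it does not: wobble/tRNA-recycling kinetics, mRNA secondary
structure, nuclease sequence bias, P-site offset miscalibration, and
multi-mapping artifacts. Passing synthetic tests therefore demonstrates the
estimators' statistical behavior under the modeled noise sources, not
robustness to every experimental bias in real libraries.

On the standard conditions, the Spearman correlations of the NFC features
with the true T_j (computed by `scripts/acceptance.py`) put the histogram
mode and the fitted log-normal median near +0.98/+1.0, the fitted skewness
near −0.98, and — because ~210 pooled samples per codon make location
estimators nearly noise-free — the sample median and fitted mean also near
+1.0. Noisier or shallower data degrade the sample median and especially
the fitted mean (which inherits σ²'s tail sensitivity) much faster than the
mode and fitted median; the fitted skewness correlates negatively because
fast codons' distributions carry proportionally larger jam- and
pause-induced right tails.

## Reproducibility

All randomness flows through seeded `numpy.random.Generator` instances; CLI
runs write a manifest (package version, seed, config hash) next to their
outputs, and identical seeds reproduce byte-identical simulator output.
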