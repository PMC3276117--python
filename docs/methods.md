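# Methods

## Model and estimation

`phasecnv` estimates population frequencies of CNV haplotypes from
unphased, uncertain per-site observations. A locus is an ordered list of
sites of three kinds: ICN (a haplotype carries an integer copy count),
SNVC (a haplotype carries an unordered multiset of copy units labelled by
their base at the variant position; the empty multiset is a deletion),
and SNP (one base per haplotype). The data for individual *j* at site *s*
is a likelihood table over the possible unphased states of that site —
total copy number (ICN), pooled base multiset (SNVC), or unordered
genotype (SNP). Only relative likelihoods matter; rescaling any
(individual, site) table by a positive constant provably leaves all
outputs unchanged (unit-tested).

**Enumeration.** Per site, every diplotype consistent with a
positive-likelihood state is enumerated: integer decompositions
a + b = T for ICN (subject to per-haplotype and total copy caps), multiset
bipartitions for SNVC, the single unordered pair for SNP. Across sites,
one one-site diplotype is chosen per site and each orientation of its two
haplotypes is assigned to the two chromosome slots; results are
deduplicated as unordered pairs. Copy-unit order within a haplotype and
haplotype order within a diplotype are not distinguished; canonical
serialization (copy units sorted in alphabet order, haplotypes sorted
lexicographically, `-`/`,`/`_`/`/` separators) makes equality and output
deterministic. The multi-site likelihood of a candidate is the product
over sites of the likelihood of the unphased state it implies, since
signal intensities cannot distinguish same-state diplotypes (e.g. [0/3]
vs [1/2]); site measurements are assumed conditionally independent given
the diplotype (this does not assume linkage equilibrium). Products are
accumulated in log space.

**EM.** With Hardy–Weinberg priors P(h)² / 2·P(h<sub>l</sub>)P(h<sub>m</sub>),
the E step computes per-individual diplotype proportions
w<sub>j,k</sub> ∝ λ<sub>j,k</sub>P(d<sub>j,k</sub>) and the M step counts
haplotypes weighted by w over 2N chromosomes. The observed-data
log-likelihood is monotonically non-decreasing; the engine asserts this
on every run and raises if violated beyond numerical tolerance.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `tolerance` | 1e-8 | absolute change of ln L at which a chain stops. The convergence criterion (ln L rather than frequency deltas) and its value are this package's choice. |
| `max_iterations` | 10 000 | per-chain cap |
| `n_restarts` | 10 | random flat-Dirichlet initializations run besides one uniform chain; highest final ln L wins, ties to the earliest chain. Restart count and distribution are this package's choice. |
| `max_allele_copies` | 2 | per-haplotype copy cap (alleles A0–A2) |
| `max_total_copies` | 4 | per-diplotype cap (totals 0–4), matching common array calling ranges; both caps configurable per site |
| `prune` threshold | 0 (off) | optional per-(individual, site) normalization and removal of states below the threshold, an enumeration-size/speed trade-off; the best state is always kept |
| call `threshold` | none | posterior proportion a call must exceed; otherwise no-call. 0.98 is a sensible conservative setting for real data |

The haplotype universe is every haplotype appearing in any enumerated
candidate; haplotypes never enumerated implicitly have frequency zero.
Missing (individual, site) tables are replaced by a uniform table over
all allowed states — an uninformative stand-in chosen here, one of
several defensible conventions. Individuals with no consistent candidate
(or zero total likelihood) are excluded with a warning and removed from N.

## Synthetic data

The generator emulates the standard evaluation design for likelihood-aware
phasing: known haplotype frequencies → i.i.d. haplotype draws paired
sequentially (HWE) → per-site unphased states → one Gaussian signal per
(individual, site) from the state's cluster → likelihood tables computed
from the same cluster model.

**Cluster layout and calibration.** Real pipelines fit per-state Gaussian
mixtures whose parameters are dataset-specific and not generally
available; the generator instead uses a canonical layout — ICN cluster
means equally spaced on one log-ratio-like axis at T·spacing; SNVC/SNP
means on a channel grid at (a, b)·spacing for a copies of the first and b
of the second allele, spherical covariance — and calibrates the common
per-site standard deviation so the expected argmax miscall rate under the
simulating state distribution hits a target. The benchmark conditions pin
that target to the realism anchors of the published evaluation: 22%
argmax copy-number miscall at an ICN site and 21% argmax genotype miscall
at an SNVC site. Calibration uses the exact Voronoi-interval normal
probabilities in 1-D and common-random-number Monte Carlo (40 000 draws,
fixed internal seed) in higher dimensions, with bisection to within 0.005
of the target. Sanity check: the calibrated one-ICN condition reproduces
a 78.1% mean argmax copy-number accuracy, matching the published 78.1%.

**Benchmark frequency tables.** The three predefined conditions use the
published known-frequency tables: one ICN site (1 copy 0.9609, 0 copies
0.0196, 2 copies 0.0196), one SNVC site (A 0.9600, − 0.0196, A,A 0.0196,
B 0.0009) and two SNVC sites (−_A 0.9592, −_− 0.0196, −_A,A 0.0196,
−_B 0.0009, A_A 0.0009). Printed tables round to four decimals and sum to
slightly more than one; they are normalized on load. In the two-site
table the duplication haplotype is represented per-site as (−, A,A): a
haplotype whose duplicated copy unit spans both sites is indistinguishable
from one with two units at the second site in per-site unphased data, so
the per-site representation loses nothing for inference.

**What the generator does not emulate.** Real-array fitted cluster
means/covariances (only spacing + calibrated sd), between-site noise
heterogeneity (every replicate site shares one calibrated sd, so
between-replicate SDs are smaller than published ones even where means
agree), probe-level structure, segmentation error, batch effects, and
deviations from HWE. Passing benchmarks therefore demonstrate correctness
of the inference machinery at matched hard-call error rates, not
performance on any particular array platform.

**Scoring.** Each replicate is scored against the realized sample:
TV against the empirical chromosome frequencies of the drawn diplotypes
and exact-match accuracy against the drawn diplotypes (the analogue of
scoring against a fixed known answer set). The "previous algorithm"
comparator replaces each table by a point mass on its argmax state and
reruns the identical EM — the deterministic hard-call input of earlier
phasing tools. Correction/corruption rates compare EM-implied unphased
states with argmax states using all individuals as denominator, which
makes state-accuracy(EM) = accuracy(argmax) + correction − corruption an
exact identity (asserted in tests).

**Problem sizes.** The benchmark runs use 14 replicate site sets × 588
individuals for the three main conditions and 10 answer sets × 14 site
replicates at n = 100 and n = 50 for the sample-size study, mirroring the
published design.

## Numerical choices and degenerate inputs

- λ products in log space; exact zeros short-circuit by excluding the
  state before enumeration.
- When every individual shares one enumeration template the E/M sums are
  computed as two matrix–vector products with the (N, K) likelihood
  matrix; a generic ragged path handles heterogeneous candidate lists.
  Both paths are tested to agree to 1e-10.
- Ties (argmax states, posterior-equal diplotypes, equal restart ln L)
  break deterministically: canonical string order / earliest chain.
- Zero-variance clusters are valid for signal simulation (they emit the
  mean) but have no density; noise-free experiments should use point-mass
  spectra (`exact_spectra`) instead.
- Frequency tables must sum to 1 within 1e-9 (estimation output) or 1e-6
  (TV inputs); per-individual posteriors sum to 1 within 1e-9.
- Frequency-spectrum bins are half-open [lo, lo + 0.02); frequencies
  below 1/(2N) or above 1 − 1/(2N) are excluded as unresolvable.

## Known limitations

- Exhaustive cross-site enumeration grows exponentially with the number
  of sites; the tool targets loci of one to roughly three sites (the
  practically relevant regime for CNV association and tagging analyses).
  State pruning mitigates but does not remove this.
- HWE is assumed; strongly non-equilibrium samples (e.g. pooled
  populations, related individuals) will bias frequencies.
- No trio/pedigree constraints, no LD statistics, no HMM/partition-
  ligation/sampling alternatives, and no VCF emission (multi-copy
  unphased states do not map cleanly onto VCF genotype fields).
- The package does not fit signal models to raw arrays; cluster
  parameters are inputs, expected from an upstream calling pipeline.
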