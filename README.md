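# phasecnv

Likelihood-aware EM inference of copy-number-variation (CNV) haplotype
frequencies and individual diplotypes from noisy, probabilistically
represented microarray-style data.

## The problem

High-throughput platforms do not observe CNV haplotypes. At a
copy-number locus they report, per individual and site, only an *unphased*
summary over the two chromosomes: the total copy number at an integer-
copy-number (ICN) site, the pooled base multiset (e.g. `AAG`) at a site
with single-nucleotide variation inside a CNV (SNVC), or the two-base
genotype at a SNP. Worse, these summaries are read off noisy signal
intensities, so the hard call with the largest likelihood is often wrong.
Phasing tools that accept only hard calls inherit those errors.

`phasecnv` instead takes, for every individual and site, a likelihood for
*every* possible unphased state (a per-site likelihood table, derived from
a Gaussian cluster model of signal intensities), and propagates that
uncertainty through haplotype-frequency estimation. The package is aimed
at statistical geneticists who need CNV allele/haplotype frequencies,
per-individual diplotypes, or simulation machinery for method evaluation.

## The model

Let haplotype *h<sub>i</sub>* have population frequency *P(h<sub>i</sub>)*
and write θ = (P(h₁), P(h₂), …). For individual *j*, every diplotype
*d<sub>j,k</sub>* consistent with any positive-likelihood state is
enumerated (per site, then across sites; e.g. total copy number 3 yields
[0/3] and [1/2]; genotype `AAG` yields [-/A,A,G], [A,A/G], [A/A,G]).
Because intensities do not distinguish diplotypes with the same unphased
state, the multi-site likelihood factorizes over sites:

λ<sub>j,k</sub> = Pr(x<sub>j,k</sub> | d<sub>j,k</sub>) = ∏<sub>s</sub> Pr(x<sub>j,k,s</sub> | d<sub>j,k,s</sub>)

Under Hardy–Weinberg equilibrium, P(d) = P(h<sub>l</sub>)² for a
homozygote and 2 P(h<sub>l</sub>)P(h<sub>m</sub>) otherwise. The EM
iteration maximizes

ln L(θ) = Σ<sub>j</sub> ln Σ<sub>k</sub> λ<sub>j,k</sub> P(d<sub>j,k</sub> | θ)

with the E step computing diplotype proportions
w<sub>j,k</sub> ∝ λ<sub>j,k</sub> P(d<sub>j,k</sub>) (normalized per
individual) and the M step counting haplotypes weighted by w over 2N
chromosomes. Individual diplotypes are called as the posterior argmax,
optionally with a no-call threshold. Estimation error is scored by the
total variation distance TV = ½ Σ<sub>i</sub> |p<sub>i</sub> − p̂<sub>i</sub>|.

## Worked example

Simulate one ICN locus for 588 individuals from haplotype frequencies
0.9609 (1 copy), 0.0196 (0 copies), 0.0196 (2 copies), with Gaussian
signal noise calibrated so that ~22% of argmax copy-number calls are
wrong, then phase it:

```sh
cat > sim.yaml <<'YAML'
n_individuals: 588
n_replicates: 1
seed: 42
sites:
  - site_id: cnv_locus
    site_type: ICN
    max_total_copies: 4
    max_allele_copies: 2
frequencies:
  "1": 0.9609
  "0": 0.0196
  "2": 0.0196
noise:
  spacing: 1.0
  target_miscall_rate: 0.22
YAML

phasecnv simulate sim.yaml -o sim
phasecnv phase --sites sim/sites.tsv --spectra sim/replicate000/spectra.tsv \
    -o phased --seed 0
```

`phase` logs `EM finished: lnL=-409.802387 after 22 iterations (chain 4,
converged=True), 588 individuals` and writes `phased/frequencies.tsv`:

```
haplotype	frequency
1	0.9612002294691451
2	0.020422770530082835
0	0.018377000000772026
```

— the estimated frequencies recover the simulating values to ~0.002
despite the 22% miscall rate. `phased/diplotypes.tsv` holds per-individual
calls with their posterior proportions and implied total copy numbers:

```
individual_id	diplotype	proportion	state_cnv_locus
ind0001	1/1	0.9765670770038922	2
```

Copying `truth.tsv` and `spectra.tsv` into the phased directory and running

```sh
phasecnv evaluate phased --sites sim/sites.tsv -o report.tsv
```

yields one metric row per replicate (plus mean ± SD rows): here
TV = 0.0116, diplotype accuracy 97.1%, argmax-call accuracy 77.4%,
correction rate 21.6%, corruption rate 1.7% — i.e. the EM repaired most of
the individuals whose hard copy-number call was wrong while corrupting
very few.

The same machinery is available as a library (`phasecnv.simulate_dataset`,
`phasecnv.build_expansion`, `phasecnv.run_em`, `phasecnv.call_diplotypes`,
`phasecnv.total_variation`, …); `phasecnv.scenarios.run_scenario` runs the
predefined one-ICN / one-SNVC / two-SNVC benchmark conditions end to end.

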