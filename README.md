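# mhcdrift

Temporal analysis of MHC class II DQA diversity across a population
bottleneck, built for ancient-DNA datasets sampled before and after the
event — the motivating case being the woolly mammoth's isolation on
Wrangel Island ~10 cal ka and its persistence there until extinction
~4 cal ka. The package answers, end to end, the question such datasets
pose: did balancing selection maintain immune-gene diversity through the
bottleneck, or is the observed loss explained by genetic drift alone?

It provides four tested stages, each usable on its own:

- **Allele calling** from replicated tagged amplicons: dual 6-nt tag
  demultiplexing (1 mismatch), primer trimming, clustering of identical
  reads with a ≥ 5% candidate threshold, replicate reconciliation with a
  C/T–G/A deamination-singleton filter (with cross-sample and external-
  catalog rescue), third-replicate homozygote confirmation, and allelic-
  dropout estimation (false-negative probability `ado_rate**k`).
- **Diversity statistics** between temporal strata: `H_O`,
  unbiased `H_E = n/(n−1)(1 − Σp²)`, allele counts and unique alleles,
  hypergeometric rarefaction of allelic richness
  `E[K_g] = Σ_j (1 − C(N−N_j, g)/C(N, g))` to a standardized 24 gene
  copies, per-locus 2×2 heterozygote χ² tests, and percent-decline
  summaries.
- **Selection scans**: Nei–Gojobori (1986) `d_N`/`d_S` with Jukes–Cantor
  correction, antigen-binding-region (ABR) masking, codon-bootstrap
  standard errors, and one/two-tailed Z-tests of positive, neutral and
  purifying selection.
- **Drift-null coalescent scan**: a heterochronous coalescent with a
  three-epoch size history (ancestral `N_anc` — 5-generation bottleneck
  `N_EB` at 12 ka — island `N_EW` until extinction), finite-sites
  mutation without transition bias, gene copies entering at the packaged
  calibrated specimen ages, and a log-grid scan of
  `P(island sample retains ≥ 63% of the ancestral sample's alleles)`
  over `(N_EB, N_EW) ∈ [2, 10,000]²` with the `P < 0.05` rejection
  boundary.

A synthetic-data module generates genotypes, Wright–Fisher-drifted
temporal strata, and damaged tagged reads with known ground truth, so the
whole pipeline runs and is tested without any external download.

## Worked example

Simulate a 24-sample run (12 per stratum, drifted island frequencies),
score genotypes from the reads, and summarize diversity:

```
$ mhcdrift simdata --seed 11 --out demo/sim --n-samples 24
wrote 14417 reads for 24 samples to demo/sim

$ mhcdrift call --seed 11 --out demo/called \
    --reads demo/sim/reads.fastq --run-dir demo/sim \
    --catalog demo/sim/catalog.fasta --ages demo/sim/samples.csv
allelic dropout rate 0.000 (0/70); false-negative prob 0.0000

$ mhcdrift diversity --out demo/div \
    --genotypes demo/called/genotypes_called.csv
percent declines: {'h_obs': 60, 'h_exp': 57, 'n_alleles': 57}
```

With error-free defaults every replicate shows both alleles, so the
dropout rate is 0 over the 70 informative heterozygous amplifications.
The declines are the percent drop of the across-locus mean from the older
to the younger stratum — here the simulation's island stratum drifted at
`N_e = 50` for 100 generations, losing over half its alleles and
heterozygosity. `demo/div/` also holds the per-locus table, the
rarefaction curves, and the χ² report as CSV.

The drift scan on a 15×15 log grid at 200 simulations per cell (about a
minute on one core):

```
$ mhcdrift driftscan --seed 1 --out demo/surface.csv \
    --grid-points 15 --n-sims 200
rejection boundary (N_EB >= 10): N_EW = 259.852644521882
```

Drift is rejected only for island sizes up to the grid point at ~260
individuals (the next point down is ~141; the true boundary lies in that
bracket), and the boundary is nearly independent of the bottleneck size
once at least ~10 individuals survive it.

The surface CSV holds one row per grid cell: `n_eb, n_ew, p, ci_low,
ci_high, n_sims`. Cells with `p < 0.05` are island sizes at which pure
drift cannot plausibly retain the observed fraction of ancestral alleles.

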