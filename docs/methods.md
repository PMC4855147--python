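# Methods

`mhcdrift` implements a temporal analysis of MHC class II DQA variation
across a late-Quaternary population bottleneck: genotype scoring from
replicated tagged amplicons of ancient DNA, pre/post-bottleneck diversity
statistics, Nei–Gojobori selection scans, and a heterochronous coalescent
test of whether genetic drift alone explains the observed allele loss.
This note records the models, the parameters that matter, and the design
choices made where the procedure was genuinely open.

## Temporal framing

Dated specimens are split into a *mainland* stratum (calibrated age
> 13 cal ka, the pre-isolation continental population) and an *island*
stratum (< 10 cal ka, after sea-level rise isolated the terminal island
refugium); ages between the thresholds are excluded. Ages published only
as bounds ("≥ 49 000") are used at their bound value and flagged — they
anchor the oldest stratum and no better point estimate exists. The
packaged fixture `data/specimen_ages.csv` carries the 24 specimens (12 per
stratum) typed at all three loci; their calibrated ages drive the
simulator's sampling scheme.

## Genotype scoring (allele calling)

Reads carry dual 6-nt tags (all tags pairwise ≥ 2 mismatches apart, so one
sequencing error cannot convert a valid tag into another) and are
demultiplexed tolerating one mismatch per tag; ambiguous or unpairable
tags go to a counted unassigned bin. Primers are matched with a
configurable tolerance (default 1 mismatch) and stripped; the 5%
candidate threshold is applied to reads that survived primer trimming
— an interpretation choice, since the alternative (threshold before
trimming) is equally defensible; it keeps the denominator meaningful when
primer failure is locus-specific.

Scoring is per sample and locus over two independent PCR replicates:

1. identical reads are clustered; clusters holding ≥ 5% (inclusive) of a
   replicate's reads are candidate alleles. Candidates are ordered by
   count, ties broken lexicographically, so outputs are deterministic.
2. candidates present in both replicates are accepted;
3. a candidate present in only one replicate (a *singleton*) that differs
   from an accepted candidate solely by C/T and/or G/A substitutions is
   treated as post-mortem cytosine deamination and discarded — unless the
   identical sequence was accepted in another sample of the run or occurs
   in a user-supplied external allele catalog (e.g. extant relatives), in
   which case it is retained. Singletons that are not damage-explainable
   leave the call failed unless a third replicate arbitrates by majority.
4. one accepted allele leaves the call a *pending* homozygote until a
   concordant third replicate confirms it (guarding against allelic
   dropout); more than two accepted alleles fail the call, flagging
   contamination or paralogy.

Allelic dropout is estimated as the fraction of replicate amplifications
of consensus heterozygotes that show exactly one of the two alleles;
amplifications showing neither allele are total failures, not dropout.
The probability of a false homozygote after `k` concordant replicates is
`ado_rate**k` (default `k = 2`, the number of concordant replicates
required before a third is requested).

## Diversity statistics

Per locus and stratum: observed heterozygosity `H_O` (fraction of typed
diploids with two distinct alleles), unbiased expected heterozygosity
`H_E = n/(n-1) · (1 − Σ p_i²)` over `n` gene copies (the unbiased form is
the common default in population-genetic software; the plug-in form is an
option), allele count `N_A`, and alleles unique to the stratum (computed
between the two strata at the same locus, not against a global catalog).
Allelic richness is rarefied hypergeometrically:
`E[K_g] = Σ_j (1 − C(N−N_j, g)/C(N, g))`, reported at every subsample size
up to `g = 24` gene copies (12 diploids, the standardized size both strata
support). The temporal change in heterozygote frequency is tested per
locus with an uncorrected Pearson chi-square on the 2×2
heterozygote/homozygote × stratum table (1 df); the uncorrected statistic
is the one that reproduces the published values, and Yates correction is
exposed as an option, off by default. Percent declines are
`100 · (mean_mainland − mean_island)/mean_mainland` of across-locus means,
rounded to the nearest integer, computed from exact heterozygote counts
rather than from rounded table entries (rounding first changes the result
by one point).

## Selection scans

The Nei–Gojobori (1986) method with Jukes–Cantor correction. Synonymous
site counts give each of a codon's nine single-base changes weight 1/3;
changes producing stop codons are excluded from both S and N, so S + N can
fall below three per codon. Codons differing at k positions average the
k! substitution orderings, dropping pathways through stops; a codon whose
every pathway is blocked is skipped and counted. Per-pair proportions use
site counts averaged over the pair; `d = −(3/4)·ln(1 − 4p/3)` corrects for
multiple hits and saturates at `p ≥ 3/4`. `d_N` and `d_S` are means over
all unordered sequence pairs, restricted to a codon mask — the
antigen-binding-region (ABR) mask is a required config input, as published
ABR designations are figure highlights rather than printed indices.

Standard errors come from a seeded codon-column bootstrap (default 1,000
replicates). The Z-tests use `Z = (d_N − d_S)/SE`, with the SE of the
difference taken from the joint bootstrap of `d_N − d_S` (quadrature of
the marginal SEs is an option; the joint form respects the strong negative
coupling of the two estimates under column resampling). Tail conventions
follow how such tables are conventionally printed: positive selection is
one-tailed upper, purifying one-tailed lower with its statistic reported
as `−Z`, neutrality two-tailed; a one-tailed p is reported as 1 when the
statistic contradicts the alternative (e.g. testing positive selection
with `d_N < d_S`).

Reproducing the published DQA Table-3/4 values requires the deposited
allele sequences (GenBank KX090927–KX090945) plus the elephant ABR mask as
inputs; the shipped tests exercise the machinery on synthetic in-frame
alignments with known ground truth instead.

## Drift-null coalescent simulation

The null model is a single population with a three-epoch piecewise-
constant diploid size history on a years-BP axis: ancestral size
`N_anc = 100,000` older than 12 ka; a bottleneck of 5 generations
(12,000 → 11,845 BP at 31 years/generation) at size `N_EB`; island size
`N_EW` from the bottleneck to extinction. The bottleneck is anchored with
its older edge at 12 ka; only its 155-year extent depends on this choice.
Gene copies enter the genealogy at the specimens' calibrated ages (2 per
diploid, all 24 specimens at every locus); within an epoch of diploid size
N each lineage pair coalesces at rate 1/(2N) per generation
(continuous-time approximation; an exact discrete-generation
Wright–Fisher mode exists for cross-checking at very small N, where the
approximation is worst). Loci (99, 89, 92 bp) are independent. Mutations
fall as a Poisson process at `μ = 1e-7` per site per generation, each
substituting a uniformly chosen different base at a uniformly chosen site
(finite sites, no transition bias); allele identity is exact sequence
identity. Under these parameters the ancestral sample's median total
allele count across loci is ~24, inside the 13–25 calibration window the
study conditions state.

The retention statistic compares allele counts summed over loci. The
default is the **count ratio** `A_island / A_ancestral`: the observed
criterion — 12 island alleles against 19 ancestral, 63% — is itself a
ratio of per-stratum counts, and per-deme allele counts are what standard
summary-statistics tools emit. A *shared* mode (fraction of ancestral
alleles whose exact sequence recurs among island tips) is provided; the
two coincide on the real data, where the island sample had no alleles
absent from the mainland sample, but shared mode is systematically
stricter in simulation. The threshold is 12/19, inclusive.

The grid scan estimates `P(retention ≥ threshold)` per `(N_EB, N_EW)` cell
on a log-spaced grid over [2, 10,000] with Clopper–Pearson binomial CIs;
each cell has an independent child stream spawned from the run seed, so
results are reproducible cell by cell. A cell is rejected at `P < 0.05`;
the rejection boundary is the largest `N_EW` whose column is rejected
across all rows with `N_EB ≥ 10`, reported with its one-grid-step bracket.
An optional conditioning filter restricts to simulations with ancestral
counts in [13, 25] for sensitivity analysis; the default treats the
calibration as parameter tuning, not per-simulation conditioning.

Desk-scale problem sizes: the shipped tests use a 15×15 grid at 200
simulations per cell and the acceptance script a single `N_EB = 100` row
at 300 per cell — enough that the boundary cell's binomial CI excludes
0.05 — rather than the 1,000 per cell a full production scan would use;
`n_sims` is a parameter throughout.

## Synthetic data

The generator emulates the study conditions with known ground truth:
Hardy–Weinberg diploid genotypes from given allele frequencies at three
loci (99/89/92 bp), Wright–Fisher multinomial drift between the two
strata, two independent PCR replicates per sample with independent
per-allele dropout, Poisson depth (default 100 reads/replicate), per-base
substitution error, and at most one deamination artifact per read at a
uniformly chosen C (→T) or G (→A) site — the minimal model that exercises
the damage filter's discard rule. It does not model indels, homopolymer
noise, chimeras, quality scores, or length-dependent amplification bias;
passing pipeline tests therefore demonstrate correctness of the scoring
logic, not robustness to every real 454 artefact (exact-identity
clustering deliberately ignores indel noise). Default read depth and
dropout/damage rates used in tests are chosen so that single damaged
reads can clear the 5% cluster threshold at low depth, the regime in
which the filter operates.

## Numerical conventions and degenerate inputs

- All randomized operations take an explicit integer seed; grid cells use
  spawned child streams.
- The 5% cluster threshold and the retention threshold are inclusive,
  with a 1e-12 tolerance against float rounding.
- `d_N/d_S` is 0 when `d_N = 0`, and undefined (NaN) when `d_S = 0` with
  `d_N > 0`; saturated pairs propagate NaN rather than being silently
  dropped.
- Chi-square with a zero margin, empty replicates, dropout estimation
  with no informative heterozygote, and rarefaction with `g` out of range
  all raise errors naming the offending input.

## Known limitations

- The simulator has no recombination, migration, or selection: the null
  is pure drift by design.
- The continuous-time approximation overstates coalescence slightly at
  N of order the sample size; the discrete mode exists for cross-checks
  but is too slow for grid scans.
- Exact-identity clustering cannot separate alleles from indel-bearing
  reads; fragments are assumed short enough that this is immaterial.
- The rejection boundary is grid-quantized; its bracket, not its point
  value, is the meaningful answer at desk scale.
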