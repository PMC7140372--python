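# Methods

This note documents the models behind `admixbench`, the defaults and why
they were chosen, the numerical conventions, and what the synthetic world
does and does not establish.

## Demographic model

A `MigrationSchedule` is a G × K table of replacement fractions m_k(t).
Generation t = 1 is the founding generation and must be entirely migrants
(row sum 1); t = G is the present, so "time since admixture = 15" means
G = 15. At each later generation a fraction Σ_k m_k(t) of the population is
replaced by fresh migrants. The expected final ancestry proportions follow
the recursion a_k(t) = (1 − Σ_j m_j(t))·a_k(t−1) + m_k(t), evaluated in
closed form by `expected_proportions`; this is exactly the expectation of
the copying process the simulator implements, which is what makes simulator
unbiasedness a testable statement.

The bundled five-way default (`default_sac_schedule`) represents the South
African Coloured scenario. The published per-generation migration fractions
for that scenario are in a supplementary table that is not redistributable
here, so the default falls back to a single founding pulse at the
previously reported proportions — Bantu-speaking African 0.32, KhoeSan
0.30, European 0.19, East Asian 0.07, South East Asian 0.12 — followed by
14 migration-free generations. Consequence: the pulse fallback reproduces
the *previously reported* proportions in expectation, not the slightly
different proportions a continuous-migration table would imply; users with
the supplementary table can load it with `load_schedule` and everything
downstream applies unchanged.

Migration is realized at the individual level: each generation-t individual
is independently a migrant with probability Σ_k m_k(t) (ancestry k with
probability m_k/Σ), drawn as a whole diploid founder (both haplotypes of
one founder individual, resampled with replacement from the small founder
pool, as an 11-per-population design forces). The i.i.d. realization keeps
the expectation exactly equal to the recursion; the alternative
(deterministic migrant counts) only reduces variance.

## Synthetic reference panels

Panels follow a Balding–Nichols star model: per site an ancestral frequency
p ~ Uniform(0.05, 0.95), then population k's frequency f_k ~
Beta(p(1−F_k)/F_k, (1−p)(1−F_k)/F_k) — mean p, variance F_k·p(1−p) — then
haplotype alleles i.i.d. Bernoulli(f_k). Two populations with drift
parameters F_a, F_b have expected pairwise Hudson F_ST ≈ (F_a+F_b)/2, which
the tests verify against a frequency-based Hudson estimator. Sites left
monomorphic across all populations are redrawn so every emitted site
survives a MAF filter. Default drift parameters (KhoeSan 0.05, Bantu 0.06,
European 0.12, South East Asian 0.10, East Asian 0.25) put the two African
panels closest together and the Eurasian panels at intermediate distances,
reproducing qualitatively the confusability structure seen with real
references (KhoeSan↔Bantu-speaking, European↔South East Asian).

Not modelled, deliberately: linkage within reference panels (sites are
independent given frequencies), mutation, coalescent genealogy, sex
chromosomes. Truth-tract bookkeeping depends only on the copying process,
so reference LD affects caller difficulty, not truth correctness. A green
test therefore establishes the arithmetic of simulation and scoring — not
that the baseline caller's absolute accuracy predicts any real tool's.

## Genetic maps and recombination

A `GeneticMap` is a piecewise-linear monotone bp↔cM mapping (HapMap-style
file format: position, rate cM/Mb, cumulative cM). Synthetic maps draw
anchor positions uniformly and genetic-length increments from a flat
Dirichlet, giving irregular local rates. Meiosis uses Poisson crossovers
without interference: count ~ Poisson(L Morgans), positions uniform in
cumulative cM mapped to bp by inverse interpolation. Zero-recombination
(flat) map stretches carry zero genetic measure, so crossovers never land
inside them; a 0-cM map yields a fair-coin whole-chromosome copy.

Numerical conventions: coordinates are 0-based half-open internally,
1-based only at VCF boundaries. Crossover breakpoints are kept as float64
bp and only rounded at file export — this removes spurious exact ties
between window-majority truth projection and callers. Gamete tracts are
re-maximalized (adjacent same-ancestry tracts merged); per haplotype the
tract genetic lengths sum to the chromosome's genetic length to 1e−9 cM.
True global proportions weight tracts by genetic length, falling back to
physical length on a degenerate 0-cM map.

## Filters

QC order is fixed: site missingness (≤ 0.05) → individual missingness
(≤ 0.01) → MAF (≥ 0.003) recomputed on kept individuals; the report counts
removals per step. The 0.01 per-individual cap is unusually strict and is
applied at face value. LD pruning is PLINK-style greedy: 50 kb windows
advancing by 10 kb; within a window, pairs are scanned in position order
and the later site of any pair with r² > 0.1 is dropped (keep-earlier,
deterministic, idempotent). r² is computed on unphased 0/1/2 dosages over
pairwise-complete individuals; zero-variance sites count as r² = 0.

## Baseline caller

Harness plumbing, not a method contribution: per window (default 0.2 cM)
and haplotype, argmax_k Σ_site log f_k(allele), with panel frequencies
smoothed as (count + 0.5)/(2n_k + 1) so the floor is ≈ 0.5/(2n_k). Ties
break to the lower ancestry code and are counted; empty windows inherit the
previous window's call. Its accuracy rises with panel differentiation and
collapses for closely related references — useful precisely because it
makes the evaluation harness's discriminations visible.

## Evaluation

* **GAI:** per-ancestry RMSE √(mean_i (q̂_ik − q_ik)²). Anonymous cluster
  columns are matched to ancestries by maximising total column correlation
  (exhaustive for K ≤ 8 with lowest-index tie-break, Hungarian otherwise);
  the assignment and tie flag are reported.
* **LAI:** "sites" means SNPs — windows are weighted by contained SNP
  count by default (genetic/physical length optional). Overall accuracy per
  individual is (correctly called sites)/(called sites). The source prints
  this formula with numerator and denominator descriptions swapped (a
  ratio that would exceed 1); correct/called is implemented. Per-ancestry
  accuracy is recall-style — denominator: called sites whose *true*
  ancestry is k; numerator: those also called k — matching the partition
  Σ_k d_ca = d_c; a precision-style variant (denominator: sites *called*
  k) is computed alongside since the source wording is ambiguous.
  Individuals with an empty denominator are excluded and reported, never
  scored 0. Haplotypes are compared without re-pairing (simulated data is
  perfectly phased).
* **Comparisons:** two-sided Wilcoxon; paired signed-rank for same-cohort
  contrasts, unpaired rank-sum available. Exact null for combined n ≤ 20
  without ties, tie-corrected normal approximation otherwise; both paths
  cross-validated in tests. All-tied paired differences return p = 1 with a
  warning.
* **Summaries:** cohort mean proportions (percent) with percentile
  bootstrap 95% CIs, 10,000 resamples, seeded (the CI method is not stated
  in the source; percentile bootstrap chosen for distribution-freeness).

## Scale defaults and test design

The intermediate population size (default pop_size = 1000) and cohort size
(n_out = 100) are not stated in the source; both are config-exposed. Tests
scale pop_size down for runtime. Two test-design points deserve record:

* **Unbiasedness testing uses replicate cohorts.** The cohort mean ancestry
  carries genetic drift shared across individuals, so the naive
  across-individual standard error understates the Monte-Carlo error of the
  cohort mean. The acceptance test simulates 8 replicate cohorts (100
  individuals each, pop_size 400, G = 15, ~50 cM) and uses the
  between-replicate SE of the grand mean, which absorbs drift correctly.
* **Perfect-marker recovery uses a well-posed marker geometry.** Exact
  accuracy 1.0 requires that no window's majority ancestry be ambiguous
  between the truth projection (genetic-length majority) and the caller
  (site-likelihood argmax). The fixture places one cluster of K perfectly
  informative markers at each window's centre and makes the map flat across
  the cluster, so crossovers cannot split a cluster and, for windows with a
  single breakpoint, the side holding the cluster is provably the
  genetic-length majority side. Windows holding two or more accumulated
  breakpoints could still disagree in principle; the fixture's short map
  (10 cM, G = 2) makes that a ~10⁻² probability event per cohort and the
  fixed seed pins the realization.

## Known limitations

Single chromosome per run (multi-chromosome = loop over independent maps);
no post-admixture selection, mutation, sex-specific maps, or pedigree
output; no phase-switch-forgiving evaluation mode (simulated data is
phased by construction); external inference tools are never executed, only
their output parsed; absolute baseline-caller accuracies characterise the
synthetic world only.
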