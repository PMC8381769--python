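# Methods

`vineflow` reimplements, as a tested library, the statistical core of an
integrated analysis of crop-germplasm dissemination: SNP-panel quality
control, descriptive population genetics, and approximate Bayesian
computation (ABC) model choice among explicit demographic scenarios. This
note records the models, the defaults and why they were chosen, the
numerical decisions, and what the simulation-based tests do and do not
demonstrate.

## Genotype model and quality control

All stages operate on a samples × loci matrix of diploid alternate-allele
dosages (0/1/2, with missing calls preserved), plus a population label per
sample and chromosome/position per locus. QC follows the standard chain for
curated array panels, in this order: per-SNP filters (missingness > 1%
removed, then MAF < 5% removed, MAF computed from non-missing calls), then
per-sample missingness (> 5% removed), then duplicate-profile removal.
Duplicates are sample pairs whose genotype mismatch fraction over loci
called in both is **below** 20%; flagged pairs are joined into connected
components and each component keeps its first sample in input order (the
choice of representative is arbitrary; first-in-order makes reruns
deterministic).

LD pruning uses the conventional 50/5/2 parameter triple: sliding windows
of 50 SNPs advancing by 5, removing within each window the locus with the
highest variance inflation factor (VIF = 1/(1−R²) of its dosage regressed
on the other kept loci of the window, with per-locus mean imputation of
missing calls inside the regression only) until every VIF is below 2. Ties
remove the later-indexed locus, and removal is global across windows, so
the output is deterministic in input order.

Core collections maximize allele coverage with a deterministic greedy
cover: count distinct (locus, allele) pairs carried, start from the sample
covering most, repeatedly add the sample adding most uncovered pairs, ties
to input order. Greedy rather than stochastic search trades a small amount
of coverage optimality for exact reproducibility; coverage is monotone in
the core size by construction.

## Descriptive statistics

* **Gene diversity** (expected heterozygosity) per locus uses the unbiased
  estimator H = n(1 − p² − q²)/(n − 1) with n the number of called gene
  copies; a population's value is the mean over usable loci.
* **Fst** is the Weir–Cockerham (1984) variance-components estimator,
  combined over loci as Σa / Σ(a+b+c). It can be slightly negative; note
  that computing it between two *identical* sample sets does not give
  exactly zero (the a-component contains a −(p̄q̄ − h̄/4)/(n̄−1) correction
  term), a property the tests pin against a direct transcription of the
  published component equations.
* **Nei's (1972) standard distance** D = −ln(Jxy/√(Jx·Jy)) from mean
  within- and between-population allelic identities. Disjoint fixed alleles
  give Jxy = 0; the distance is then flagged infinite (and capped at 10.0
  wherever a finite vector is required, i.e. inside ABC summary vectors).
* **NJ trees** from (clamped-nonnegative) distance matrices delegate to
  scikit-bio's Saitou–Nei implementation; additive matrices are recovered
  exactly.
* **LD decay**: r² is the squared Pearson correlation of unphased dosage
  vectors over samples called at both loci (composite LD — array data are
  unphased), restricted to same-chromosome pairs within 10 Mb, averaged in
  100-kb physical-distance bins. The "decay distance" at a threshold
  (default r² = 0.05) interpolates linearly between consecutive bin-midpoint
  means and reports the first downward crossing; a curve that never crosses
  from above is flagged undefined rather than extrapolated.
* **IBD relatedness** uses the genome-wide method of moments: observed
  identity-by-state counts are equated to their expectations given pooled
  allele frequencies and inverted to (k0, k1, k2). The reported k's are
  truncated to the probability simplex; π̂ = k2 + k1/2 is computed from the
  *untruncated* estimates and clipped to [0, 1], because truncating first
  biases π̂ upward by roughly σ/2 at a few thousand loci and would make
  unrelated pairs look weakly related. Group-level sharing is summarized as
  log10 of the mean pairwise π̂ per population pair, and individual
  structure by classical (Torgerson) MDS of 1 − π̂, keeping positive
  eigenvalues only and fixing axis signs so each axis's largest-magnitude
  loading is positive.

## Demographic scenarios

A scenario is a backward-time event list over named populations: divergence
(all lineages of the derived population move into its source, which
persists with its own Ne) and point admixture (each lineage of the admixed
population moves to source A with probability r, else B). Every population
branch, including purely ancestral ones, carries its own effective size in
diploid individuals; times are in generations (no calendar conversion is
attempted). Twelve scenarios for four competing-hypothesis groups of the
grapevine east-to-west dissemination question ship as validated fixtures,
three per hypothesis (two serial routes and, in three of the groups, one
admixture model).

The source study does not publish its priors. Package defaults: Ne ~
log-uniform[100, 10000] diploids per branch (log-uniform because effective
sizes are scale parameters), t1 ~ U[10, 500], t2 ~ U[10, 2000] generations
with the ordering constraint t2 > t1 enforced by resampling only violating
parameters, and admixture proportion r ~ U[0.05, 0.95]. All priors are
overridable per scenario in configuration.

## Coalescent SNP simulation

Loci are simulated independently under the structured coalescent with
exact exponential waiting times: within a population of size Ne, k lineages
coalesce at rate k(k−1)/2 / (2Ne) per generation; events move lineages
between populations; no coalescence occurs across populations before their
join. Each locus carries exactly one mutation dropped on a branch chosen
proportionally to its length, so every column is polymorphic; a pooled
minor-allele-frequency ascertainment filter (default MAF ≥ 5%, matching the
panel QC threshold) redraws the entire locus — a fresh genealogy, not just
a new mutation — so the accepted genealogy distribution is correctly
conditioned. Gene copies 2i, 2i+1 form diploid individual i within its
population. Positions come from a synthetic 19-chromosome × 25-Mb map and
are decorative for ABC (loci are unlinked; the ABC statistics are
frequency-based, and LD analyses never consume simulated data).

The engine is numba-compiled (~60–90 µs per 180-tip genealogy including
ascertainment redraws); its correctness is cross-checked against coalescent
theory (E[TMRCA] = 2Ne for n = 2), an independently written minimal
Kingman simulator, and msprime on an equivalent two-population divergence
demography.

## ABC model choice

The summary vector for P populations is: mean gene diversity per population
(fixed population order), pairwise WC84 Fst, pairwise Nei D (both in
lexicographic pair order) — 9 statistics for 3 populations. Infinite Nei
distances are capped at 10.0 and an Fst pair with no polymorphic locus
contributes 0 (no measurable differentiation). The reference table holds
one row per simulated dataset (scenario id, parameter draw, summary
vector); statistics are standardized by their mean and standard deviation
over the whole table, dropping zero-variance statistics with a warning.

Rejection retains the ⌈tolerance·N⌉ rows closest to the observed vector in
standardized Euclidean distance (default tolerance 1%), boundary ties by
row index. Posterior model probabilities come from a multinomial logistic
regression of scenario label on standardized statistics over the retained
rows, weighted by the Epanechnikov kernel w = 1 − (d/d_max)² (the standard
regression-ABC choice) with a tiny ridge penalty (1e−6) so complete
separation stays finite, evaluated at the observed vector. 95% CIs use a
percentile bootstrap over the retained rows (B = 100 by default; the CI is
widened if needed to contain the point estimate). The direct estimate (the
per-scenario share of retained rows) is reported alongside.

The selection rule ranks scenarios by posterior probability; exact ties go
to the fewest total outlying statistics, then input order. The report also
flags whether the winner's CI overlaps the runner-up's and whether the
winner minimizes the outlier count — the published analysis required both.

Parameter adjustment is weighted local-linear regression with a logit
transform to the prior bounds: z = ln((θ−a)/(b−θ)), regress z on
standardized statistics with the Epanechnikov weights, shift each retained
draw by −b̂ᵀ(S_i − s_obs), back-transform. Adjusted draws are therefore
inside the prior bounds by construction; point-prior (a = b) parameters
pass through unchanged.

Confusion analysis simulates pseudo-observed datasets (pods) per scenario
from its priors and classifies each by the highest logistic posterior
probability (outlier counts are a goodness-of-fit criterion, not used for
pod classification). Type I(s) is the fraction of pods from s not assigned
s; type II(s) the fraction of other scenarios' pods assigned s; performance
the overall correct fraction. Model checking resamples the adjusted
posterior, simulates posterior-predictive datasets, computes per-statistic
two-sided empirical tail probabilities p = 2·min(F̂, 1−F̂), counts outliers
at p < 0.05 and p < 0.01, and projects reference, predictive and observed
points on the top two principal components of the standardized reference
statistics.

## The discrimination benchmark

The benchmark (`vineflow.benchmarks.separated_benchmark`) measures
scenario-choice power on the hypothesis-1 fixture with well-separated point
models: Ne = 1000 diploids on every branch; the serial route through the
south (S1) and the independent-derivation model (S3) at t1 = 100,
t2 = 600 generations; the mirror serial route (S2) at t1 = 300, t2 = 600.
The mirror scenario needs its own divergence time: with equal Ne on every
branch, S1 and S2 at identical times are exact label-exchange images of
each other — the labelled genealogy distributions coincide, no statistic
can separate them, and any benchmark using identical parameters would
measure a coin flip rather than the method. Problem sizes are 30 diploids
per population, 500 loci per dataset, 2000 reference simulations per
scenario, tolerance 1%, and 20 pods per scenario; at these sizes the
benchmark runs in about ten minutes on one CPU and achieves a mean
type I/II error of 0%, well under the 20% adequacy bound used to certify
power in the source analysis.

## Synthetic study data

The generator wraps the simulator with the artifacts the QC stage exists
for: per-cell Bernoulli missingness at separate per-SNP and per-sample
rates (no array-batch structure — the simplest model that exercises the
thresholds), and clone samples copied from random originals with an
independent symmetric genotype flip per locus (duplicated profiles in real
panels are clonally propagated varieties with genotyping noise). A manifest
records the generating scenario and parameters, clone pairs and injected
missing cells, so tests can assert exact ground-truth recovery.

What passing tests show — and what they do not: the synthetic panels have
independent loci, no genotyping batch effects, no ascertainment bias beyond
the MAF filter, and population labels that match the generating demes
exactly. Real germplasm panels violate all four (linked loci, array batch
structure, discovery-panel ascertainment, admixed and mislabeled
accessions), so green tests certify the correctness of the machinery, not
the historical conclusions drawn from any real panel.

## Numerical and degenerate-input decisions

* Standardization constants always come from the full reference table;
  model probabilities are therefore invariant to affine rescaling of any
  statistic.
* A scenario absent from the retained set gets direct estimate 0 and a
  warning; the logistic model cannot score an absent class, so its Pp is 0.
* Epanechnikov weights degenerate to uniform when all retained distances
  are equal (d_max = 0 or all weights 0).
* `reject` requires 0 < tolerance ≤ 1; `adjust_parameters` requires at
  least n_statistics + 2 retained rows of the target scenario.
* Random streams: every public entry point takes one integer seed;
  internally `numpy.random.SeedSequence` spawns one child stream per
  simulated dataset (reference tables are therefore chunk-order stable) and
  the numba kernels are seeded with 31-bit integers derived from the same
  streams.

## Known limitations

* No intra-locus recombination, linked loci, microsatellites, bottleneck or
  growth phases, or continuous migration — the scenario language covers
  splits and point admixtures only, which is what the dissemination
  hypotheses require.
* The IBD method of moments assumes homogeneous allele frequencies; in
  structured panels π̂ between members of diverged groups is deflated.
* The logistic-regression CIs are bootstrap percentile intervals over
  retained simulations; they quantify rejection-set uncertainty, not prior
  sensitivity.
* Pairwise LD computation is quadratic in loci per chromosome; it is meant
  for array-scale panels (thousands of loci), not sequencing data.
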