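# Methods

This note documents the statistical procedures implemented in `trmex`, the
parameters that matter, what the synthetic-data generators do and do not
emulate, and the numerical and design choices made where the design was
genuinely open.

## Pseudobulk construction and filtering

Single-cell raw counts are summed gene-wise over each combination of
grouping keys (default donor × tissue × cluster). Samples with fewer than
20 cells are removed (a sample with exactly 20 is kept); the removed pairs
are logged. Genes whose identifiers start with HLA/TRA/TRB/TRG/TRD
(case-insensitive) are dropped — in real data these encode HLA alleles and
rearranged receptor segments whose "expression" reflects genotype and
clonotype rather than phenotype. A gene is retained iff, in at least one
replicate group, its count is strictly above `min_count` in at least
`min_samples` samples; the defaults (> 5 in ≥ 2 samples) suit cohorts with
few replicates per group, and the alternative (> 3 in ≥ 4) suits cohorts
with more, smaller samples.

## Scaling, RLE and RUV-III

Between-sample scaling uses trimmed-mean-of-M-values (TMM) factors: M and A
statistics are computed on library-size-normalized counts against a
reference sample (the one whose 75th-percentile count fraction is closest
to the mean), genes in the extreme 30% of M or 5% of A are trimmed, and the
remaining M values are averaged with inverse-variance (delta-method)
weights. Factors are normalized to geometric mean 1. Because M values are
computed on count *fractions*, a pure sequencing-depth difference yields
unit factors; only compositional bias moves them. Counts become
`log2(CPM + prior)` with the prior count (default 1/2) guarding zeros;
effective library size = library size × TMM factor.

Relative log expression (RLE) subtracts each gene's median across samples;
per-sample RLE medians rank samples for diagnostics and PRPS construction.

RUV-III removes unwanted variation using replicates and negative-control
genes. With replicate membership matrix M (one group per sample), the
algorithm removes replicate-group means (`R = Y − M(M'M)⁻¹M'Y`), takes the
leading left singular vectors of R, projects Y onto them to obtain gene
loadings α, solves for sample scores W on the control-gene columns only,
and subtracts `Wα`. Estimability requires `k ≤ n_samples − n_groups` and
`k ≤ n_controls`. Biology shared by replicates lives in the group means and
is untouched; conversely, when replicate groups are nested inside batches
the batch effect is indistinguishable from biology and is *not* removed —
this failure mode is exercised in the tests. By default RUV-III runs on the
post-filter gene set. W is estimated on log-scale data and then reused as
covariates in the count-scale GLM.

For batched cohorts without replicates (PRPS): within each batch, samples
are ranked by median RLE and split into bottom/middle/top tiers (remainder
samples go to the lower tiers, deterministically). Per subtype per tier,
5–10 samples yield one pseudo-sample averaging five randomly selected
members (seeded); more than 10 yield two pseudo-samples from the bottom
five and top five ranked members; fewer than five yield none. Pseudo-samples
sharing a subtype form replicate groups; real samples enter as singletons.

## Differential expression

Each gene is modeled as NB with log link: `log μ = Xβ + offset`, X holding
one coefficient per group plus the RUV-III scores W, the offset being the
log effective library size. The NB variance is `μ + φμ²` (φ = 0 is
Poisson). Contrasts c (summing to zero; e.g. target = 1, others = −1/(G−1),
optionally excluding groups such as a CD103− resident cluster from the
average) are tested by likelihood ratio: the null model is the design
post-multiplied by a null-space basis of c (so `c'β = 0` by construction),
both models are fit by IRLS (statsmodels GLM, ≤ 100 iterations, tolerance
1e-10; non-convergent NB fits fall back to Poisson and are flagged), and
`2Δℓ` is referred to χ²(1). The log2 fold change is `c'β̂ / ln 2`. P values
are BH-adjusted across tested genes; `de ⇔ p_adj < 0.05`.

Dispersions are estimated per gene by Cox–Reid adjusted profile likelihood:
fitted means come from a Poisson fit (the mean model is nearly free of φ),
and the profile in φ is maximized on [1e-6, 20] with the adjustment
`−½ log det(X'WX)` correcting the bias from estimating the mean
coefficients. Estimates are then shrunk toward the 10%-trimmed mean of all
per-gene estimates with weight 0.25 — a deliberately simple stabilizer in
place of full empirical-Bayes trended machinery, which is out of scope.
This combination gives type-I error within [0.03, 0.07] at α = 0.05 and a
p-value ECDF within KS 0.05 of uniform on ~5,000 null genes (verified in
the acceptance tests at 8 samples per group).

**Two-stage signatures.** Stage 1 contrasts the subset against the average
of the other groups; stage 2 contrasts the two subsets being deconvoluted
directly. A gene enters the up (down) set iff it is up- (down-) DE in both
stages. Note the composite truth of this rule: a gene expressed only by the
*other* subset (e.g. a T<sub>EX</sub>-exclusive gene when deriving
T<sub>RM</sub>) genuinely satisfies both contrasts with reversed sign and is
a true discovery of the rule, not a false positive; the recovery reports
therefore score false discoveries against the composite truth while recall
is reported against the subset's own planted genes. `union` and
`stage2_only` combination modes are available for sensitivity analyses.

## Refinement and enrichment

Cross-dataset refinement takes the union of the two same-direction
signature lists as candidates and keeps a gene iff (a) it is DE in both
datasets with the same sign or (b) DE in one with a same-sign |log2FC|
strictly above 0.5 in the other. The rule is symmetric in the two inputs
and the result is a subset of the union of the inputs. (A strict
intersection of the two lists would make case (b) unreachable, since a
non-DE gene cannot sit in the other dataset's signature; the union reading
is the one consistent with case (b).)

Enrichment uses the weighted Kolmogorov–Smirnov running sum: genes ordered
by decreasing score (ties broken by gene id for determinism), set members
stepping up by `|score|^p` (normalized; default exponent p = 1, p = 0 gives
the classic unweighted statistic, invariant under monotone score
transformations), non-members stepping down by `1/(N − n_set)`. ES is the
signed extremum; the leading edge is the members at or before it (after it
for negative ES). The null permutes gene labels — appropriate because the
input is a single ranked list, not a sample × gene matrix — and
`p = (1 + #{|ES*| ≥ |ES|}) / (1 + n_perm)`, so the attainable floor is
`1/(n_perm + 1)`. This permutation null replaces the correlation-adjusted
competitive test sometimes used for barcode plots; with a single ranked
list there is no inter-gene correlation structure to estimate.

## Module scoring and abundance ratios

The module score of a gene set in a cell is the mean normalized expression
of the set genes minus the mean of control genes: candidate controls (all
genes outside the set) are binned into 24 equal-occupancy bins by average
expression, and each set gene draws up to 100 controls (seeded) from the
bin matching its own average. Excluding the set from the control pools
prevents self-contamination when the set concentrates in the top expression
bins. Scores are location-equivariant and identically zero on a constant
matrix. Up and down scores combine as `(up − down)/2`; with no down set the
up score passes through. Defaults (24 bins, 100 controls, fixed seed)
follow the conventions of the widely used binned-control scoring functions.
Input is the package's log-normalized matrix (`log2(1 + CPM/100)` per
cell); any normalized matrix may be substituted.

Per-sample subset abundance is `log2((n_EX + 0.5)/(n_RM + 0.5))` — the
pseudocount protects empty denominators and makes the measure antisymmetric
under swapping numerator and denominator. The ratio-vs-TMB association is
ordinary least squares with a two-sided t-test on the slope (≥ 3 paired
observations with predictor variance required).

## TCR repertoire

Clonotype = joined α+β CDR3 nucleotide strings. Cells annotated with more
than one distinct β-chain CDR3 are removed as doublets *before* the
highest-UMI retention step (retention could otherwise rescue a doublet);
then the highest-UMI contig per chain per cell is kept, ties broken by
sequence. Clone sizes are donor-scoped — public clonotypes across donors
are not assumed — with a global scope available. Expanded = ≥ 2 cells.
Overlap between subsets uses Jaccard dissimilarity of expanded-clone sets
and exclusive (UpSet-style) shared-clone counts in which a clone belongs to
the combination of exactly those subsets holding at least the cutoff number
of its cells; counts at cutoff n+1 never exceed those at n. The top-100
clone composition matrix row-scales each clone's subset distribution to
100%, with ties at the size boundary broken by lexicographic key.

Viral annotation: per (donor, clonotype), candidate references are those
whose HLA allele the donor carries; the per-entry distance is the
Levenshtein distance on CDR3 amino acids, combining chains by `max` (both
chains must match closely — conservative; `sum` and `min` configurable),
single-chain references contributing that chain alone. The clone's distance
is the minimum over candidates and the flag is `distance < 1` — read
literally, only exact matches; because an integer edit distance of exactly
1 is arguably intended to qualify under a "≤" reading, the generator plants
mutants at exactly distance 1 and the threshold mode is configurable
(`inclusive=True`), with both behaviors asserted in the tests.

## Concordance

Gene-wise log2FCs from independent studies are averaged (per gene, over the
tables containing it) to form pooled profiles, then the signs in two
studies are cross-classified into a 2×2 table; genes with a log2FC of
exactly 0 in either study have no sign and are excluded (counted in the
log). The two-sided Fisher p sums hypergeometric point probabilities not
exceeding the observed table's (relative tolerance 1e-10 absorbs
floating-point ties); the reported odds ratio is the conditional MLE. The
exact test is discrete and conservative — balanced tables return p = 1 —
so its null p distribution is super-uniform by construction; the tests
verify it is never anticonservative rather than uniform.

## Synthetic data

`simulate_cells` draws gene baseline abundances from a lognormal, plants
disjoint up/down sets per subset at ±effect log2FC, adds per-donor N(0,
0.15) log2 shifts on every gene (the unwanted variation), draws lognormal
library sizes (σ = 0.3, keeping TMM factors nontrivial but bounded), and
emits NB counts with constant per-gene dispersion (default 0.3, a typical
pseudobulk-scale overdispersion). A reserved control-gene set is guaranteed
non-DE (it still carries donor effects — exactly what RUV-III should
remove). `plant_seed` decouples the planted biology from the noise so two
cohorts can share truth, which is what cross-dataset refinement assumes.
`simulate_repertoire` draws Zipf clone sizes (exponent 2), one donor and
one "home" subset per clone (occupied with probability 0.8), in-frame CDR3
nucleotide strings of 30–48 nt translated with the standard table, and
plants a fraction of clones from the reference table at edit distance
exactly 0 or exactly 1. `simulate_bulk_batches` produces log-scale Gaussian
expression with additive per-batch shifts and planted subtype effects.

Not emulated: ambient RNA, doublet transcriptomes, cell-cycle and stress
programs, trended mean–dispersion relationships, V(D)J germline
recombination statistics, CITE-seq protein channels. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated model, not robustness to every artifact of real droplet data.

## Problem sizes and determinism

The tests and the acceptance script run at deliberately modest sizes chosen
to make the Monte-Carlo assertions stable: ~1,200–2,400 cells and
1,200–6,200 genes per simulated cohort, 40 pseudobulk samples (8 per
group), repertoires of ≤ 500 clones (where brute-force all-pairs oracles
are exact), 200–999 permutations for enrichment. All randomness flows from
one root seed split per stage by SHA-256, so fixed seeds give byte-identical
outputs (asserted file-by-file in the tests); derived seeds stay below 2³¹.

## Known limitations

- Dispersion estimation is per-gene with simple shrinkage; no trended
  empirical-Bayes priors or quasi-likelihood F-tests.
- The NB-GLM treats donors via RUV-III covariates rather than random
  effects; strong donor × gene interactions beyond k factors would inflate
  variance.
- Module scores are computed on log-normalized data; variance-stabilized
  inputs are accepted but not produced by the package.
- Viral annotation depends entirely on the completeness of the reference
  CDR3 table and donor HLA calls; absence of a flag is not evidence of
  tumor specificity.
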