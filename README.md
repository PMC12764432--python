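# trmex

Deconvolution of **tissue-resident memory (T<sub>RM</sub>)** from
**exhausted (T<sub>EX</sub>)** CD8+ T cells in tumors, as a tested, reusable
Python library.

Intratumoral T<sub>RM</sub> and T<sub>EX</sub> cells share a residency
program (CD69/CD103 up, *KLF2*/S1PR1 down), so published residency
signatures conflate a dysfunctional, chronically stimulated population with
a functional memory one. Separating them matters: the balance of the two
predicts responsiveness to checkpoint blockade and tracks tumor mutational
burden. `trmex` implements the computational machinery needed to pull the
two programs apart from single-cell data and to characterize their clonal
structure:

- **Pseudobulk differential expression** — raw counts summed per
  donor × cluster, samples with < 20 cells removed, low/receptor genes
  filtered, and gene-wise negative-binomial GLMs
  (`log μ_gs = x_s'β_g + o_s`, Var = μ + φμ²) with likelihood-ratio tests of
  contrasts such as *subset vs the average of all other subsets*;
  Benjamini–Hochberg control at α = 0.05.
- **Normalization** — TMM scaling factors, relative log expression (RLE)
  diagnostics, and **RUV-III**: unwanted variation estimated from replicate
  residuals restricted to negative-control genes and removed, with the
  estimated factors W reused as GLM covariates. For batched bulk cohorts
  without replicates, **PRPS** (pseudo-replicates of pseudo-samples) builds
  the replicate structure from RLE-ranked tiers.
- **Two-stage signatures** — genes DE both in *subset vs rest* and in
  *T<sub>RM</sub> vs T<sub>EX</sub>* head-to-head with concordant sign, and
  **cross-dataset refinement**: keep a gene if concordantly DE in both
  cohorts, or DE in one with a same-sign |log2FC| > 0.5 in the other.
- **Module scoring** — per-cell score = mean expression of signature genes
  minus expression-bin-matched control genes; up and down scores combined as
  (up − down)/2. Running-sum GSEA with a gene-label permutation null.
- **TCR repertoire** — clonotypes keyed by the joined α+β CDR3 nucleotide
  sequences (highest-UMI contig per chain, multi-β cells dropped as
  doublets), expanded-clone (≥ 2 cells) overlap via Jaccard dissimilarity
  and UpSet-style shared counts at 1/2/3-cell cutoffs, and viral-specificity
  annotation by CDR3 amino-acid edit distance to a reference table under
  donor-HLA restriction (strict "< 1" threshold: exact matches).
- **Concordance** — cross-study log2FC sign contingency tables with an exact
  Fisher test (point-probability two-sided p).
- **Synthetic data with planted truth** — NB counts with subset effects and
  donor shifts, batched bulk cohorts, and clone-size-skewed paired-chain
  repertoires with planted viral clones, so every stage is testable without
  patient data.

## Worked example

`examples/01_simulate_and_signatures.py` simulates 4 donors × 2 tissues ×
5 subsets with a planted |log2FC| = 1 T<sub>RM</sub> program and runs the
full derivation:

```
simulated 1200 cells x 1200 genes, 40 planted TRM up genes
pseudobulk: 40 samples x 1182 genes (8 samples/group)
signature: 51 up / 44 down genes
recall of planted TRM genes: 0.900
mean log2FC on planted up genes: 1.018 (planted effect: 1.0)
```

90% of the planted T<sub>RM</sub> genes are recovered and the effect-size
estimate is essentially unbiased (1.018 vs the planted 1.0). The other
examples cover module scoring and the T<sub>EX</sub>/T<sub>RM</sub>-vs-TMB
regression (`02`), TCR overlap and viral annotation (`03`), cross-cohort
refinement and enrichment (`04`), and concordance plus PRPS normalization
(`05`).

A thin CLI mirrors the library
(`trmex simulate|pseudobulk|de|signatures|refine|score|tcr|concordance|run|demo`);
`trmex demo --seed 0` runs everything end to end and writes a
truth-recovery report with a content-hashed output manifest.

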