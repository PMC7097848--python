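# Methods

This note records the statistical model behind each stage of the pipeline,
the defaults and why they were chosen, and what the synthetic cohorts do and
do not establish about real data.

## Composite signature scores

A signature is an ordered list of gene symbols; the two built-ins are the
IFN-I signature (*PLSCR1, OASL, IFI6, IFIT3, IFITM3*) and the IL-36
signature (*IL1B, PI3, VNN2, TNFAIP6, SERPINB1*). Scoring has two steps:

1. **Calibrator normalization.** Each signature gene's expression (RPKM or
   qPCR relative expression) is divided by its value in a single calibrator
   sample. By default the calibrator is the healthy control whose
   signature-gene profile is closest — L1 distance on `log2(x+1)` — to the
   control median profile, with ties broken by control order. This is
   deterministic, robust to a single aberrant control, and makes a typical
   control score ≈ 1; any sample id can be supplied instead.
2. **Median aggregation.** The score is the per-sample median over the
   retained genes; an even count averages the two central values. Signature
   genes absent from the matrix, or zero in the calibrator, are dropped with
   a warning rather than pseudo-counted — the median over the remaining
   genes needs no imputation assumption. If nothing remains it is an error.

No log transform is applied inside the score: it is a fold-change median and
is displayed on a linear axis. The score is invariant to gene order and
scales linearly when a sample's signature genes are scaled uniformly; both
properties are tested against direct recomputation.

RPKM conversion is the standard `counts × 10⁹ / (length_bp × library_size)`
with library sizes taken as full-matrix column sums (not signature-gene
sums), which is the conventional definition and keeps the conversion
independent of the signature in use. qPCR input uses the standard
`2^−((Ct_target − Ct_reference) − ΔCt_calibrator)` conversion and then flows
through the same scoring path with `value_kind="relative"`.

## Differential expression

The engine is intentionally transparent rather than count-model based: a
two-sided Welch t test per gene on `log2(x+1)`, BH step-up FDR across all
tested genes, and a linear fold change `(mean_case + ε)/(mean_control + ε)`
with ε = 0.01 to keep genes silent in one group finite without materially
shifting expressed genes. Genes constant across both groups get p = 1.
Negative-binomial modeling, covariates and batch correction are out of
scope; the pipeline's consumers are the score/enrichment stages downstream.

The upregulation rule is **fold change ≥ 1.5 and FDR < 0.05** — inclusive on
the fold-change side, strict on the FDR side; the edge behavior is pinned by
tests. Top-N selection ranks upregulated genes by smallest p, breaking ties
by larger fold change, then lexicographic gene id; rank by p (rather than
FDR, which ties across whole rejection steps) is a recorded choice.

## Enrichment and overlap

Module over-representation is a hypergeometric upper tail per module with BH
across the tested modules (the same BH implementation as the DE stage).
Modules are intersected with the universe first; the universe should be the
genes detected in the experiment, not the genome — the hypergeometric model
describes draws from the sampled frame, and all tests here enforce
`query ⊆ universe`.

Overlap significance between two gene sets reports the hypergeometric tail
and a bootstrap confirmation: each resample redraws a size-matched `set_a`
uniformly without replacement from the universe, holding `set_b` fixed (the
minimal null that preserves `set_b`'s structure; symmetric redrawing is
available via a flag). The empirical p uses the add-one estimator
`(1 + hits)/(n + 1)`, so it is never exactly zero and has resolution
`1/(n+1)`. Agreement between the two routes is tested at 3 binomial
standard errors.

## Stratification and clinical association

The high/low cutoff is `median + 2·SD` of healthy-control scores, with SD
the sample standard deviation (n−1); a scaled-MAD alternative sits behind
`robust=True`. "High" means **strictly** above the cutoff — a patient at
the control envelope is not outside it.

The Fisher exact test is the two-sided point-probability ("Irwin") rule:
sum the hypergeometric point probabilities of all margin-preserving tables
whose probability does not exceed the observed table's, compared with a
relative tolerance of 10⁻⁷ so float rounding cannot flip a tied table. It
is computed by enumeration in log space and verified against an
exact-fraction oracle for every table with total ≤ 20. The doubling-one-tail
variant is not used; the point-probability rule is the one that reproduces
the worked 7/8-vs-3/9 flares table at p = 0.0498. Association building is
complete-case: samples with a missing flag are dropped, and a degenerate
margin yields a warning and p = 1.

Group comparisons follow the classical choices: equal-variance unpaired t
for two groups (Welch behind a flag), one-way ANOVA plus Dunnett many-to-one
comparisons for three or more, with the Dunnett family adjustment evaluated
numerically from a seeded generator (and tested against the two-group t in
the family-of-one reduction). Spearman correlation uses midranks; for
n ≤ 9 the two-sided p is exact by full enumeration of rank permutations
(the permutation distribution depends only on the rank multisets, which the
implementation exploits for caching), above that the t approximation.
Paired designs use the exact Wilcoxon signed rank (zero differences
dropped; exact up to n = 25) for two conditions and the Friedman chi-square
with Dunn pairwise z tests (Bonferroni family adjustment) for three or
more; missing cells are an error because the tests are paired.

Exact conditional tests are **conservative**: their discrete null rejection
rate at α = 0.05 sits below 0.05 (often far below at n ≈ 17). Calibration
properties for the Fisher association are therefore asserted as
super-uniformity (P(p ≤ α) ≤ α), not as uniformity of the p distribution —
no exact 2×2 test can produce uniform p-values at these sample sizes.

## Synthetic cohorts

The generator emulates a small blood case/control study. Per gene a
baseline `b_g ~ N(5, 2²)` on log2 RPKM. Each active case draws a latent
standard-normal pair with correlation ρ (default 0.9) and converts it to
program activations

```
a_IFN  = log2(fold_ifn)  · (1 + dispersion · z₁)
a_IL36 = log2(fold_il36) · (1 + dispersion · z₂)
```

added to the signature genes' log2 means; expression is
`2^(baseline + activation + N(0, noise_sd²))` with `noise_sd = 0.3`.
Controls (and inactive cases in the validation-style preset) carry no
program. The clinical flag is `Bernoulli(logistic(−0.7 + 1.35·a_IFN))` for
patients — ≈ 33% prevalence at zero activation rising to ≈ 88% at the mean
activation of a 4-fold program — and missing for controls. A counts mode
draws Poisson counts around the log-normal mean with random gene lengths to
exercise the RPKM conversion.

Default sizes mirror the emulated study designs: 9 cases vs 7 controls
(whole blood), and a validation preset of 17 patients (8 program-active vs
9 inactive) with 26 controls for the cutoff. Defaults `fold_ifn = 4`,
`fold_il36 = 3` plant a strong interferon program and a moderate IL-36
program.

**Dispersion** (the between-patient spread of activation, relative to the
log2 fold) is the one genuinely free parameter. It was fixed at 0.3 by a
design-stage power analysis: it spreads a 4-fold program over roughly 1.7-
to 9-fold across patients — the order-of-magnitude heterogeneity typical of
blood interferon scores — while keeping the per-gene effects detectable by
the DE stage at n = 9 vs 7 against ~2,000 background genes. Larger values
make gene-level discovery unrealistically hard at these sample sizes;
smaller values make patient scores implausibly homogeneous and starve the
score–score correlation of variance. Because dispersion multiplies
`log2(fold)`, setting `fold = 1` removes the program *and* its variance, so
null cohorts are exact nulls — type-I measurements are clean.

What the simulations do not capture: library-size and gene-length biases
beyond the Poisson counts mode, cell-type composition shifts (no
deconvolution), correlated background genes, batch structure, and
per-gene effect heterogeneity within a signature (available via config but
off by default). Passing tests therefore establish the correctness and
calibration of the pipeline's statistics under a clean generative model,
not the biological effect sizes of any real cohort.

## Problem sizes and numerical choices

Oracle sweeps run the Fisher test over every 2×2 table with total ≤ 20
(10,625 tables, exact-fraction oracle) and the hypergeometric tail over all
configurations at universe sizes 5, 9, 12, 15 (full subset enumeration).
Null calibration uses 2,000 simulated cohorts; power and score-coupling
recovery use 500; end-to-end module recovery uses 20; the outcome
association rate uses 300 — sizes at which the binomial error on each
reported rate is a few tenths of a percent to ~3%. Bootstrap overlap checks
use 10,000 resamples. All simulation seeds derive from a single
user-supplied seed through `numpy.random.default_rng`, and identical seeds
reproduce byte-identical cohort serializations.
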