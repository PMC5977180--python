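# Methods

This note documents the statistical models behind `exomewas`, the defaults
of the synthetic-data generator, the numerical choices that required a
decision, and what the tests do and do not establish about real data.

## Study design emulated

The pipeline targets an extreme small-cohort design: 8 sequenced cases
against public European reference panels used as controls (discovery panel
of 107, pseudo-replication panels of 107/91/99, and their merge), ~10⁴–10⁵
exonic biallelic SNVs, per-variant DANN deleteriousness scores in [0,1],
and external two-group expression studies for candidate-gene validation.
With 16 case alleles, asymptotic tests are off the table; everything is
exact or resampling-based, and the package's main job is to keep those
small-sample procedures honest.

## Synthetic-data generator

`simulate.gen_genotypes` draws ancestral allele frequencies from
Beta(0.15, 0.7) — chosen so that ~38% of variants have folded MAF > 0.05,
matching the common/rare split an exome scan of this kind sees — and
population-specific frequencies from the Balding–Nichols model
Beta(p(1−F)/F, (1−p)(1−F)/F). Defaults: F = 0.005 between European-like
panels (intra-continental differentiation), F = 0.1 when continental
contrast is wanted (MDS demonstrations). Genotypes are Binomial(2, freq);
cases are drawn from the discovery panel's realized frequencies, so
case-vs-discovery comparisons are null by construction unless signals are
injected.

Risk variants override frequencies per group (defaults emulate the
discovery effect sizes: case AF 15/16 vs control 0.09346, and 13/16 vs
0.1402). Burden genes append rare variants (control frequencies uniform on
0.002–0.03) whose case frequencies are `enrichment`× higher (default 10),
with DANN ~ Beta(8,2) against a Beta(2,2) background — the pathogenicity
contrast the weighted test is meant to detect. One global seed feeds named
`SeedSequence` sub-streams (frequencies, genotypes, DANN, burden), so each
stage is independently reproducible.

`simulate.gen_expression` produces log-scale Gaussian matrices with
mean-shifted DE genes. `var_prior_df` draws per-gene variances from a
scaled inverse chi-square around `noise_sd²` — exactly the empirical-Bayes
variance model — because homoscedastic data makes the shrinkage prior
degenerate (d₀ → ∞) and is not what arrays look like. Defaults for the
packaged pipeline use noise_sd 0.4 and |log₂FC| 1.2–2.0, effect sizes at
which a genuine biomarker clears BH-FDR in studies of 5–10 per group.

What the generator does **not** emulate: linkage disequilibrium along the
backbone (variants are independent given frequencies; LD machinery is
exercised by its own haplotype samplers in tests), genotyping/calling
error, missingness patterns correlated with batch, platform effects in
expression, and admixture gradients within panels. Passing tests therefore
demonstrate correctness of the statistics under the stated sampling models,
not robustness to those real-data artifacts.

## Single-point association

The allelic (2×2 allele-count) test was chosen over genotypic tests because
reconstructed allele counts reproduce the design's published odds ratios
exactly (15·194/(1·20) = 145.5). Missing genotypes are excluded per variant
per group; never imputed. The common-variant filter is strict
(control MAF > 0.05) and, for pseudo-replication scans, is applied on the
*discovery* panel's MAF so every panel tests the same variant set.

Three p-like quantities coexist deliberately:

- the ordinary two-sided Fisher exact p (probability-mass criterion, with
  1e-7 relative slack when comparing table probabilities) is the discovery
  p — valid and conservative; its achieved size at this design is ~0.034
  at nominal 0.05;
- the exact mid-p (half-weight on tables exactly as probable as observed)
  feeds λ and calibration diagnostics: measured over null scans it has
  size ~0.041–0.050 and λ 0.93–1.0 across MAF spectra, whereas the exact p
  deflates λ to ~0.6 and the Pearson χ² inflates it to ~1.3 on exome-like
  spectra at 16 case alleles;
- the odds ratio takes Haldane–Anscombe +0.5 on all cells only when a cell
  is zero, and only for display.

λ = median(qχ²₁(1−p))/0.45494. The permutation QQ envelope permutes
case/control labels preserving group sizes, re-runs the full scan (the
Fisher p for fixed margins is memoized, so permutation scans are lookups),
and takes per-rank 2.5/97.5 percentiles of the sorted −log₁₀ p. Envelope
bands are pointwise: on discrete p-values the sorted observed curve is
strongly rank-correlated, so a typical dataset sits inside the bands at
~99% of ranks while an occasional dataset crosses in long stretches; the
coverage test asserts the median across replicate datasets. Discovery
claims rest on the top ranks and the Bonferroni set, which are stable.

## Gene burden

Weights follow Madsen–Browning: q_j = (m_j+1)/(2n_j+2) from the cohort's
controls, w_j = 1/√(n_j q_j (1−q_j)). The DANN score enters as a
multiplicative per-variant weight (default `dann_mode=weight`). Two
alternatives are exposed: `gene_mean` multiplies base weights by the gene's
mean DANN — which leaves the within-gene rank-sum invariant, so it is a
labelling of the statistic rather than a different test (made explicit here
because "average score as covariate" designs are often described this
way) — and `off` for unweighted Madsen–Browning. Variants lacking a score
are dropped from weighting (logged); genes with no scored variants are
excluded.

The statistic is the case rank-sum with midranks. Permutation p is
(1 + #{perm ≥ obs})/(n_perm+1): never zero, valid under exchangeability.
Two regimes matter:

- with common variants the score is effectively continuous and p is
  uniform under the null (KS-checked);
- with rare variants most samples score exactly 0, the ≥-counting over
  massive tie groups makes p superuniform — conservative, not a defect,
  but uniformity tests must not be run in this regime.

Because the p floor at 999 permutations (10⁻³) exceeds a Bonferroni line of
0.05/500 genes, `burden_scan` escalates to 49,999 permutations for genes
whose first-stage p ≤ 0.01; both stages and counts are recorded in the
output metadata. An enriched gene whose 8 carriers outrank all controls
reaches the escalated floor 2×10⁻⁵, clearing the line.

## LD

EM for two-locus haplotype frequencies initializes at linkage equilibrium
and splits double-heterozygotes between cis/trans by current frequency
products; convergence at max Δf < 1e-10 or 1,000 iterations, with the
log-likelihood asserted non-decreasing. D′ CIs follow the Wall–Pritchard
convention: likelihood over |D′| ∈ {0, 0.01, …, 1} with allele frequencies
fixed at observed values and the sign taken from the EM point estimate,
normalized to a discrete posterior; lower/upper are the smallest grid
values with cumulative mass ≥ 0.05/0.95. Note the flat-posterior limit
puts the upper bound at 0.95, so "uninformative" is operationally "neither
strong LD nor strong recombination", not "upper ≈ 1". Gabriel thresholds
(0.70, 0.98, 0.90, 95%) are constants in `exomewas.ld`; blocks are
contiguous spans resolved longest-first, computed within candidate genes
and a 500 kb window.

## Expression

Per-gene two-group fit with pooled variance (d = n−2). Hyper-parameters by
moment-matching e_g = log s²_g − ψ(d/2) + log(d/2): the excess of var(e)
over ψ′(d/2) inverts to d₀ via a Newton solve of the trigamma equation;
no positive excess ⇒ d₀ = ∞ (full pooling, warned). Moderated
t = lfc/√(s̃²(1/n₁+1/n₀)) with d+d₀ df. The implementation is cross-checked
in tests against an independent R/limma run on the same matrix (t, p, d₀,
s₀² to 1e-6) and against a direct evaluation of the shrinkage formula
(1e-10). BH FDR goes through `statsmodels`; AUC through `scikit-learn`'s
Mann–Whitney formulation, verified against exhaustive pair counting, and
reported oriented (≥ 0.5 with a direction flag). The cross-study candidate
report flags direction discordance only among FDR-significant results
(emulating tissue-dependent regulation).

## Ancestry and relatedness

The ancestry estimator is a supervised simplex-constrained least-squares
projection of dosages onto known reference frequencies (SLSQP, analytic
gradient, deterministic) — appropriate because the question is confirmatory
QC against known panels, not unsupervised structure discovery. Relatedness
uses uncorrected method-of-moments IBS-class expectations from pooled
frequencies; adequate at ≥ ~100 samples and a few hundred common loci for
screening duplicates (π̂ ≈ 1), parent-offspring (≈ 0.5) and unrelated
pairs (≈ 0), which is all the pipeline asks of it.

## Problem sizes and determinism

Packaged defaults run the full pipeline at 4,000 background variants and
500-gene expression studies; calibration analyses use 2,000 common
variants, 200-permutation envelopes, and 500-gene burden scans with
999→49,999 adaptive permutations. These sizes give stable estimates of
every reported quantity (λ sd ≈ 0.03 at 2,000 variants; envelope and
burden discovery are exact-set stable across seeds). Every stochastic
stage takes an explicit seed derived from one global seed; reports and
TSVs are bit-identical across reruns on one platform.

## Known limitations

No covariate-adjusted (logistic/regression) association; no SKAT-style
variance-component burden tests; no unsupervised ancestry (K inference);
no genotype imputation; LD blocks only within candidate genes; expression
preprocessing (normalization, probe mapping, batch correction) is assumed
done upstream. The exact test's conservativeness at 16 case alleles is
intrinsic — power claims at this design should be read against the
simulated operating characteristics, not nominal α.
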