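# Methods

`nwdose` analyses factorial nitrogen-by-water (N-by-W) dose experiments in
plants. Its premise is that a gene's expression may track any of four
distinct functions of the two supplied doses: the absolute amount of
nitrogen (*N*-moles), the amount of water (*W*-volume), the nitrogen
concentration (*N/W*, which rises as soil dries at fixed N), or the
synergy of the two (*N×W*, maximal when both are high). The package
classifies genes among these possibilities, checks how fast such responses
arise, reproduces the classification under categorical field conditions,
and asks whether the resulting gene classes carry phenotypic information.

## The lab dose model

Per gene, counts are modelled with a negative-binomial (NB) log-link GLM

    log E[y_ij] = log s_j + α_i + b_N N_j + b_W W_j + b_{N/W} (N/W)_j + b_{N×W} (N×W)_j

where `s_j` is the sample's median-of-ratios size factor. Predictors are
z-scored across samples (population SD, so variance is exactly 1); the
interaction column is the elementwise product of the standardized main
effects, re-standardized. Standardization makes the coefficients
comparable, which the N-vs-N/W weight statistic (below) presupposes, and
the product-of-standardized construction keeps the interaction column
essentially orthogonal to the main effects on the dose grid (|r| < 0.2
on the default 4×4 design, versus near-collinearity for a raw product).

The lab design encodes N as the amount supplied: concentration (mM) ×
the fixed 130 mL feed volume, i.e. mmol. The four defaults are 0.625,
1.25, 2.5, 5 mM crossed with water volumes 16.25, 32.5, 65, 130 mL,
each combination in triplicate (48 samples).

**Dispersion.** Each gene's NB dispersion φ (variance = μ + φμ²) is
estimated by maximizing the Cox–Reid adjusted profile likelihood
(−½ log det X'WX correction) at the Poisson fitted means, started from a
method-of-moments value and floored at 1e-8. The adjustment compensates
for the five mean parameters estimated from 48 observations; without it
the per-term Wald tests run anticonservative (~0.07 at nominal 0.05 on
null simulations; ~0.055 with it). No empirical-Bayes shrinkage across
genes is applied, which costs power at low counts relative to shrinkage
estimators but keeps every gene's test self-contained.

**Backward elimination.** Wald p-values for the four terms are BH-adjusted
per term across genes. A gene whose four adjusted p-values all fall below
`model_alpha` (default 0.005) is classed "full". Otherwise the term with
the largest adjusted p is dropped (ties broken toward the later term in
the fixed order N, W, N/W, N×W — arbitrary but deterministic), the reduced
model is refit at the full-model dispersion, and adjustment is recomputed
per term across the genes active at that stage. Iterating down to
one-term models visits the catalogue of 14 reduced forms (4 three-term,
6 two-term, 4 one-term subsets); genes accepted by no form are
"unclassified" and excluded downstream. Every gene records its
elimination trace so the acceptance rule can be audited after the fact.
BH adjustment is per term across genes (not pooled over term×gene tests);
at reduced stages genes carrying different subsets of the same size are
pooled per term name.

**N-moles vs N-molarity weight.** For genes classed N, N/W or N+N/W,
`n_weight = 100·|b_N| / (|b_N| + |b_{N/W}|)` with an absent term
contributing zero; the N/W weight is its complement. Absolute values make
the weight well-defined for repressed genes. On data where genes are
driven purely by one of the two predictors the statistic is strongly
bimodal at 0 and 100.

## Synthetic data

The generator inverts the analysis model: per gene a baseline log-mean is
drawn uniformly on [log 50, log 500] (a moderately expressed gene), class
effects of magnitude `effect_size` (default 1.0 on the natural-log scale)
are placed on the class's standardized predictors with a random common
sign (induced/repressed 50/50), and counts are NB draws at dispersion
φ = 0.05. Defaults mirror the study conditions the package is tested
under: the 4×4×3 lab design, a 19-cultivar 2×2×3 field design, and
10-timepoint (0–120 min) paired treated/control courses in triplicate
with a saturating uptake curve `1 − exp(−t/30 min)`.

Field effects act on 0/1 fertilizer/irrigation indicators; synergy genes
get a positive log-scale interaction, concentration genes a negative one,
and every cultivar contributes a Gaussian baseline offset
(`genotype_sd`, default 0.3). Time-course responders shift their treated
log-mean by log(fold) from a per-gene onset time onward.

What the generator does **not** emulate: per-gene baseline distributions
estimated from real data, correlated gene modules beyond the shared dose
patterns, batch effects, library-size heterogeneity (available only as an
explicit lognormal `size_factor_sd` knob, default off), and zero
inflation. Passing tests therefore demonstrate the procedures recover the
model they assume, under realistic counting noise — not that the model is
correct for any particular organism.

One consequence worth knowing: median-of-ratios normalization assumes
most genes are not dose-responsive. Simulations with a high
dose-responsive fraction and few genes (a few hundred) distort the size
factors enough to push spurious classes onto null genes; the effect
shrinks as gene count grows and is immaterial at the 2 500-gene scale the
recovery checks use.

## Count filtering

Genes with total counts below 128 across samples, or with a median count
of zero, are removed before modelling. The median rule is stated in its
only non-vacuous reading for non-negative counts (a literal "median < 0"
would never remove anything): genes whose median is 0 — expressed in
fewer than half the samples — are dropped.

## Time-course detection

Both arms are normalized jointly; expression is log2(normalized + 1).
Per gene, a Gaussian working model fits a natural cubic spline over time
(3 interior knots at the 25/50/75% quantiles of the timepoints, 5 df per
arm including the intercept) with arm-specific curves, and compares it by
F-test against the model with a shared curve plus an arm offset. The
Gaussian-on-log2 choice matches the scale the spline is defined on and
makes the per-gene test a closed-form nested-model comparison;
replicates are pooled into the fit rather than averaged first. A gene is
DE when the BH-adjusted p falls below `assoc_alpha` (0.05) and its
combined count over all columns of both arms exceeds
`timecourse_min_total` (100; the combined-arms reading of "total over all
timepoints" is used). DE genes are binned per timepoint by the
treated-arm mean normalized expression ratio against the treated t=0
mean: strictly above 1.25 is "up", strictly below 1/1.25 is "down"; a
gene may occupy several timepoints. Note that a responder whose onset is
late can be noise-binned in the wrong direction at pre-onset timepoints;
direction fidelity is exact when the shift spans all positive timepoints.
Per-timepoint DE counts are correlated (Pearson) with the tracer-uptake
curve.

## Field analysis

The field model is an NB GLM on categorical N (0 vs 150 kg/ha), W
(deplete vs replete), their interaction, and a genotype covariate
(cultivar dummies) which absorbs cultivar differences and is never used
to subset. Term significance is by likelihood-ratio (analysis-of-
deviance) tests at the full-model dispersion, BH-adjusted per term.
Classification: a significant interaction assigns N×W when its log2 fold
change is positive and N/W when negative (positive means expression is
driven by matched high/high–low/low dose combinations, the synergy
signature; negative means mismatched combinations, the concentration
signature); otherwise a single significant main term assigns N or W. A
gene's direction is the sign of its high-N/high-W contrast
(b_N + b_W + b_{N:W}); the same convention defines direction in the field
generator. Because genotype enters as a free covariate, adding any known
per-cultivar offset to the model offset leaves the dose-term inference
unchanged up to optimizer tolerance — the package exposes an
`extra_offset` argument so this invariance can be verified directly.

Lab–field conservation intersects per-class gene sets requiring equal
direction labels on both sides. For lab genes the direction is the sign
of the class-defining coefficient (for multi-term genes, the high-dose
contrast).

Phenotype model selection runs the same backward elimination as the gene
models, but as Gaussian OLS on log2 phenotype with raw per-term p-values
(a single response, so cross-gene FDR does not apply) and cultivar
dummies for field designs; the classical categorical N×W ANOVA F and p
are reported alongside. The grain-yield formula
`weight × ((100 − moisture)/86) / area` treats 86 as the opaque 14%-
moisture reference constant; it is exactly homogeneous of degree 1 in
weight and −1 in area.

## Association statistics

*Pearson/FDR screen*: vectorized per-gene correlation with a phenotype,
two-sided t-based p, BH across genes; constant genes are flagged rather
than dropped.

*Monte-Carlo overlap*: the null redraws |A| genes uniformly without
replacement from the declared background and counts overlaps with B;
`p = (1 + #{null ≥ observed}) / (1 + n_perm)` (add-one convention, never
exactly zero). Because the null overlap is hypergeometric, the test is
validated against the closed-form tail on random configurations.

*Eigengenes*: PC1 of the gene set's log2(normalized + 1), gene-centered
expression via SVD; per-sample scores and the PC1 variance proportion are
reported. The association statistic is |Pearson r| against the phenotype
(absolute value because a principal component's sign is arbitrary); the
null rebuilds eigengenes from random same-size sets drawn from the
background (the filtered expressed genes), with the same add-one p. The
pseudocount of 1 before log2 handles zero counts.

A caveat the synthetic experiments expose: if the background's only
covariation structure is the very pattern under test, random sets
containing a few such genes produce eigengenes aligned with it and the
null concentrates near the observed statistic. Power statements therefore
use backgrounds mixing all four dose classes with nulls, the analogue of
a transcriptome with many co-existing response programmes.

## Numerical choices and degenerate inputs

- NB dispersion floored at 1e-8 and capped at 50; bounded scalar search
  on log φ (xatol 1e-3), falling back to the method-of-moments start if
  the search stalls at a worse likelihood.
- Fit failures (separation, non-finite coefficients) flag the gene
  "unclassified"/non-converged with a diagnostic; genes are never dropped
  silently.
- Constant genes: correlation undefined → flagged; unit-interval
  normalization maps them to all zeros; identical counts in every sample
  fit with near-zero coefficients and adjusted p ≈ 1.
- An all-zero sample makes size factors undefined → error naming the
  sample; an empty post-filter matrix warns and returns empty.
- Ties in the elimination (equal adjusted p) drop the later term in the
  fixed order; a zero interaction fold change with a significant
  interaction is flagged as a tie, not assigned.

## Problem sizes

The test suite and the acceptance script size their simulations to be
decisive yet quick: classifier recovery at 2 500 genes × 48 samples
(the scale at which normalization is unbiased), field recovery at 250
genes over a 6-cultivar × 2 × 2 × 2 design, time-course calibration and
power at 1 000 genes × 60 columns, eigengene null uniformity at 500
repeats × 200 permutations on a 16-sample design, and eigengene power at
20 simulation seeds × 500 permutations. Full-scale permutation counts
(n_perm = 10 000) remain the library defaults.

## Known limitations

- No empirical-Bayes dispersion moderation: power at low counts is below
  what shrinkage-based tools achieve; the classification *procedure* is
  unaffected.
- The greedy single-path elimination can mis-class genes whose true form
  is a multi-term subset when one term sits near the threshold; it never
  searches subsets exhaustively by design.
- Wald tests in the lab model and LRTs in the field model are asymptotic;
  at 48 samples they are mildly anticonservative even with the Cox–Reid
  adjustment.
- The field W factor is binary by construction; no soil water-potential
  modelling is attempted.
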