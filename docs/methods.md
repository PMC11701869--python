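# Methods

`frontloadseq` implements the statistical chain of a reciprocal-style coral
transplant experiment: colonies of *Pocillopora* collected from a highly
variable reef-flat habitat and a stable reef-slope habitat, grown for weeks
under stable or variable seawater pCO₂, profiled by 3′ tag sequencing
(gene-level counts), and assayed for skeletal micromorphology. The package
covers count quality control and variance stabilization, per-gene
negative-binomial mixed models, the frontloading classifier, signed
co-expression networks, length-bias-corrected GO enrichment, and linear
mixed models for skeletal features — together with a synthetic-data
generator that plants known truth for every stage.

## The count model

For gene *g* and sample *j* the observed count is

    y_gj ~ NB(mu_gj, alpha_g),      Var = mu + alpha mu^2
    log mu_gj = log s_j + x_j' beta_g + u_g,genotype(j)
    u_g,k ~ N(0, sigma_u^2)

* `s_j` — median-of-ratios size factors (geometric mean 1), the standard
  normalization for sequencing depth.
* `x_j` — sum-to-zero (±1) contrasts for origin (flat = +1), treatment
  (variable = +1) and their product, so each type-III Wald test has one
  degree of freedom and main effects stay interpretable under interaction.
* `u` — a colony (genotype) random intercept: fragments of one colony are
  clones and share expression idiosyncrasies. Colonies are nested within
  origin.
* `alpha_g` — a fixed per-gene dispersion supplied to the fit. The default
  is the trended estimate `alpha(mu) = alpha_asym + alpha_extra / mu`
  obtained by robust (3-MAD-trimmed, iterated) least squares of per-gene
  method-of-moments dispersions on 1/mu; gene-wise estimates are also
  available. Method-of-moments dispersions computed on the raw count
  matrix absorb the colony variance component, which makes within-colony
  Wald tests conservative (measured empirical size ≈ 0.02 at alpha = 0.05
  under the generator's defaults); supplying dispersions that exclude the
  colony component restores nominal size (≈ 0.05). This trade-off is
  inherent to any pipeline that estimates dispersions marginally before
  fitting a mixed model.

The colony intercepts are integrated out by a Laplace approximation.
Because colonies partition samples, the penalized inner problem separates
into one scalar Newton solve per colony (tolerance 1e-8, damped steps);
the outer problem optimizes `(beta, sigma_u)` by L-BFGS-B with
`sigma_u >= 0` (at most 200 objective evaluations, tolerance 1e-6 on the
projected gradient). The Wald covariance is the inverse observed
information of the Laplace objective, including the `sigma_u` row when the
variance is off the boundary. A single fit agrees with glmmTMB (nbinom2,
fixed dispersion, same contrasts) to ~1e-3 on coefficients and ~1e-5 on
the random-intercept SD; with `sigma_u = 0` data the fit collapses onto
the ordinary NB GLM. Genes whose fit fails to converge are flagged and
excluded from DE tables and frontloading, mirroring how non-converging
genes are dropped in practice.

q-values are computed per term: pi0 is estimated from pi0(lambda) =
#{p > lambda} / (m (1 − lambda)) on lambda = 0.05 … 0.95, smoothed by a
least-squares cubic and read at lambda = 0.95 (a cubic smoothing spline
with ~3 effective df over 19 knots is numerically the same curve); for
fewer than 100 p-values pi0 = 1 (Benjamini–Hochberg) is used.

## Variance-stabilizing transform

The VST is the calibrated integral of the reciprocal square-root of the
NB variance function,

    g(x) = ∫₀ˣ du / sqrt(u (1 + alpha_extra) + alpha_asym u²),

evaluated by trapezoidal quadrature on a log-spaced grid (the first panel
uses the exact small-x antiderivative), interpolated with a monotone
cubic, scaled by `sqrt(alpha_asym)/ln 2` so that differences approach
log₂ ratios for large counts, and anchored so the top grid point maps to
log₂ of itself. The transform is strictly increasing, finite at zero, and
flattens the per-gene SD-vs-mean relationship (fitted slope within
±0.05 where log₂(x+1) is strongly negative).

## Frontloading

Using model-estimated cell means m (random effect at zero, normalized
scale; never raw cell averages):

* control ratio `C = m(flat,stable) / m(slope,stable)`
* fold-change ratio
  `F = [m(flat,variable)/m(flat,stable)] / [m(slope,variable)/m(slope,stable)]`
* frontloaded ⇔ `C > 1` and `F < 1` (strict; a gene exactly on a boundary
  is not frontloaded).

`C` and `F` are scale-invariant, and swapping origin labels maps both to
their reciprocals. An alternative reading of the published criterion that
builds the control ratio from the flat-origin variable-treatment cell is
available behind a configuration switch; the default follows the formulaic
definition (both ratios from within-treatment comparisons).

The classifier has no significance filter, so genes whose true means sit
exactly on a boundary (C = F = 1) are called frontloaded with substantial
probability by estimation noise alone — for an exact null the asymptotic
false-positive rate is P(C>1, F<1) = 3/8, from the −1/√2 correlation of
log C and log F under equal per-cell variances. Recovery of planted labels
is therefore validated on a scenario whose genes all sit at 2-fold
distances from both boundaries, spread over the four (C, F) quadrants with
10% in the frontloaded quadrant; under those conditions (colony SD 0.3,
46 samples) sensitivity and specificity both exceed 0.9. On data
containing boundary-null genes the frontloaded *fraction* necessarily
includes a noise floor — a caveat that applies equally to real data.

## Co-expression networks

Signed adjacency `a_ij = ((1 + cor_ij)/2)^beta` with soft power beta = 5,
topological overlap

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),

and average-linkage clustering of 1 − TOM. Module detection is a dynamic
hybrid cut implemented bottom-up over the merge sequence: growing branches
absorb small straggler clusters; when a branch that is large enough
(≥ 30 genes), internally tight and clearly separated meets another
substantial cluster, both sides are closed and assessed. A closed branch
becomes a module if, after shedding members far from its core (the 30
most-connected members; keep below core scatter + half the headroom to
the attachment height, and require the minimum size among members within
a quarter of the headroom), it satisfies: normalized mean scatter ≤
0.64 + 0.075·deepSplit, a gap of at least (1 − that ceiling)·3/4 between
attachment and scatter, and scatter ≤ 0.85 × attachment height (this
ratio is what rejects diffuse branches of featureless data, where scatter
and attachment heights coincide). Heights are normalized between the 5th
percentile and the maximum of the merge heights. A PAM-like second stage
assigns each leftover gene to its nearest module when its mean
dissimilarity is below the module radius; everything else is grey.
The reference hybrid cut has many unpublished internal constants, so the
correctness bar here is planted-partition recovery (adjusted Rand index
≥ 0.9 on planted blocks, no modules on featureless data), not
label-for-label equality with the reference tool.

Module eigengenes are the first principal component of the standardized
member expression, unit variance, sign-oriented to positive mean member
correlation. Modules whose eigengenes correlate above 0.85
(dissimilarity < 0.15) are merged iteratively with recomputation after
each merge. Module–trait relations are Pearson correlations with
t-distribution p-values (pairwise deletion, n − 2 df), rows and columns
ordered by average-linkage clustering on correlation distance. Modules
are named by the conventional colour sequence in decreasing size order.

## GO enrichment with length bias

Longer genes accumulate more reads and are more likely to be flagged DE
at a fixed effect size. The probability weighting function (PWF) is fit
by isotonic regression of flag proportions on length-rank-binned mean
lengths (50 equal-count bins by default — a few hundred genes per bin at
transcriptome scale keeps the monotone fit near-flat when flagging is
length-independent; 200 bins visibly overfits bin noise), interpolated to
per-gene weights and calibrated so the mean weight equals the flag rate.
Each category is tested against the Wallenius noncentral hypergeometric
upper tail with odds
`omega = [w̄_in/(1 − w̄_in)] / [w̄_out/(1 − w̄_out)]` (the standard
two-group collapse of per-gene weights; the exact multivariate Wallenius
is intractable at scale). With omega = 1 the test reduces exactly to the
central hypergeometric. Unannotated genes remain in the universe.
BH adjustment is step-up with monotonicity enforcement; a user-supplied
parent-term map provides a rollup summary in place of semantic reduction.

## Micromorphometry

One linear mixed model per skeletal feature (coenosteum width, corallite
diameter, spine length, RAD area, RADs per spine): fixed origin ×
treatment in sum-to-zero contrasts, colony random intercept, REML
(statsmodels MixedLM). Type-III Wald chi-square tests use the
fixed-effect covariance. EMMs are cell predictions at random effect zero
with delta-method SEs; in balanced designs they equal raw cell means.
Pairwise contrasts are adjusted with the studentized range for a family
of four means; contrasts are studentized on the residual degrees of
freedom (the classical Tukey HSD convention) rather than the normal
limit — at bench-scale replication the finite-df reference keeps the
family-wise error near nominal (≈ 0.05–0.06 measured) where the normal
limit drifts above 0.06. The per-term ANOVA keeps the asymptotic Wald
chi-square, matching how such tests are conventionally reported.
`percent_change(reference, new) = 100 (new − reference)/reference` backs
the worked percentage summaries.

## The synthetic generator

`SimDesign` defaults encode the study layout: 12 colonies per origin, one
fragment per colony per treatment (48 samples; the analysis set used in
validation drops one flat colony's two fragments to mirror the
outlier-driven exclusion, giving 11/11/12/12), baseline means log-uniform
on [10, 1000], NB dispersion trend (0.1, 5), colony SD 0.3 (log scale),
size factors log-uniform on [0.7, 1.4], and 2-fold planted effects with
class proportions 70% null / 10% origin / 5% treatment / 5% interaction /
10% frontloaded. Planted frontloaded genes hold flat expression flat
across treatments and upregulate the slope origin under the variable
treatment, so their true C and F satisfy the defining inequalities
exactly. Planted co-expression modules multiply the mean by
exp(loading × latent factor) with the latent factor shared within module;
module members are drawn from the null class so module structure is not
confounded with the planted contrasts. Gene lengths are log-normal
(median ≈ 1.8 kb); a length-bias parameter lengthens planted DE genes so
that flag probability rises with length, and two GO categories are
planted with members drawn at 4:1 odds from DE genes to give enrichment a
true positive. Diel pCO₂ series are sinusoids sampled every 15 minutes
(a typical autonomous-sensor cadence); the amplitude summary is the mean
daily max − min. Micromorphometric values are cell mean + colony
intercept + residual, colonies nested in origin, with paper-scale default
cell means.

What the generator does not emulate: genes are independent given their
class (no correlated background co-expression beyond the planted
modules), dispersions follow the trend exactly (no gene-wise dispersion
scatter), library composition effects beyond scalar size factors, batch
or lane effects, and symbiont-host read mixtures. Passing tests therefore
demonstrate correctness of the estimators and classifiers under the
stated model, not robustness to every artefact of real tag-seq data.

## Validation problem sizes

The acceptance benchmarks use 200 genes for classifier recovery, 2,000
null genes for Wald-test size, 100 random 10-node matrices for the TOM
oracle, 3 planted blocks of 60 genes for module recovery, 3,000 genes for
VST flattening, and 2,000 null simulations (96 observations, 6 colonies
per origin) for the Tukey family-wise error — sizes at which each check
is statistically informative while the full battery runs in a few
minutes on one CPU.

## Known limitations

* The Wald tests are asymptotic; with 24 colonies the origin (between-
  colony) test runs slightly hot (~0.065–0.07 at nominal 0.05). Interaction
  and treatment tests are well calibrated.
* Dispersion shrinkage (empirical-Bayes toward the trend) is not
  implemented; the trend itself or gene-wise MoM values are the options.
* The hybrid tree cut is behaviour-compatible, not constant-for-constant
  identical, with the reference implementation; exact module counts on a
  given real dataset may differ.
* Outlier flagging (PCA distance, median + 5 MAD) is a documented,
  testable stand-in for the visual inspection plus duplication-rate
  screening used in practice; manual exclusion by sample id is supported.
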