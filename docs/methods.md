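# Methods

This note documents the models, estimator conventions, default parameter
choices and known limitations of `rilgs`. It is written for a reader who
wants to know exactly what the package computes and why the defaults are
what they are.

## The simulated study design

The generator emulates a breeding-study design that is common for
cool-season grain legumes: three elite parent cultivars crossed pairwise,
three RIL populations of roughly equal size (defaults 102 / 100 / 104
lines) derived by single-seed descent, genotyped with a GBS-like sparse
SNP assay, and phenotyped for a yield-like and a protein-content-like
trait in randomized complete blocks (3 replicates) across 3 environments.
Protein yield is never simulated as a trait of its own: it is computed per
plot as `yield × protein/100`, exactly as it would be from field data.

**Parents and connectedness.** Parent 1 carries the reference allele at
every marker; parents 2 and 3 are drawn marker-wise so that each pairwise
divergence (fraction of markers at which two parents differ) matches its
target in expectation. Defaults (0.25 between the two "local" parents,
0.35 from each to the third) encode the typical situation where one
founder is genetically more distant. Because populations only ever inherit
alleles from their two founders, an allele private to the third parent
can never appear in the cross that excludes it — the property that makes
inter-population prediction across connected crosses meaningful.

**Meiosis.** Gametes are generated per chromosome as a two-state Markov
chain along the marker sequence with switch probability given by Haldane's
map function, r = (1 − exp(−2d/100))/2 for d cM — no crossover
interference. `generations` counts selfing meioses applied to the F1, so
`generations = 1` yields F2 genotypes and expected residual
heterozygosity is 0.5^g; with the default g = 6 about 1.6% of calls at
segregating markers are heterozygous, and they are kept (coded 1), since
real F6-derived lines are not perfectly inbred.

**Trait architecture.** Both traits share one set of causal loci (default
100, drawn among polymorphic markers); effect sizes are bivariate normal
with correlation equal to the between-trait genetic-correlation target
(default 0.15, slightly positive). Genetic values are centered and
rescaled so the realized line-value variance equals S²_G *exactly*
(finite-sample standardization). GEI deviations are iid normal per
line × environment — the *unrestricted* compound-symmetry structure, which
is the estimand of REML with an iid genotype-within-environment random
effect — drawn with the same between-trait correlation, and rescaled by a
single factor so the realized interaction mean square (sum of squared
double-centered deviations over (n−1)(e−1)) equals S²_GE exactly. Row
centering of the deviations was considered and rejected: it makes the GEI
orthogonal to line means, which biases the standard EMS/REML genotypic
variance estimator downward by S²_GE/e and breaks the equivalence between
the closed-form EMS estimates and REML that the test suite asserts.

**Default variance components.** The yield-like trait uses S²_G = 0.575,
S²_GE = 1.435 (interaction-dominated; ratio 0.40) around a mean of 4.60
t/ha; the protein-like trait uses S²_G = 0.724, S²_GE = 0.302
(genetics-dominated; ratio 2.39) around 24.27% dry matter. Residual plot
variances are not independent knobs: they were calibrated once by
inverting the multi-environment heritability formula at the heritability
levels such trials report (≈ 0.52 for yield, ≈ 0.82 for protein content)
with e = 3 environments and n = 3 blocks, giving S²_e ≈ 0.472 and 0.524.
A useful consequence — and a genuine check of internal consistency — is
that the *derived* protein-yield trait then shows a multi-environment
heritability near 0.54 without ever being parameterized. Environment
fixed effects (±1.7 t/ha for yield, ±1.05% for protein) echo the spread of
environment means in such trials; block effects default to zero.

**Missingness.** Entry (i, j) is masked with probability
1 − (1 − mpm_j)(1 − mps_i), so marginal per-marker and per-sample rates
match the requested profiles when the other profile is zero. Masking is
deterministic given the seed.

**What the generator does not emulate.** No sequencing reads, depths or
genotype likelihoods; no genotyping error; no spatial field trends or
year-specific climate drivers; no selection or drift during line
development; marker density and map length are arbitrary defaults (7 × 100
cM, configurable), not a real map. Tests passing on these panels show the
estimators are correct and internally consistent under the stated model —
they do not certify behavior under model violations real data may carry.

## Variance components and derived statistics

For balanced randomized complete blocks the estimators are closed-form
expected-mean-squares (EMS) solutions; all random effects are treated as
unrestricted iid (the convention under which EMS equals REML on balanced
data with interior estimates, verified against an independently coded
EM-REML to 1e−6 in the tests). The pooled two-way analysis uses

- S²_e = MS_res,
- S²_GE = (MS_GE − MS_res)/n,
- S²_G = (MS_G − MS_GE)/(e·n),

with F-tests of genotype against the GEI mean square and GEI against the
residual. The nested analysis (populations R, genotypes within
populations) adds S²_R, S²_G(R), S²_RE, S²_G(R)E by the analogous EMS
equations; with unequal population sizes the coefficients use the mean
lines-per-population and the result is flagged approximate. Negative
method-of-moments estimates are truncated at zero and flagged. An EM-REML
fallback (`reml_components`) handles unbalanced layouts at small scale.

Derived quantities follow the standard genotype-mean-basis definitions:
CV_g = 100·S_G/m; H² = S²_G/(S²_G + S²_e/n) within one environment and
S²_G/(S²_G + S²_GE/e + S²_e/(e·n)) across environments; BLUPs are
H²-shrinkage of line means toward the grand mean (the shrinkage target is
configurable; per-environment BLUPs feed the genomic-prediction and GWAS
stages). Genetic correlation across environments is r/(H₁H₂) — reported
raw with a clamped companion value, since noisy H estimates can push it
beyond |1|. Genetic correlation between traits within an environment uses
the genotypic covariance from two-way MANOVA mean cross-products,
Cov_G = (MCP_G − MCP_e)/n, with a first-order delta-method standard error
(variances of mean squares approximated as 2·MS²/df and of cross-products
as (MCP² + MS_x·MS_y)/df).

## Whole-genome regression

All models regress on allele doses centered by training-column means,
without scaling (effects in dose units); incomplete matrices are refused
rather than silently mean-imputed.

**rrBLUP.** The ridge system û = Xcᵀ(XcXcᵀ + λI)⁻¹(y − μ̂) is solved in
kinship form after an eigendecomposition of XcXcᵀ; λ = σ²_e/σ²_u is
estimated by maximizing the restricted likelihood on a log-grid over
[1e−5, 1e5] refined by bounded scalar optimization (boundary hits are
flagged). The intercept is the GLS mean under the fitted covariance.

**Bayesian samplers.** Single-site Gibbs with residual updating.
Bayesian A: per-marker scaled-inverse-χ² effect variances (df 4.1, scale
from var(y)·h²_prior/Σvar(x_j) with h²_prior = 0.5). Bayesian C: common
effect variance plus inclusion indicators with π ~ Beta(1, 9), π sampled.
Bayesian Lasso (Park–Casella): normal-exponential mixture; the λ²
hyperprior is Gamma(shape 1, rate 1/λ²₀) with λ²₀ = 2·Σvar(x)·(1 −
h²_prior)/h²_prior, i.e. the prior mean of λ² is the value at which the
double-exponential prior variance matches the heritability guess. The
shape-1 choice matters: a sharper hyperprior (e.g. rate 1) pins λ² near
its prior ratio through the Στ²/2 feedback and lets the model absorb
noise on null data; with the diffuse choice the posterior residual
variance on pure-noise responses is calibrated (checked in the tests).
Default chain 12,000 iterations / 2,000 burn-in / thin 5; the test-suite
and acceptance runs use 1,500/300/4, which is sufficient for stable
posterior-mean effects at the ~300-line scale while keeping desk-scale
runtimes. Constant responses short-circuit to a zero-effect fit.

## Cross-validation

Training targets are per-line means of environment-wise BLUPs over a pair
of environments; validation is against the BLUPs of the held-out
environment. Intra-population: stratified k-fold (population proportions
per fold within one line), folds re-drawn each repetition, predictive
ability r_ab (Pearson) computed within each population to remove
population-mean bias, then averaged folds → repetitions → environment
sets → populations → grand mean, in that fixed order (with unbalanced
missing cells the order matters, so it is part of the contract).
Inter-population: fit on all lines of one population, score within each
other population; reported per training population and overall.
Undefined correlations (fewer than 3 validation lines, or either vector
constant to within 1e−10 relative tolerance) are recorded as missing and
excluded from means — never zero-filled, which would bias the averages.

## GWAS

Kinship is the standardized (Astle–Balding) estimator
K = (1/M)Σ(x−2p)(x−2p)ᵀ/(2p(1−p)); structure covariates are the first 10
principal components (sign-fixed, truncated at rank with a warning).
Variance components of the null model y = Wα + g + e, g ~ N(0, Kσ²_g),
are estimated once by REML on the eigendecomposition of K; every marker
is then tested by GLS under the fixed covariance V = Kσ²_g + Iσ²_e
(P3D/EMMAX scheme; per-marker REML would cost M times more for little
gain at this scale). After rotation by V^(−1/2) the test is an OLS Wald
t-test; explained phenotypic variance is the squared partial correlation
between rotated marker and rotated phenotype × 100. Population labels are
*not* fitted as fixed effects — structure is handled by K and the PCs
only. Multiple testing: Bonferroni α/M and Benjamini–Hochberg step-up
(threshold reported as undefined when no rank passes, with a top-N
fallback exposed for exploration). Significant markers are clustered into
loci by single linkage over pairs with allelic-correlation R² > 0.8
(connected components at a fixed cut).

A note on null calibration: the uniformity checks simulate structured
panels with *independent* markers. With linked markers the per-marker
p-values remain marginally calibrated (rejection rate ≈ 5% at α = 0.05)
but are locally correlated through LD, which over-disperses
whole-distribution statistics such as the Kolmogorov–Smirnov test; the
check targets structure correction, not LD, so independence is the right
null design.

## Selection-efficiency calculator

Annual gains are ΔG'_G = i_G·r_Ac·s_A/t_G and ΔG'_P = i_P·H·s_A/t_P, with
t_G = 0.5 years (two genomic cycles per year) and t_P ∈ {1, 2}. Intensity
uses the large-sample truncated-normal closed form i(p) = φ(z_p)/p rather
than printed tables. Cost parity with per-genotype costs 220 € (field
evaluation) and 60 € (genotyping) multiplies the candidate count by 11/3
≈ 3.7 and divides the selected fraction accordingly; the multiplier is
kept unrounded internally (20%/3.6667 = 5.5%, whereas dividing by the
displayed 3.7 would print 5.4%). `intensity_ratio` reproduces
printed-table arithmetic exactly: the genomic fraction is rounded to one
decimal of a percent and the two intensities to three decimals before
dividing (2.309/1.755 = 1.316 at p_P = 10%; 2.023/1.400 = 1.445 at 20%);
the half-up mean of those two ratios, 1.381, is available as the fixed
compromise multiplier. Accuracies r_Ac = r_ab/H beyond 1 are clamped and
flagged. The efficiency ratio is independent of s_A, and doubling t_P
doubles it exactly — a structural identity asserted in the tests.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale panels — 306 lines, 7 × 60
markers before QC (≈ 210 after), 5-fold single-repetition CV, shortened
Gibbs chains — chosen so the whole chain, including 50-seed recovery
studies, runs in a few minutes on one CPU; all sizes scale up through
configuration. Seeds fan out from a single master seed via
`numpy.random.SeedSequence`, so every table is bit-reproducible. Ridge
and REML searches are bounded in [1e−5, 1e5] with boundary warnings;
singular GLS covariances receive a 1e−8 ridge jitter with a warning;
negative variance estimates truncate to zero with a flag; k-NN imputation
ties resolve toward the marker mode and are logged.

## Known limitations

- The nested (with-population) EMS analysis is approximate for unequal
  population sizes; exact treatment would require REML on the full model.
- The delta-method standard error for the between-trait genetic
  correlation is first-order only.
- The Gibbs samplers are single-site and make no attempt at convergence
  diagnostics beyond posterior-mean stability; very short chains on very
  sparse architectures can under-shrink.
- Inter-population predictive ability depends strongly on realized parent
  divergence and marker sharing; the generator's defaults produce the
  qualitative intra-vs-inter contrast, not any particular numeric value.
- The GWAS explained-variance column is per-marker and not additive
  across linked markers.
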