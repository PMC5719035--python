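# Methods

## The model

The package studies how the *shape* of a genotype–phenotype (G–P) map turns
homogeneous variation in a developmental input into heterogeneous phenotypic
variation — the developmental-nonlinearity account of canalization. The
developmental input is relative *Fgf8* expression ε (wild type = 1); the
phenotype is a one-dimensional craniofacial shape score z. The G–P map is a
saturating (von Bertalanffy) curve

    f(ε) = L_m − (L_m − L_0) e^(−kε)

with asymptote `L_m`, zero-expression intercept `L_0`, and rate constant `k`.
Two reference parameterizations are shipped: the embryonic E10.5 curve
(L_m = 0.01765, L_0 = −0.12787, k = 5.3003) and the neonatal P0 curve
(L_m = 0.0288, L_0 = −1.333, k = 13.049), both in regression-score units.

Within a genotype, developmental values are modeled as a normal distribution
truncated at zero (expression cannot be negative), with mean ε̄ and SD σ_ε.
Propagation to the phenotype follows the standard nonlinear-G–P-map
machinery:

- mean phenotype z̄ = ∫ f(ε) p(ε) dε,
- mean sensitivity Φ = ∫ f′(ε) p(ε) dε,
- first-order phenotypic variance σ_z² = Φ² σ_ε²,
- exact propagated variance Var[f(ε)] = E[f²] − z̄².

All four have closed forms through the truncated-normal exponential moment
M(t) = E[e^{tε}] = e^{μt+σ²t²/2} Φ_N(μ/σ + σt)/Φ_N(μ/σ), evaluated in log
space (`scipy.special.log_ndtr`) so deep tails (t = −2k ≈ −26) do not
underflow. Adaptive quadrature of the same integrals runs alongside as an
internal cross-check; any disagreement beyond 1e−8 raises instead of
returning silently. σ_ε² in the first-order formula is the variance of the
*truncated* distribution, so the first-order and exact routes coincide
exactly for linear maps (this is tested; a `LinearMap` class participates in
the same API). The curve is never evaluated at negative ε.

Because f is concave increasing over the relevant range, predicted variance
at fixed σ_ε is strictly decreasing in ε̄: genotypes above roughly 40% of
wild-type expression are buffered, genotypes below are not. The
`threshold_expression` helper makes that operational as the point where the
slope falls to a chosen fraction of f′(0): ε* = ln(1/fraction)/k, ≈ 0.43 for
the E10.5 curve at fraction 0.1.

## Curve fitting

`fit_vb` minimizes Σ(zᵢ − f(εᵢ))² with trust-region least squares and an
analytic Jacobian. The objective is multimodal in k for noisy data, so four
starts are tried (L_m = max z, L_0 = min z, k ∈ {0.5, 1, 5, 50}) and the
best residual sum of squares wins. Fits with k on the box boundary
(1e−8, 1e4) are flagged unconverged rather than returned silently — a
linear dataset lands there by construction.

## Geometric morphometrics

Generalized Procrustes analysis translates each K×3 configuration to the
origin, scales to unit centroid size, and iteratively rotates (proper
rotations only; reflections excluded) to the evolving consensus until the
consensus moves < 1e−10 (cap 100 iterations). The output frame is then
canonicalized: the consensus is rotated onto its principal axes with signs
anchored on the *left* singular vectors (landmark loadings), which makes the
aligned coordinates invariant — to machine precision — under arbitrary
rotation/translation/scaling of the inputs. Tangent-space projection is
omitted: all analyses operate near the consensus where the sphere and the
tangent plane agree to second order.

Downstream statistics operate on the flat n×3K matrix:

- **Shape PCA** with a deterministic sign convention (largest-magnitude
  loading positive).
- **Covariate standardization** regresses each coordinate on stage
  (embryos) or centroid size (neonates) and keeps residuals + grand mean.
  The pipeline estimates the slope from pooled *within-genotype* covariance
  (equivalent to including genotype in the model). A pooled regression is
  also available, but when the true allometry is small relative to the
  genotype signal, a chance correlation between the covariate and genotype
  leaks between-group signal into the within-group residuals and inflates
  disparity estimates severalfold; the within-group estimator removes this.
- **Lab-offset removal** subtracts, per non-reference lab, the difference
  between that lab's and the reference lab's wild-type mean shapes. The
  generator therefore places wild-type individuals in every lab.
- **Shape regression** on expression returns the coefficient vector, an R²
  over the total Procrustes sum of squares, and regression scores — the
  projections of centered shapes onto the unit coefficient vector (the CAC
  score in pooled analyses). These scores are the z fed to the curve fit.
- **Morphological disparity** (Procrustes variance): mean squared deviation
  from the group mean, divisor n by default (the population convention;
  n−1 available via `ddof=1`).

### Disparity permutation test

The pairwise statistic is |PV_a − PV_b|. Naively permuting centered residual
vectors is anticonservative at study-like sizes (measured type-I error
5.9–7.2% at α = 0.05 for n = 10/group): centered residuals sum to zero
within a group, so mixed permuted groups look spuriously tight. Instead,
each group's n centered rows are Helmert-rotated into n−1 rows whose squared
norms are uncorrelated and average exactly to SS/(n−1); the null permutes
these scalars across groups. Measured levels are 4.4–5.7% across (p, n)
grids with full power at a 4× variance ratio, n = 20. Raw-label permutation
(exact when group means are equal) remains available. Mean-shape differences
use the Euclidean distance between group means in the common aligned frame,
with raw-label permutation. All P values use the add-one convention
(1 + #{null ≥ obs})/(n_perm + 1) and are never exactly zero.

`variance_power_simulation` estimates rejection rates for two groups with a
variance ratio, by default drawing isotropic Gaussians in 23 dimensions
(the effective dimensionality of 10 aligned 3D landmarks, 3K − 7); a series
template can be passed to run the full landmark-generation + GPA route.
Under these conditions, detecting a 15–30% variance increase with n = 10
per group has power well below 0.8 — variance differences of that size are
genuinely hard to see with disparity statistics at such n.

## Expression statistics

ΔΔCt quantification averages replicate Ct per (sample, gene), forms
ΔCt = Ct(target) − Ct(reference), subtracts the wild-type group mean ΔCt
(on the cycle scale, *before* exponentiation), and reports 2^(−ΔΔCt); by
Jensen's inequality the wild-type group mean of the reported values sits
slightly above 1. Levene's test (mean-centered) and one-way ANOVA are thin
wrappers over scipy with df reported in (within, between) order.

Counts are normalized by median-of-ratios size factors (median over
all-nonzero genes of count / gene geometric mean), anchored at geometric
mean 1; note that with this anchor, rescaling one sample by c moves factor
*ratios* by c while all factors absorb c^(1/n). Correlations and
concordance work on log2(normalized + 1).

The resampling statistics: fold-change profiles report per-genotype mean
|fold change| vs wild type over a gene set with delta-method SEs;
nearest-neighbor differences are tested by bootstrap over the pooled pair's
samples (add-one, two-sided). Within-genotype concordance computes
Fisher-z-transformed Pearson correlations between all pairs of individuals
across a gene set (z capped at atanh(1 − 1e−12)), compared to wild type by
bootstrap over individuals (duplicate draws are collapsed before forming
pairs, since a self-pair is identically r = 1). Gene-set–signal correlation
compares a set's mean per-gene Pearson correlation with the expression level
against the same statistic on random same-size gene sets drawn genome-wide
(two-sided 95% flag plus an add-one P).

## SNP summaries

Allele frequencies are mean dosage / 2 over non-missing calls
(pairwise-complete). Additive genetic variance uses the Σ 2p(1−p) proxy
with unit allelic effects — comparable across groups, no absolute scale.
The inbreeding coefficient is 1 − H_obs/H_exp averaged over polymorphic
loci.

## The synthetic allelic series

The generator is the package's study system. Defaults:

| parameter | value | why |
|---|---|---|
| genotypes | 9, means (1.00, 1.10, 0.85, 0.72, 0.62, 0.55, 0.30, 0.22, 0.14) | spans 0.14–1.1 of wild type; heterozygote-like genotypes cluster in the buffered regime and severe hypomorphs below 0.3, leaving the threshold region unpopulated as in the real series |
| group sizes | 27, 15, 30, 13, 16, 16, 19, 12, 8 | the embryonic design |
| σ_ε | 0.12, common | variance homogeneity across genotypes is part of the design; calibrated so Levene's test at these group sizes is typically non-significant (median P ≈ 0.43) |
| curve | E10.5 reference | ground truth for landmarks |
| K | 10 landmarks, unit centroid size | deterministic helical template with no rotational symmetry |
| landmark noise | SD 0.0015/coordinate | ≈0.5% of inter-landmark spacing — digitization-scale error giving a disparity floor of ≈(3K−7)·σ² ≈ 5e−5 |
| labs | 2, offset 0.004 along a direction orthogonal to the signal | makes offset removal non-trivial; wild types are split across labs |
| nuisance transforms | uniform random rotations, log-uniform scale in [0.5, 2], Gaussian translations | exercises superimposition; no reflections |

The shape-change direction and the allometry/lab-offset vectors are
deterministic unit vectors orthogonalized against the template's
similarity-transform subspace (translations, infinitesimal rotations,
scaling), so superimposition neither absorbs nor distorts them to first
order. Counts are negative binomial (Var = μ + αμ²) with log-normal library
factors (~2-fold spread); gene classes are saturating-responsive, linear,
compensatory-negative, and unresponsive. qPCR tables carry a shared
per-sample loading shift on both genes so reference normalization is
exercised. SNP panels are near-isogenic lines with a configurable
within-line segregating fraction.

What the generator does *not* emulate: landmark covariance structure beyond
isotropic noise (real shapes have correlated, anisotropic variation),
spatially structured allometry, RNA-seq compositional artifacts beyond
library scaling, measurement error in expression when used as a regressor,
and linkage in SNP panels. Passing tests therefore certify the estimators
and their calibration under the stated model, not the biology of any real
dataset.

## Numerical choices and degenerate inputs

Quadrature: `scipy.integrate.quad` with epsabs/epsrel 1e−12 on
[0, ε̄ + 10σ]. GPA rejects configurations with coincident or collinear
landmarks by specimen name. Groups of size 1 get NaN disparity and are
flagged. Constant covariates, missing reference genes, labs without wild
types, and all-zero genes fail loudly with the offending record named.
Permutation and bootstrap routines accept either an integer seed or a
Generator and are bit-reproducible for fixed seeds; the pipeline writes
byte-identical CSVs on reruns.

## Scale of the shipped experiments

The analysis drivers and tests run the full 156-specimen series, 300-gene ×
18-sample count matrices, a 2000-locus SNP panel, 500-replicate null
calibrations, and 20-replicate parameter-recovery experiments; these sizes
give binomial/Monte-Carlo error small enough for the assertions made while
keeping each driver in seconds to a couple of minutes.

## Known limitations

- The regression score compresses the phenotype by ~f²/2 through unit-size
  scaling, so even noise-free pipelines recover k to ~0.5%, not machine
  precision.
- A group's realized variance differs from the distribution-level
  prediction by the sampling error of a variance, which is large for the
  strongly skewed f(ε) at n ≈ 8–30; predicted-vs-observed comparisons
  across genotypes are therefore made in ranks.
- The truncated-normal device assumes the biological floor is exactly at
  zero expression and that σ_ε is measured without error.
- With expression means near the threshold, a genotype's variance becomes
  dominated by its ε-distribution's lower tail; conclusions there are
  sensitive to the normality assumption.
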