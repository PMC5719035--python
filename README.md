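# gpmap — nonlinear genotype–phenotype maps and phenotypic robustness

Why are some genotypes phenotypically noisier than others, even when the
underlying variation they carry is the same? One mechanistic answer is the
*shape* of the genotype–phenotype (G–P) map: if a developmental input
relates to the phenotype through a saturating curve, genotypes sitting on
the flat part are buffered (canalized) while genotypes on the steep part
amplify the same input variance into large phenotypic variance.

This package implements that analysis end to end for an allelic series —
a graded set of genotypes spanning ~14–110% of wild-type *Fgf8* expression
with 3D craniofacial landmark phenotypes — and ships a synthetic-data
generator with known ground truth so every stage is testable without any
external download. It is aimed at quantitative/evo-devo biologists and
biostatisticians working with landmark-based morphometrics and expression
data.

## The model

The G–P curve is von Bertalanffy,

    z = L_m − (L_m − L_0) e^(−kε),

where ε is relative expression (wild type = 1), z a one-dimensional shape
score, `L_m` the asymptotic phenotype, `L_0` the phenotype at zero
expression, and `k` the rate constant. Within-genotype developmental values
follow a normal distribution truncated at zero, p(ε). Variance propagates
through the map as

    z̄ = ∫ f(ε) p(ε) dε,   Φ = ∫ f′(ε) p(ε) dε,   σ_z² = Φ² σ_ε²,

with the exact propagated variance Var[f(ε)] computed alongside the
first-order form. Everything has closed forms via the truncated-normal
exponential moment M(t) = E[e^{tε}]; quadrature cross-checks run inside
every call. Around the curve sit the supporting analyses: generalized
Procrustes superimposition, shape regression (CAC/regression scores),
morphological disparity with calibrated permutation tests, ΔΔCt
quantification, median-of-ratios count normalization, fold-change /
concordance / gene-set resampling statistics, and SNP-based additive
genetic variance. See `docs/methods.md` for the full account.

## Worked example

Simulate the default nine-genotype series, run the whole pipeline, and
compare predicted with observed shape variance:

```python
from gpmap import PipelineConfig, default_series, run_pipeline

report = run_pipeline(
    PipelineConfig(seed=1, series=default_series(), n_permutations=999)
)
p = report.curve_fit.params
print(f"fitted curve: L_m={p.L_m:.5f} L_0={p.L_0:.5f} k={p.k:.3f}")
print(f"threshold: {report.threshold:.2%} of wild-type expression")
print(f"predicted vs observed variance, Spearman rho = "
      f"{report.predicted_observed_spearman:.3f}")
```

prints

```
fitted curve: L_m=0.01313 L_0=-0.13249 k=5.261
threshold: 43.77% of wild type
predicted vs observed variance, Spearman rho = 0.917
```

The fitted curve is close to the generating E10.5 reference curve
(L_m = 0.01765, L_0 = −0.12787, k = 5.3003); the threshold — the expression
level where the curve's slope has decayed to 10% of its maximum — lands
near 40% of wild type; and the propagated per-genotype variance tracks the
observed morphological disparity in rank (ρ = 0.92). The report's
per-genotype table shows the robustness structure directly: disparity is
flat (≈5e−5, the landmark-noise floor) for every genotype above 40%
expression and rises more than tenfold below it.

The numbered drivers under `analysis/` run the same study as separate
steps — `01_simulate_series.py` writes the synthetic datasets,
`02_morphometrics.py` superimposes and tests disparity,
`03_fit_gp_curve.py` fits the curve and maps the variance response
surface, `04_expression_stats.py` runs the qPCR and transcriptome
statistics, `05_strain_genetics.py` the SNP summaries, and
`06_robustness_report.py` the end-to-end comparison — each writing tables
under `results/`.

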