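"""Synthetic allelic-series data with known ground truth.

Emulates the study design of an Fgf8 dosage series: nine genotypes whose
mean relative expression spans roughly 0.14–1.1 of wild type with a
common within-genotype SD, craniofacial shape varying along a single
direction in landmark space as a saturating function of expression, qPCR
Ct tables that recover expression through the ΔΔCt pipeline, RNA-seq
style count matrices with responsive and unresponsive genes, and
near-isogenic SNP panels.  Every generated dataset carries its ground
truth so downstream estimates can be checked against the generating
values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gp_map import E105_CURVE, VonBertalanffyParams, vb_eval
from .morphometrics import LandmarkConfiguration

__all__ = [
    "GenotypeSpec",
    "SeriesConfig",
    "GeneModel",
    "default_series",
    "default_template",
    "default_direction",
    "default_gene_models",
    "sample_expression",
    "sample_landmarks",
    "sample_counts",
    "sample_qpcr",
    "sample_snp_panel",
]


@dataclass(frozen=True)
class GenotypeSpec:
    """One genotype of the allelic series."""

    name: str
    mean_expression: float   # relative to wild type (WT = 1)
    expression_sd: float
    n_individuals: int
    lab: str = "lab1"
    is_wild_type: bool = False

    def __post_init__(self) -> None:
        if self.mean_expression < 0:
            raise ValueError(f"{self.name}: mean_expression must be >= 0")
        if self.expression_sd <= 0:
            raise ValueError(f"{self.name}: expression_sd must be > 0")
        if self.n_individuals < 1:
            raise ValueError(f"{self.name}: need at least one individual")


@dataclass
class SeriesConfig:
    """Full generative description of one synthetic allelic series."""

    genotypes: list[GenotypeSpec]
    curve: VonBertalanffyParams
    landmark_template: np.ndarray          # K×3, centroid size 1
    shape_direction: np.ndarray            # unit vector, length 3K
    landmark_noise_sd: float
    lab_offset: np.ndarray | None = None   # 3K, applied to non-reference labs
    stage_allometry: np.ndarray | None = None  # 3K per unit stage
    seed: int = 0

    def __post_init__(self) -> None:
        self.landmark_template = np.asarray(self.landmark_template, dtype=float)
        self.shape_direction = np.asarray(self.shape_direction, dtype=float)
        k = self.landmark_template.shape[0]
        if k < 4:
            raise ValueError("need at least 4 landmarks")
        if self.shape_direction.shape != (3 * k,):
            raise ValueError("shape_direction must have length 3K")
        if abs(np.linalg.norm(self.shape_direction) - 1.0) > 1e-8:
            raise ValueError("shape_direction must have unit norm")
        if self.landmark_noise_sd <= 0:
            raise ValueError("landmark_noise_sd must be > 0")
        names = [g.name for g in self.genotypes]
        if len(names) != len(set(names)):
            raise ValueError("duplicate genotype names")


@dataclass(frozen=True)
class GeneModel:
    """Expression response of one gene to the perturbed signal.

    ``response_class`` picks the qualitative behaviour:

    - ``downstream_nonlinear``: mean multiplier follows a saturating
      curve of ε normalized to 1 at wild type;
    - ``downstream_linear``: multiplier linear in ε;
    - ``compensatory_negative``: multiplier increases as ε decreases;
    - ``unresponsive``: multiplier 1 everywhere.
    """

    gene_id: str
    response_class: str = "unresponsive"
    baseline_mean: float = 100.0
    response_curve: dict = field(default_factory=dict)
    dispersion: float = 0.1   # negative-binomial dispersion (Var = μ + α μ²)

    def __post_init__(self) -> None:
        if self.baseline_mean <= 0:
            raise ValueError(f"{self.gene_id}: baseline_mean must be > 0")
        if self.dispersion <= 0:
            raise ValueError(f"{self.gene_id}: dispersion must be > 0")
        if self.response_class not in {
            "downstream_nonlinear",
            "downstream_linear",
            "compensatory_negative",
            "unresponsive",
        }:
            raise ValueError(f"unknown response_class {self.response_class!r}")

    def multiplier(self, eps) -> np.ndarray:
        """Mean count multiplier as a function of expression ε (WT = 1)."""
        eps = np.asarray(eps, dtype=float)
        p = self.response_curve
        if self.response_class == "unresponsive":
            return np.ones_like(eps)
        if self.response_class == "downstream_nonlinear":
            curve = VonBertalanffyParams(
                p.get("L_m", 1.05), p.get("L_0", 0.05), p.get("k", 5.3)
            )
            return np.maximum(vb_eval(curve, eps) / vb_eval(curve, 1.0), 1e-6)
        if self.response_class == "downstream_linear":
            floor = p.get("floor", 0.1)
            return floor + (1.0 - floor) * eps
        # compensatory_negative
        slope = p.get("slope", 0.5)
        return np.maximum(1.0 + slope * (1.0 - eps), 1e-6)


# ---------------------------------------------------------------------------
# defaults mirroring the E10.5 study design


#: per-genotype sample sizes of the embryonic dataset, wild type first
_E105_N = (27, 15, 30, 13, 16, 16, 19, 12, 8)
#: genotype labels of the two combined allelic series
_GENOTYPE_NAMES = (
    "WT", "Flox/+", "Neo/+", "Flox/-", "+/-",
    "Flox/+;Crect", "Flox/-;Crect", "Neo/Neo", "Neo/-",
)
#: mean relative expression per genotype spanning 0.14–1.1 of wild type;
#: heterozygote-like genotypes cluster in the buffered regime (>0.45) and
#: severe hypomorphs sit below 0.3, leaving the threshold region sparse
_MEAN_EXPRESSION = (1.00, 1.10, 0.85, 0.72, 0.62, 0.55, 0.30, 0.22, 0.14)
#: common within-genotype expression SD (homogeneous across the series)
DEFAULT_EXPRESSION_SD = 0.12
#: digitization / biological landmark noise per coordinate (Procrustes units)
DEFAULT_LANDMARK_NOISE_SD = 0.0015


def default_template(k: int = 10) -> np.ndarray:
    """Deterministic K×3 mean shape with unit centroid size.

    Points on two interleaved helical arcs — irregular enough that the
    configuration has no rotational symmetry.
    """
    t = np.linspace(0.0, 1.5 * np.pi, k)
    pts = np.column_stack(
        [
            np.cos(t) * (1.0 + 0.15 * t / np.pi),
            np.sin(t) * (1.0 - 0.1 * t / np.pi),
            0.35 * t / np.pi + 0.2 * np.cos(2.3 * t),
        ]
    )
    pts -= pts.mean(axis=0)
    pts /= np.sqrt(np.sum(pts * pts))
    return pts


def _similarity_basis(template: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the similarity-transform subspace at a template.

    Spans translations (3), infinitesimal rotations (3) and scaling (1)
    — the directions removed by Procrustes superimposition.
    """
    k = template.shape[0]
    cols = []
    for ax in range(3):
        v = np.zeros((k, 3))
        v[:, ax] = 1.0
        cols.append(v.reshape(-1))
    gens = [
        np.array([[0, -1, 0], [1, 0, 0], [0, 0, 0]], float),
        np.array([[0, 0, 1], [0, 0, 0], [-1, 0, 0]], float),
        np.array([[0, 0, 0], [0, 0, -1], [0, 1, 0]], float),
    ]
    for g in gens:
        cols.append((template @ g.T).reshape(-1))
    cols.append(template.reshape(-1))
    q, _ = np.linalg.qr(np.column_stack(cols))
    return q


def default_direction(template: np.ndarray) -> np.ndarray:
    """Deterministic unit shape-change direction orthogonal to similarity
    transforms of the template (so superimposition does not absorb it)."""
    k = template.shape[0]
    raw = np.sin(1.0 + 2.0 * np.arange(3 * k))  # fixed, aperiodic
    q = _similarity_basis(template)
    v = raw - q @ (q.T @ raw)
    return v / np.linalg.norm(v)


def default_series(
    expression_sd: float = DEFAULT_EXPRESSION_SD,
    landmark_noise_sd: float = DEFAULT_LANDMARK_NOISE_SD,
    curve: VonBertalanffyParams = E105_CURVE,
    k_landmarks: int = 10,
    seed: int = 0,
    n_scale: float = 1.0,
) -> SeriesConfig:
    """The default nine-genotype series mirroring the E10.5 design.

    Genotype means span 0.14–1.1 of wild type with a common SD, group
    sizes follow the embryonic dataset, two labs contribute specimens
    and non-reference-lab shapes carry a small constant offset.
    ``n_scale`` scales all group sizes (minimum 2 per group).
    """
    labs = ("lab1", "lab1", "lab2", "lab2", "lab2", "lab1", "lab1", "lab2", "lab2")
    genotypes = [
        GenotypeSpec(
            name=nm,
            mean_expression=mu,
            expression_sd=expression_sd,
            n_individuals=max(2, int(round(n * n_scale))),
            lab=lab,
            is_wild_type=(nm == "WT"),
        )
        for nm, mu, n, lab in zip(_GENOTYPE_NAMES, _MEAN_EXPRESSION, _E105_N, labs)
    ]
    template = default_template(k_landmarks)
    direction = default_direction(template)
    q = _similarity_basis(template)

    def orthogonalize(raw):
        v = raw - q @ (q.T @ raw)
        v -= direction * (direction @ v)
        return v / np.linalg.norm(v)

    lab_offset = 0.004 * orthogonalize(np.cos(0.7 + 1.3 * np.arange(3 * k_landmarks)))
    stage_allometry = 0.002 * orthogonalize(
        np.sin(0.3 + 0.9 * np.arange(3 * k_landmarks)) ** 2 - 0.5
    )
    return SeriesConfig(
        genotypes=genotypes,
        curve=curve,
        landmark_template=template,
        shape_direction=direction,
        landmark_noise_sd=landmark_noise_sd,
        lab_offset=lab_offset,
        stage_allometry=stage_allometry,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# samplers


def sample_expression(spec: GenotypeSpec, seed: int | np.random.Generator) -> np.ndarray:
    """Per-individual expression: normal(μ, σ²) truncated below at 0."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    a = (0.0 - spec.mean_expression) / spec.expression_sd
    return stats.truncnorm.rvs(
        a, np.inf,
        loc=spec.mean_expression,
        scale=spec.expression_sd,
        size=spec.n_individuals,
        random_state=rng,
    )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (reflections excluded)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1.0
    return q


def sample_landmarks(config: SeriesConfig) -> tuple[list[LandmarkConfiguration], pd.DataFrame]:
    """Generate one landmark dataset for the whole series.

    Each specimen's shape is::

        template + direction·f(ε_i) + allometry·stage_i + lab offset
                 + iid N(0, noise²) per coordinate

    followed by an arbitrary rigid rotation, translation, and positive
    scale (log-uniform in [0.5, 2]).  Returns the configurations plus a
    ground-truth table (true expression, stage, lab, genotype).
    """
    rng = np.random.default_rng(config.seed)
    k = config.landmark_template.shape[0]
    direction = config.shape_direction.reshape(k, 3)
    labs_present = sorted({g.lab for g in config.genotypes})
    ref_lab = labs_present[0]
    configs: list[LandmarkConfiguration] = []
    truth_rows = []
    for g in config.genotypes:
        eps = sample_expression(g, rng)
        f_val = vb_eval(config.curve, eps)
        if not np.all(np.isfinite(np.atleast_1d(f_val))):
            raise FloatingPointError(f"curve evaluation non-finite for {g.name}")
        stages = rng.integers(8, 15, size=g.n_individuals).astype(float)
        for i in range(g.n_individuals):
            # each site contributes its own controls: wild-type individuals
            # are spread round-robin over all labs so offsets are anchorable
            lab_i = (
                labs_present[i % len(labs_present)] if g.is_wild_type else g.lab
            )
            shape = config.landmark_template + direction * np.atleast_1d(f_val)[i]
            if config.stage_allometry is not None:
                shape = shape + config.stage_allometry.reshape(k, 3) * (stages[i] - 11.0)
            if config.lab_offset is not None and lab_i != ref_lab:
                shape = shape + config.lab_offset.reshape(k, 3)
            shape = shape + rng.normal(0.0, config.landmark_noise_sd, size=(k, 3))
            # nuisance similarity transform, removed again by superimposition
            rot = _random_rotation(rng)
            scale = np.exp(rng.uniform(np.log(0.5), np.log(2.0)))
            shift = rng.normal(0.0, 1.0, size=3)
            coords = scale * (shape @ rot.T) + shift
            sid = f"{g.name}_{i:03d}"
            configs.append(
                LandmarkConfiguration(
                    specimen_id=sid,
                    coords=coords,
                    genotype=g.name,
                    lab=lab_i,
                    stage=stages[i],
                    size_covariate=None,
                )
            )
            truth_rows.append(
                {
                    "specimen_id": sid,
                    "genotype": g.name,
                    "lab": lab_i,
                    "stage": stages[i],
                    "true_expression": float(np.atleast_1d(eps)[i]),
                    "true_phenotype": float(np.atleast_1d(f_val)[i]),
                    "nuisance_scale": scale,
                }
            )
    return configs, pd.DataFrame(truth_rows)


def sample_counts(
    config: SeriesConfig,
    genes: Sequence[GeneModel],
    seed: int | np.random.Generator,
    n_per_genotype: int | None = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """RNA-seq style count matrix (genes × samples) for the series.

    Counts are negative binomial with mean
    baseline · multiplier(ε_i) · library_factor_i; library factors are
    log-normal with ~2-fold spread.  ``n_per_genotype`` caps individuals
    per genotype (RNA-seq designs are smaller than morphometric ones);
    None uses every individual.  Returns (counts, sample metadata with
    true expression and library factors).
    """
    if len(config.genotypes) < 2:
        raise ValueError("need at least 2 genotypes")
    if len(genes) < 1:
        raise ValueError("need at least 1 gene")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    samples, eps_all, libf_all, geno_all = [], [], [], []
    for g in config.genotypes:
        n = g.n_individuals if n_per_genotype is None else min(n_per_genotype, g.n_individuals)
        eps = sample_expression(
            GenotypeSpec(g.name, g.mean_expression, g.expression_sd, n, g.lab), rng
        )
        for i in range(n):
            samples.append(f"{g.name}_s{i}")
            eps_all.append(float(np.atleast_1d(eps)[i]))
            libf_all.append(float(np.exp(rng.normal(0.0, 0.25))))
            geno_all.append(g.name)
    eps_arr = np.array(eps_all)
    lib_arr = np.array(libf_all)
    mat = np.empty((len(genes), len(samples)), dtype=int)
    for gi, gene in enumerate(genes):
        mu = gene.baseline_mean * gene.multiplier(eps_arr) * lib_arr
        if gene.dispersion < 1e-8:
            mat[gi] = rng.poisson(mu)
        else:
            # NB with Var = μ + α μ²  →  n = 1/α, p = n/(n+μ)
            n_nb = 1.0 / gene.dispersion
            mat[gi] = rng.negative_binomial(n_nb, n_nb / (n_nb + mu))
    counts = pd.DataFrame(mat, index=[g.gene_id for g in genes], columns=samples)
    meta = pd.DataFrame(
        {
            "sample_id": samples,
            "genotype": geno_all,
            "true_expression": eps_all,
            "library_factor": libf_all,
        }
    )
    return counts, meta


def default_gene_models(
    n_unresponsive: int = 240,
    n_nonlinear: int = 30,
    n_linear: int = 20,
    n_compensatory: int = 10,
    seed: int = 12345,
) -> list[GeneModel]:
    """A default gene panel: mostly unresponsive genes plus nonlinear and
    linear downstream responders and a few negatively-responding genes."""
    rng = np.random.default_rng(seed)
    models = []

    def base():
        return float(np.exp(rng.uniform(np.log(30), np.log(3000))))

    for i in range(n_nonlinear):
        models.append(GeneModel(f"ds_nl_{i:03d}", "downstream_nonlinear", base()))
    for i in range(n_linear):
        models.append(GeneModel(f"ds_lin_{i:03d}", "downstream_linear", base()))
    for i in range(n_compensatory):
        models.append(GeneModel(f"comp_{i:03d}", "compensatory_negative", base()))
    for i in range(n_unresponsive):
        models.append(GeneModel(f"bg_{i:04d}", "unresponsive", base()))
    return models


def sample_qpcr(
    config: SeriesConfig,
    seed: int | np.random.Generator,
    technical_sd: float = 0.1,
    reference_mean_ct: float = 18.0,
    target_offset: float = 6.0,
    n_replicates: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ct table (triplicate target + reference wells per sample).

    Reference-gene Ct is normal around a fixed mean; target Ct is the
    reference mean plus an offset minus log2(ε_i), so the ΔΔCt pipeline
    recovers ε up to technical noise.  Returns (Ct table, truth table).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rows, truth = [], []
    for g in config.genotypes:
        eps = sample_expression(g, rng)
        for i in range(g.n_individuals):
            e = float(np.atleast_1d(eps)[i])
            sid = f"{g.name}_q{i:03d}"
            base_ref = reference_mean_ct + rng.normal(0.0, 0.3)
            target_true = reference_mean_ct + target_offset - np.log2(max(e, 1e-9))
            # sample-to-sample loading shifts both genes equally
            loading = base_ref - reference_mean_ct
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "sample_id": sid,
                        "genotype": g.name,
                        "gene": "reference",
                        "replicate": rep,
                        "ct": base_ref + rng.normal(0.0, technical_sd),
                    }
                )
                rows.append(
                    {
                        "sample_id": sid,
                        "genotype": g.name,
                        "gene": "target",
                        "replicate": rep,
                        "ct": target_true + loading + rng.normal(0.0, technical_sd),
                    }
                )
            truth.append({"sample_id": sid, "genotype": g.name, "true_expression": e})
    return pd.DataFrame(rows), pd.DataFrame(truth)


def sample_snp_panel(
    n_lines: int,
    n_loci: int,
    within_line_het: float,
    seed: int | np.random.Generator,
    n_per_line: int = 5,
) -> tuple[pd.DataFrame, pd.Series]:
    """Near-isogenic SNP panel: loci × samples dosage matrix (0/1/2).

    Within each line, a fraction ``within_line_het`` of loci segregates
    (Hardy–Weinberg at frequency 0.5); the rest are fixed at the line's
    founder allele.  Returns (matrix, line label per sample column).
    """
    if n_lines < 1 or n_loci < 1:
        raise ValueError("need at least one line and one locus")
    if not 0 <= within_line_het <= 1:
        raise ValueError("within_line_het must be in [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cols, labels = [], []
    mat = np.empty((n_loci, n_lines * n_per_line), dtype=int)
    for li in range(n_lines):
        fixed = rng.choice([0, 2], size=n_loci)
        seg = rng.random(n_loci) < within_line_het
        for si in range(n_per_line):
            dos = fixed.copy()
            dos[seg] = rng.binomial(2, 0.5, size=int(seg.sum()))
            col = li * n_per_line + si
            mat[:, col] = dos
            cols.append(f"line{li}_s{si}")
            labels.append(f"line{li}")
    df = pd.DataFrame(mat, index=[f"snp{j:06d}" for j in range(n_loci)], columns=cols)
    return df, pd.Series(labels, index=cols, name="line")
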