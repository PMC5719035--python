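"""Landmark-based shape statistics.

Generalized Procrustes superimposition (translation, unit-centroid-size
scaling, rotation-only fitting), covariate standardization, batch (lab)
offset removal, shape PCA, multivariate shape regression with regression
scores, Procrustes variance (morphological disparity), permutation tests
on disparity and mean shape, and a power simulation for variance
differences.

Shapes are handled in two forms: as ``LandmarkConfiguration`` objects
(one specimen, K×3 coordinates plus covariates) before superimposition,
and as flat n×3K matrices afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import helmert as sp_helmert

__all__ = [
    "LandmarkConfiguration",
    "AlignedShapeSet",
    "ShapeRegressionResult",
    "generalized_procrustes",
    "shape_pca",
    "standardize_shapes",
    "remove_lab_offset",
    "shape_regression",
    "procrustes_variance",
    "disparity_permutation_test",
    "mean_shape_permutation_test",
    "variance_power_simulation",
    "procrustes_distance",
]


@dataclass
class LandmarkConfiguration:
    """One specimen's raw landmarks plus its covariates."""

    specimen_id: str
    coords: np.ndarray  # K×3
    genotype: str = ""
    lab: str = ""
    stage: float | None = None          # e.g. tail-somite count for embryos
    size_covariate: float | None = None  # e.g. centroid size for neonates

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"{self.specimen_id}: coords must be K×3")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"{self.specimen_id}: non-finite landmark coordinates")

    @property
    def centroid_size(self) -> float:
        c = self.coords - self.coords.mean(axis=0)
        return float(np.sqrt(np.sum(c * c)))


@dataclass
class AlignedShapeSet:
    """Procrustes-superimposed shapes: n×3K matrix + sizes + consensus."""

    shapes: np.ndarray           # n × 3K
    centroid_sizes: np.ndarray   # n
    consensus: np.ndarray        # 3K
    metadata: pd.DataFrame       # one row per specimen

    @property
    def n(self) -> int:
        return self.shapes.shape[0]

    @property
    def k(self) -> int:
        return self.shapes.shape[1] // 3

    def with_shapes(self, shapes: np.ndarray) -> "AlignedShapeSet":
        out = replace(self, shapes=np.asarray(shapes, dtype=float))
        out.consensus = out.shapes.mean(axis=0)
        return out


@dataclass
class ShapeRegressionResult:
    """Multivariate regression of shape on one covariate."""

    coefficients: np.ndarray     # 3K slope vector
    intercept: np.ndarray        # 3K
    r_squared: float
    regression_scores: np.ndarray  # n; projections onto unit coefficient vector
    residual_shapes: np.ndarray    # n × 3K (fitted mean added back)


def _optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation (det = +1, reflections excluded) minimizing ‖source·R − target‖."""
    u, _, vt = np.linalg.svd(source.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    u[:, -1] *= d
    return u @ vt


def _canonical_rotation(consensus: np.ndarray) -> np.ndarray:
    """Rotation sending a K×3 consensus to a deterministic orientation.

    Signs are anchored on the left singular vectors (landmark loadings),
    which do not change when the input frame is rotated, so the output
    orientation depends only on the consensus *shape*.
    """
    u, _, vt = np.linalg.svd(consensus, full_matrices=False)
    r = vt.T
    for j in range(2):
        if u[np.argmax(np.abs(u[:, j])), j] < 0:
            r[:, j] *= -1.0
    r[:, 2] = np.cross(r[:, 0], r[:, 1])  # right-handed, det = +1
    return r


def _center_scale(coords: np.ndarray, specimen: str) -> tuple[np.ndarray, float]:
    c = coords - coords.mean(axis=0)
    size = np.sqrt(np.sum(c * c))
    if size < 1e-12:
        raise ValueError(f"degenerate configuration (coincident landmarks): {specimen}")
    c /= size
    if np.linalg.matrix_rank(c, tol=1e-10) < 2:
        raise ValueError(f"degenerate configuration (collinear landmarks): {specimen}")
    return c, float(size)


def generalized_procrustes(
    configs: Sequence[LandmarkConfiguration],
    tol: float = 1e-10,
    max_iter: int = 100,
) -> AlignedShapeSet:
    """Generalized Procrustes superimposition of a set of configurations.

    Each configuration is translated to the origin and scaled to unit
    centroid size, then iteratively rotated to the evolving consensus
    (mean) shape until the consensus moves by less than ``tol``.
    Rotations are proper (no reflections).
    """
    if len(configs) < 2:
        raise ValueError("need at least two configurations")
    ks = {c.coords.shape[0] for c in configs}
    if len(ks) != 1:
        raise ValueError(f"inconsistent landmark counts: {sorted(ks)}")
    k = ks.pop()
    if k < 3:
        raise ValueError("need at least 3 landmarks")

    mats, sizes = [], []
    for c in configs:
        m, s = _center_scale(c.coords, c.specimen_id)
        mats.append(m)
        sizes.append(s)
    mats = np.array(mats)  # n × K × 3

    consensus = mats[0].copy()
    for _ in range(max_iter):
        for i in range(len(mats)):
            mats[i] = mats[i] @ _optimal_rotation(mats[i], consensus)
        new = mats.mean(axis=0)
        new /= np.sqrt(np.sum(new * new))
        if np.max(np.abs(new - consensus)) < tol:
            consensus = new
            break
        consensus = new
    # final rotation pass against the converged consensus
    for i in range(len(mats)):
        mats[i] = mats[i] @ _optimal_rotation(mats[i], consensus)

    # canonical orientation: principal axes of the consensus go to the
    # coordinate axes with deterministic signs, so the output frame does
    # not depend on how the inputs happened to be oriented
    canon = _canonical_rotation(mats.mean(axis=0))
    for i in range(len(mats)):
        mats[i] = mats[i] @ canon

    meta = pd.DataFrame(
        {
            "specimen_id": [c.specimen_id for c in configs],
            "genotype": [c.genotype for c in configs],
            "lab": [c.lab for c in configs],
            "stage": [c.stage for c in configs],
            "size_covariate": [c.size_covariate for c in configs],
        }
    )
    return AlignedShapeSet(
        shapes=mats.reshape(len(mats), -1),
        centroid_sizes=np.array(sizes),
        consensus=mats.mean(axis=0).reshape(-1),
        metadata=meta,
    )


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two aligned (flat) shape vectors."""
    return float(np.linalg.norm(np.asarray(a, float) - np.asarray(b, float)))


def shape_pca(shapes: np.ndarray):
    """PCA of a shape matrix (rows = specimens).

    Returns ``(scores, eigenvalues, proportions)``.  Eigenvalues are of
    the covariance of centered rows; the sign of each component is fixed
    so that its largest-magnitude loading is positive.
    """
    x = np.asarray(shapes, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least two shapes")
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    eigvals = s ** 2 / (x.shape[0] - 1)
    # deterministic sign: largest-|loading| entry positive
    for i in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    scores = u * s
    total = eigvals.sum()
    props = eigvals / total if total > 0 else np.zeros_like(eigvals)
    return scores, eigvals, props


def _regress_out(shapes: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    """Residuals of per-coordinate linear regression, grand mean added back."""
    x = np.asarray(covariate, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant")
    design = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(design, shapes, rcond=None)
    resid = shapes - design @ beta
    return resid + shapes.mean(axis=0)


def standardize_shapes(
    aligned: AlignedShapeSet,
    covariate: str,
    within: str | None = None,
) -> AlignedShapeSet:
    """Remove the linear effect of a covariate (stage or size) from shape.

    Embryo datasets are standardized on developmental stage (tail-somite
    count); neonate datasets on centroid size.  Returns a new set whose
    shapes are the regression residuals plus the grand mean.

    With ``within`` set to a grouping column (typically ``genotype``),
    the slope is estimated from the pooled within-group covariance —
    equivalent to adding the group factor to the standardization model.
    This prevents a chance correlation between the covariate and a large
    between-group signal from leaking that signal into the within-group
    residuals.
    """
    if covariate not in aligned.metadata.columns:
        raise KeyError(f"covariate {covariate!r} not in metadata")
    vals = aligned.metadata[covariate].to_numpy(dtype=float)
    if np.any(~np.isfinite(vals)):
        raise ValueError(f"covariate {covariate!r} missing for some specimens")
    if within is None:
        return aligned.with_shapes(_regress_out(aligned.shapes, vals))

    groups = aligned.metadata[within].to_numpy()
    if np.ptp(vals) == 0:
        raise ValueError("covariate is constant")
    xc = vals.astype(float).copy()
    yc = aligned.shapes.copy()
    for g in pd.unique(groups):
        sel = groups == g
        xc[sel] -= xc[sel].mean()
        yc[sel] -= yc[sel].mean(axis=0)
    denom = xc @ xc
    if denom <= 0:
        raise ValueError("covariate is constant within every group")
    beta = (xc @ yc) / denom
    resid = aligned.shapes - np.outer(vals - vals.mean(), beta)
    return aligned.with_shapes(resid)


def remove_lab_offset(aligned: AlignedShapeSet, wild_type_genotype: str) -> AlignedShapeSet:
    """Remove between-lab batch effects using wild-type groups as anchors.

    For each non-reference lab, the difference between that lab's
    wild-type mean shape and the reference lab's wild-type mean shape is
    subtracted from every specimen of that lab.  The first lab in sorted
    order is the reference.
    """
    labs = aligned.metadata["lab"].to_numpy()
    genos = aligned.metadata["genotype"].to_numpy()
    uniq = sorted(set(labs))
    wt_means = {}
    for lab in uniq:
        sel = (labs == lab) & (genos == wild_type_genotype)
        if not sel.any():
            raise ValueError(f"lab {lab!r} has no wild-type specimens")
        wt_means[lab] = aligned.shapes[sel].mean(axis=0)
    ref = uniq[0]
    shapes = aligned.shapes.copy()
    for lab in uniq[1:]:
        shapes[labs == lab] -= wt_means[lab] - wt_means[ref]
    return aligned.with_shapes(shapes)


def shape_regression(shapes: np.ndarray, covariate: np.ndarray) -> ShapeRegressionResult:
    """Multivariate least-squares regression of shape on one covariate.

    ``r_squared`` is the fraction of the total (summed over coordinates)
    Procrustes sum of squares explained by the fit.  The regression
    score of a specimen is the projection of its centered shape onto the
    unit-normalized coefficient vector — with a pooled analysis this is
    the common allometric component (CAC) score.
    """
    x = np.asarray(covariate, dtype=float)
    y = np.asarray(shapes, dtype=float)
    if y.shape[0] < 3:
        raise ValueError("need at least 3 specimens")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant")
    design = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ beta
    resid = y - fitted
    yc = y - y.mean(axis=0)
    ss_tot = float(np.sum(yc * yc))
    ss_res = float(np.sum(resid * resid))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    coef = beta[1]
    norm = np.linalg.norm(coef)
    scores = yc @ (coef / norm) if norm > 0 else np.zeros(y.shape[0])
    return ShapeRegressionResult(
        coefficients=coef,
        intercept=beta[0],
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        regression_scores=scores,
        residual_shapes=resid + y.mean(axis=0),
    )


# ---------------------------------------------------------------------------
# disparity and permutation tests


def procrustes_variance(
    shapes: np.ndarray,
    groups: Sequence,
    ddof: int = 0,
) -> pd.Series:
    """Morphological disparity per group.

    Mean squared deviation from the group mean shape, summed over all
    coordinates; divisor n (``ddof=0``, the population convention of the
    morphological-disparity literature) by default, switchable to n−1.
    Groups of size 1 get NaN.
    """
    y = np.asarray(shapes, dtype=float)
    g = np.asarray(groups)
    out = {}
    for lab in pd.unique(g):
        sub = y[g == lab]
        if sub.shape[0] - ddof < 1 or sub.shape[0] < 2:
            out[lab] = np.nan
            continue
        dev = sub - sub.mean(axis=0)
        out[lab] = float(np.sum(dev * dev) / (sub.shape[0] - ddof))
    return pd.Series(out, name="disparity")


def _group_variances(y: np.ndarray, codes: np.ndarray, n_groups: int, ddof: int):
    """Per-group disparity for integer-coded labels (vector of length n_groups)."""
    out = np.full(n_groups, np.nan)
    for gi in range(n_groups):
        sub = y[codes == gi]
        if sub.shape[0] >= 2:
            dev = sub - sub.mean(axis=0)
            out[gi] = np.sum(dev * dev) / (sub.shape[0] - ddof)
    return out


def disparity_permutation_test(
    shapes: np.ndarray,
    groups: Sequence,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
    ddof: int = 0,
    residualize: bool = True,
) -> pd.DataFrame:
    """Pairwise permutation test for differences in Procrustes variance.

    The observed statistic for a pair of groups is |PV_a − PV_b| with
    PV = SS/(n−1).  With ``residualize`` (the default) each group's n
    centered rows are Helmert-rotated into n−1 rows whose squared norms
    average exactly to SS/(n−1) and are mutually uncorrelated; the null
    permutes these scalars across groups.  (Permuting centered residual
    vectors directly is anticonservative at small n: they sum to zero
    within a group, so mixed permuted groups look spuriously tight.)
    With ``residualize=False``, raw rows are permuted and group
    variances recomputed about the permuted means; that variant is exact
    only when group means are equal.  P values use the add-one
    convention P = (1 + #{null ≥ obs}) / (n_perm + 1) and so are never
    exactly 0.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    y = np.asarray(shapes, dtype=float)
    g = np.asarray(groups)
    labels = list(pd.unique(g))
    # stable integer coding in first-appearance order
    lab_to_code = {lab: i for i, lab in enumerate(labels)}
    codes = np.array([lab_to_code[v] for v in g])
    n_groups = len(labels)

    if residualize:
        # Helmert-rotate each group: n centered rows become n−1 rows with
        # independent squared norms whose mean is exactly SS/(n−1); the
        # scalars are exchangeable across groups under the null
        s_parts, code_parts = [], []
        for gi in range(n_groups):
            sub = y[codes == gi]
            if sub.shape[0] < 2:
                continue
            h = sp_helmert(sub.shape[0]) @ sub
            s_parts.append(np.sum(h * h, axis=1))
            code_parts.append(np.full(sub.shape[0] - 1, gi))
        s = np.concatenate(s_parts)
        s_codes = np.concatenate(code_parts)

        def group_stat(c):
            out = np.full(n_groups, np.nan)
            for gi in range(n_groups):
                sub = s[c == gi]
                if sub.size >= 1:
                    out[gi] = sub.mean()
            return out

        obs = group_stat(s_codes)
        null = np.empty((n_perm, n_groups))
        perm_codes = s_codes.copy()
        for b in range(n_perm):
            rng.shuffle(perm_codes)
            null[b] = group_stat(perm_codes)
    else:
        obs = _group_variances(y, codes, n_groups, ddof)
        null = np.empty((n_perm, n_groups))
        perm_codes = codes.copy()
        for b in range(n_perm):
            rng.shuffle(perm_codes)
            null[b] = _group_variances(y, perm_codes, n_groups, ddof)

    pmat = pd.DataFrame(np.ones((n_groups, n_groups)), index=labels, columns=labels)
    for i in range(n_groups):
        for j in range(i + 1, n_groups):
            d_obs = abs(obs[i] - obs[j])
            d_null = np.abs(null[:, i] - null[:, j])
            p = (1 + np.sum(d_null >= d_obs)) / (n_perm + 1)
            pmat.iat[i, j] = pmat.iat[j, i] = p
    return pmat


def mean_shape_permutation_test(
    shapes: np.ndarray,
    groups: Sequence,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Pairwise permutation test for mean-shape differences.

    Statistic: Procrustes distance between group mean shapes (shapes are
    assumed already superimposed, so this is the Euclidean distance in
    the common coordinate frame).  Null by permuting group labels.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    y = np.asarray(shapes, dtype=float)
    g = np.asarray(groups)
    labels = list(pd.unique(g))
    lab_to_code = {lab: i for i, lab in enumerate(labels)}
    codes = np.array([lab_to_code[v] for v in g])
    n_groups = len(labels)

    def group_means(c):
        return np.array([y[c == gi].mean(axis=0) for gi in range(n_groups)])

    obs_means = group_means(codes)
    null = np.empty((n_perm, n_groups, y.shape[1]))
    perm_codes = codes.copy()
    for b in range(n_perm):
        rng.shuffle(perm_codes)
        null[b] = group_means(perm_codes)

    pmat = pd.DataFrame(np.ones((n_groups, n_groups)), index=labels, columns=labels)
    for i in range(n_groups):
        for j in range(i + 1, n_groups):
            d_obs = np.linalg.norm(obs_means[i] - obs_means[j])
            d_null = np.linalg.norm(null[:, i] - null[:, j], axis=1)
            p = (1 + np.sum(d_null >= d_obs)) / (n_perm + 1)
            pmat.iat[i, j] = pmat.iat[j, i] = p
    return pmat


def variance_power_simulation(
    n_per_group: int,
    variance_ratio: float,
    alpha: float = 0.05,
    reps: int = 200,
    n_perm: int = 199,
    p_dims: int = 23,
    seed: int | np.random.Generator = 0,
    template=None,
) -> dict:
    """Power to detect a variance ratio between two groups by permutation.

    Each replicate draws two isotropic Gaussian groups in ``p_dims``
    dimensions (matching the effective dimensionality of aligned
    landmark residuals) with variances 1 and ``variance_ratio``, runs
    the disparity permutation test, and rejects when P ≤ alpha.  If a
    synthetic-series ``template`` is given, replicates instead generate
    landmark configurations from it (one genotype, noise SD inflated by
    √ratio in the second group) and superimpose them, exercising the
    full pipeline at higher cost.

    Returns power with its binomial standard error.
    """
    if reps < 100:
        raise ValueError("reps must be at least 100")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    labels = np.array(["a"] * n_per_group + ["b"] * n_per_group)
    hits = 0
    for _ in range(reps):
        if template is None:
            a = rng.standard_normal((n_per_group, p_dims))
            b = rng.standard_normal((n_per_group, p_dims)) * np.sqrt(variance_ratio)
            y = np.vstack([a, b])
        else:
            y = _template_replicate(template, n_per_group, variance_ratio, rng)
        p = disparity_permutation_test(y, labels, n_perm=n_perm, seed=rng)
        if p.iloc[0, 1] <= alpha:
            hits += 1
    power = hits / reps
    se = float(np.sqrt(power * (1 - power) / reps))
    return {"power": power, "se": se, "reps": reps, "alpha": alpha}


def _template_replicate(template, n_per_group, variance_ratio, rng):
    """Two noise-only groups from a series template, superimposed."""
    k = template.landmark_template.shape[0]
    sd = template.landmark_noise_sd
    configs = []
    for gi, scale in enumerate([1.0, np.sqrt(variance_ratio)]):
        for i in range(n_per_group):
            coords = template.landmark_template + rng.normal(
                0.0, sd * scale, size=(k, 3)
            )
            configs.append(
                LandmarkConfiguration(
                    specimen_id=f"g{gi}_{i}", coords=coords, genotype=str(gi)
                )
            )
    return generalized_procrustes(configs).shapes
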