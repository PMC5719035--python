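"""qPCR quantification and transcriptome-level resampling statistics.

Covers relative quantification of qPCR Ct tables (ΔΔCt), variance and
mean tests on expression across genotypes, median-of-ratios size-factor
normalization for count matrices, per-genotype fold-change profiles with
nearest-neighbor bootstrap tests, within-genotype expression concordance
(Fisher-z pairwise correlations between individuals), and gene-set
correlation tests against the perturbed signal with genome-wide
resampling null distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSet",
    "delta_delta_ct",
    "levene_test",
    "oneway_anova",
    "size_factor_normalize",
    "foldchange_profile",
    "neighbor_bootstrap_test",
    "within_genotype_concordance",
    "geneset_fgf8_correlation_test",
]

#: Fisher z is capped here for perfect correlations
FISHER_Z_CAP = float(np.arctanh(1.0 - 1e-12))


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: tuple[str, ...]

    def present_in(self, index) -> tuple[list[str], list[str]]:
        """Split members into (present, missing) against a gene index."""
        idx = set(index)
        present = [g for g in self.members if g in idx]
        missing = [g for g in self.members if g not in idx]
        return present, missing


def delta_delta_ct(
    table: pd.DataFrame,
    target: str = "target",
    reference: str = "reference",
    wt_genotype: str = "WT",
) -> pd.DataFrame:
    """Relative expression per sample by the ΔΔCt method.

    Per sample: ΔCt = mean Ct(target) − mean Ct(reference) over
    replicates.  ΔΔCt = ΔCt − mean ΔCt of the wild-type group, and the
    relative expression is 2^(−ΔΔCt).  Because the wild-type mean ΔCt is
    averaged on the cycle scale before exponentiation, the wild-type
    group's mean relative expression is close to, but not exactly, 1.
    """
    required = {"sample_id", "genotype", "gene", "ct"}
    if not required <= set(table.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    per = table.pivot_table(index=["sample_id", "genotype"], columns="gene",
                            values="ct", aggfunc="mean")
    for gene in (target, reference):
        if gene not in per.columns:
            raise ValueError(f"gene {gene!r} absent from Ct table")
    missing_ref = per[per[reference].isna()].index.get_level_values(0).tolist()
    if missing_ref:
        raise ValueError(f"samples missing reference gene: {missing_ref}")
    per = per.reset_index()
    per["delta_ct"] = per[target] - per[reference]
    wt = per.loc[per["genotype"] == wt_genotype, "delta_ct"]
    if wt.empty:
        raise ValueError(f"no samples with wild-type genotype {wt_genotype!r}")
    per["delta_delta_ct"] = per["delta_ct"] - wt.mean()
    per["relative_expression"] = 2.0 ** (-per["delta_delta_ct"])
    return per[["sample_id", "genotype", "delta_ct", "delta_delta_ct",
                "relative_expression"]]


def levene_test(values: np.ndarray, groups: Sequence) -> dict:
    """Levene's test (mean-centered variant) for variance homogeneity.

    Returns W, (df within, df between) in that order, and P.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    samples = [v[g == lab] for lab in pd.unique(g)]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >=2 groups with n >= 2 each")
    w, p = stats.levene(*samples, center="mean")
    n, k = v.size, len(samples)
    return {"W": float(w), "df": (n - k, k - 1), "P": float(p)}


def oneway_anova(values: np.ndarray, groups: Sequence) -> dict:
    """One-way ANOVA; df reported as (within, between)."""
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    samples = [v[g == lab] for lab in pd.unique(g)]
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    f, p = stats.f_oneway(*samples)
    n, k = v.size, len(samples)
    return {"F": float(f), "df": (n - k, k - 1), "P": float(p)}


# ---------------------------------------------------------------------------
# count-matrix machinery


def size_factor_normalize(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Median-of-ratios size factors and the normalized matrix.

    For each gene expressed in every sample, the ratio of each sample's
    count to the gene's geometric mean is formed; a sample's size factor
    is the median of these ratios.  Normalized counts are counts divided
    by the sample's factor.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    x = counts.to_numpy(dtype=float)
    all_pos = np.all(x > 0, axis=1)
    if not all_pos.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; "
            "filter samples or provide deeper coverage"
        )
    logx = np.log(x[all_pos])
    log_gm = logx.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logx - log_gm, axis=0))
    norm = counts / factors
    return norm, pd.Series(factors, index=counts.columns, name="size_factor")


def _genotype_of(columns, metadata: pd.DataFrame) -> pd.Series:
    meta = metadata.set_index("sample_id")["genotype"]
    missing = [c for c in columns if c not in meta.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")
    return meta.loc[list(columns)]


def foldchange_profile(
    norm: pd.DataFrame,
    metadata: pd.DataFrame,
    gene_set: GeneSet | None = None,
    wt_genotype: str = "WT",
) -> pd.DataFrame:
    """Per-genotype mean |fold change| vs wild type over a gene set.

    Fold change per gene is the genotype mean of normalized counts over
    the wild-type mean; its standard error is propagated from the two
    group SEs on the log scale (delta method).  The profile reports, per
    genotype, the average of |fold change| and the average |SE| over the
    set.  Genes with a zero wild-type mean are excluded and reported.
    """
    genos = _genotype_of(norm.columns, metadata)
    if wt_genotype not in set(genos):
        raise ValueError(f"wild-type genotype {wt_genotype!r} absent")
    if gene_set is not None:
        present, missing = gene_set.present_in(norm.index)
        if not present:
            raise ValueError(f"gene set {gene_set.name!r} has no genes in matrix")
        mat = norm.loc[present]
    else:
        missing = []
        mat = norm

    wt_cols = genos[genos == wt_genotype].index
    wt_mean = mat[wt_cols].mean(axis=1)
    usable = wt_mean > 0
    excluded = mat.index[~usable].tolist()
    mat = mat.loc[usable]
    wt_mean = wt_mean[usable]
    wt_se = mat[wt_cols].std(axis=1, ddof=1) / np.sqrt(len(wt_cols))

    rows = []
    for geno in pd.unique(genos):
        if geno == wt_genotype:
            continue
        cols = genos[genos == geno].index
        gmean = mat[cols].mean(axis=1)
        gse = mat[cols].std(axis=1, ddof=1) / np.sqrt(len(cols))
        fc = gmean / wt_mean
        # delta-method SE of the ratio
        se = fc * np.sqrt(
            (gse / gmean.replace(0, np.nan)) ** 2 + (wt_se / wt_mean) ** 2
        )
        rows.append(
            {
                "genotype": geno,
                "n_samples": len(cols),
                "mean_abs_foldchange": float(np.abs(fc).mean()),
                "mean_abs_se": float(np.abs(se).fillna(0.0).mean()),
                "n_genes": int(mat.shape[0]),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["excluded_genes"] = excluded
    out.attrs["missing_members"] = missing
    return out


def neighbor_bootstrap_test(
    norm: pd.DataFrame,
    metadata: pd.DataFrame,
    genotype_order: Sequence[str],
    gene_set: GeneSet | None = None,
    n_boot: int = 999,
    seed: int | np.random.Generator = 0,
    wt_genotype: str = "WT",
) -> pd.DataFrame:
    """Bootstrap test between nearest-neighbor genotypes on the profile.

    For each adjacent pair in ``genotype_order`` (ordered by mean
    expression), the statistic is the difference of the two groups' mean
    |fold change vs wild type|.  The null pools the pair's samples and
    resamples group assignments with replacement; P uses the add-one
    convention.
    """
    if n_boot < 999:
        raise ValueError("n_boot must be at least 999")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    genos = _genotype_of(norm.columns, metadata)
    if gene_set is not None:
        present, _ = gene_set.present_in(norm.index)
        mat = norm.loc[present].to_numpy(dtype=float)
    else:
        mat = norm.to_numpy(dtype=float)
    wt_cols = np.where(genos.to_numpy() == wt_genotype)[0]
    wt_mean = mat[:, wt_cols].mean(axis=1)
    usable = wt_mean > 0
    mat = mat[usable]
    wt_mean = wt_mean[usable]

    def stat(cols_a, cols_b):
        fa = np.abs(mat[:, cols_a].mean(axis=1) / wt_mean).mean()
        fb = np.abs(mat[:, cols_b].mean(axis=1) / wt_mean).mean()
        return fa - fb

    rows = []
    gnames = genos.to_numpy()
    for a, b in zip(genotype_order[:-1], genotype_order[1:]):
        ia = np.where(gnames == a)[0]
        ib = np.where(gnames == b)[0]
        flagged = len(ia) < 2 or len(ib) < 2
        obs = stat(ia, ib)
        pooled = np.concatenate([ia, ib])
        na = len(ia)
        null = np.empty(n_boot)
        for t in range(n_boot):
            draw = rng.choice(pooled, size=len(pooled), replace=True)
            null[t] = stat(draw[:na], draw[na:])
        p = (1 + np.sum(np.abs(null) >= abs(obs))) / (n_boot + 1)
        rows.append(
            {"genotype_a": a, "genotype_b": b, "statistic": obs, "P": p,
             "flagged_small_n": flagged}
        )
    return pd.DataFrame(rows)


def within_genotype_concordance(
    norm: pd.DataFrame,
    metadata: pd.DataFrame,
    gene_set: GeneSet | None = None,
    n_boot: int = 999,
    seed: int | np.random.Generator = 0,
    wt_genotype: str = "WT",
    use_covariance: bool = False,
) -> pd.DataFrame:
    """Concordance of expression among individuals within each genotype.

    For every pair of individuals in a genotype, the Pearson correlation
    of their log2(normalized + 1) profiles across the set's genes is
    computed and Fisher z-transformed (capped for perfect correlations).
    Each genotype's mean z is compared against the wild-type group by a
    bootstrap over individuals (add-one P, two-sided).  Consistently
    high z across genotypes — no genotype standing out — is the
    signature of *absent* dysregulation.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    genos = _genotype_of(norm.columns, metadata)
    if gene_set is not None:
        present, _ = gene_set.present_in(norm.index)
        if len(present) < 3:
            raise ValueError("need a gene set with >= 3 genes present")
        mat = norm.loc[present]
    else:
        mat = norm
    logm = np.log2(mat.to_numpy(dtype=float) + 1.0)

    def pair_zs(cols: np.ndarray) -> np.ndarray:
        zs = []
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                a, b = logm[:, cols[i]], logm[:, cols[j]]
                if np.std(a) == 0 or np.std(b) == 0:
                    continue  # constant profile; pair skipped
                if use_covariance:
                    zs.append(np.cov(a, b)[0, 1])
                else:
                    r = np.clip(np.corrcoef(a, b)[0, 1], -1.0 + 1e-15, 1.0 - 1e-15)
                    zs.append(np.clip(np.arctanh(r), -FISHER_Z_CAP, FISHER_Z_CAP))
        return np.asarray(zs)

    gnames = genos.to_numpy()
    wt_cols = np.where(gnames == wt_genotype)[0]
    if len(wt_cols) < 2:
        raise ValueError("wild-type group needs n >= 2")
    wt_z = pair_zs(wt_cols)

    rows = []
    for geno in pd.unique(gnames):
        cols = np.where(gnames == geno)[0]
        if len(cols) < 2:
            raise ValueError(f"genotype {geno!r} needs n >= 2")
        z = pair_zs(cols)
        if geno == wt_genotype:
            rows.append({"genotype": geno, "mean_z": float(wt_z.mean()),
                         "n_pairs": len(wt_z), "P_vs_wt": np.nan})
            continue
        obs = z.mean() - wt_z.mean()
        null = np.empty(n_boot)
        for t in range(n_boot):
            ca = rng.choice(cols, size=len(cols), replace=True)
            cb = rng.choice(wt_cols, size=len(wt_cols), replace=True)
            za, zb = pair_zs(np.unique(ca)), pair_zs(np.unique(cb))
            if za.size == 0 or zb.size == 0:
                null[t] = 0.0
            else:
                null[t] = (za.mean() - zb.mean()) - obs
        p = (1 + np.sum(np.abs(null) >= abs(obs))) / (n_boot + 1)
        rows.append({"genotype": geno, "mean_z": float(z.mean()),
                     "n_pairs": len(z), "P_vs_wt": float(p)})
    return pd.DataFrame(rows)


def geneset_fgf8_correlation_test(
    norm: pd.DataFrame,
    fgf8_levels: pd.Series,
    sets: Sequence[GeneSet],
    n_resample: int = 999,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene-set correlation with the perturbed signal vs a resampling null.

    Per gene: Pearson correlation of log2(normalized + 1) expression
    with the per-sample signal level.  Per set: the mean gene-level
    correlation, compared with the same statistic on ``n_resample``
    random same-size gene sets drawn genome-wide (two-sided 95% flag).
    Individual genes are flagged against the 95% band of the genome-wide
    single-gene correlation distribution.

    Returns ``(set table, gene table)``.
    """
    if n_resample < 999:
        raise ValueError("n_resample must be at least 999")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    levels = fgf8_levels.loc[list(norm.columns)].to_numpy(dtype=float)
    logm = np.log2(norm.to_numpy(dtype=float) + 1.0)
    lc = levels - levels.mean()
    denom_l = np.sqrt(np.sum(lc * lc))
    mc = logm - logm.mean(axis=1, keepdims=True)
    denom_g = np.sqrt(np.sum(mc * mc, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (mc @ lc) / (denom_g * denom_l)
    r = np.where(np.isfinite(r), r, 0.0)

    gene_lo, gene_hi = np.percentile(r, [2.5, 97.5])
    gene_table = pd.DataFrame(
        {
            "gene": norm.index,
            "correlation": r,
            "outside_95ci": (r < gene_lo) | (r > gene_hi),
        }
    )

    rows = []
    n_genes = r.size
    for gs in sets:
        present, missing = gs.present_in(norm.index)
        if not present:
            raise ValueError(f"gene set {gs.name!r} has no genes in the matrix")
        idx = norm.index.get_indexer(present)
        obs = float(r[idx].mean())
        draws = rng.integers(0, n_genes, size=(n_resample, len(idx)))
        null = r[draws].mean(axis=1)
        lo, hi = np.percentile(null, [2.5, 97.5])
        p = (1 + np.sum(np.abs(null - null.mean()) >= abs(obs - null.mean()))) / (
            n_resample + 1
        )
        rows.append(
            {
                "set": gs.name,
                "n_genes": len(idx),
                "n_missing": len(missing),
                "mean_correlation": obs,
                "null_lo": float(lo),
                "null_hi": float(hi),
                "outside_95ci": bool(obs < lo or obs > hi),
                "P": float(p),
            }
        )
    return pd.DataFrame(rows), gene_table
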