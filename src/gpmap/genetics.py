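"""SNP-frequency summaries for near-isogenic lines.

Establishes whether genomic variance tracks phenotypic variance across
an allelic series: per-group allele frequencies, the additive genetic
variance proxy Σ 2p(1−p) (unit allelic effects), and a relative
inbreeding coefficient from observed vs expected heterozygosity.
Genotypes are coded as alt-allele dosage 0/1/2 with NaN for missing.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "allele_frequencies",
    "additive_variance",
    "inbreeding_coefficient",
    "read_snp_csv",
]


def _group_matrix(m: pd.DataFrame, line_labels: pd.Series, group: str) -> np.ndarray:
    cols = line_labels.index[line_labels == group]
    if len(cols) < 1:
        raise ValueError(f"group {group!r} has no samples")
    return m[cols].to_numpy(dtype=float)


def allele_frequencies(m: pd.DataFrame, line_labels: pd.Series) -> pd.DataFrame:
    """Alt-allele frequency per locus per group (pairwise-complete).

    Missing genotypes (NaN) are excluded from the denominator; a locus
    with no calls in a group gets NaN frequency and is counted in the
    missing fraction.
    """
    out = {}
    for group in pd.unique(line_labels):
        x = _group_matrix(m, line_labels, group)
        with np.errstate(invalid="ignore"):
            out[group] = np.nanmean(x, axis=1) / 2.0
    freqs = pd.DataFrame(out, index=m.index)
    freqs.attrs["missing_fraction"] = {
        g: float(np.isnan(_group_matrix(m, line_labels, g)).mean())
        for g in pd.unique(line_labels)
    }
    return freqs


def additive_variance(freqs: pd.DataFrame | pd.Series) -> pd.DataFrame:
    """Additive genetic variance proxy per group: Σ 2p(1−p) over loci.

    Unit allelic effects are assumed, so the totals are comparable
    between groups but carry no absolute phenotypic scale.  Loci with
    undefined frequency are skipped.
    """
    f = freqs.to_frame() if isinstance(freqs, pd.Series) else freqs
    per_locus = 2.0 * f * (1.0 - f)
    totals = per_locus.sum(axis=0, skipna=True)
    out = pd.DataFrame({"additive_variance": totals})
    out["n_loci_used"] = per_locus.notna().sum(axis=0).to_numpy()
    out.attrs["per_locus"] = per_locus
    return out


def inbreeding_coefficient(m: pd.DataFrame, line_labels: pd.Series) -> pd.Series:
    """F = 1 − H_obs/H_exp averaged over polymorphic loci, per group.

    H_obs is the fraction of heterozygous calls at a locus; H_exp is
    2p(1−p) from the group's allele frequency.  Groups with no
    polymorphic locus get NaN (flagged in ``attrs``).
    """
    out, flagged = {}, []
    for group in pd.unique(line_labels):
        x = _group_matrix(m, line_labels, group)
        with np.errstate(invalid="ignore"):
            p = np.nanmean(x, axis=1) / 2.0
        h_exp = 2.0 * p * (1.0 - p)
        poly = np.isfinite(h_exp) & (h_exp > 0)
        if not poly.any():
            out[group] = np.nan
            flagged.append(group)
            continue
        h_obs = np.nanmean(x[poly] == 1, axis=1)
        out[group] = float(np.mean(1.0 - h_obs / h_exp[poly]))
    s = pd.Series(out, name="F")
    s.attrs["undefined_groups"] = flagged
    return s


def read_snp_csv(path) -> tuple[pd.DataFrame, pd.Series]:
    """Read a loci × samples dosage CSV.

    First column holds locus ids; an optional first row named ``line``
    gives the line label per sample (otherwise each sample is its own
    line).  Entries outside {0, 1, 2} become missing.
    """
    raw = pd.read_csv(path, index_col=0)
    if "line" in raw.index:
        labels = raw.loc["line"].astype(str)
        raw = raw.drop(index="line")
    else:
        labels = pd.Series(raw.columns, index=raw.columns)
    m = raw.apply(pd.to_numeric, errors="coerce")
    m = m.where(m.isin([0, 1, 2]))
    labels.name = "line"
    return m, labels
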