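"""Readers and writers for the plain-text formats used by the analyses.

Landmark data travel as wide CSV (one specimen per row: id, covariates,
then x1,y1,z1,...) or TPS files with LM3 records; counts as TSV (genes ×
samples); gene sets as GMT; Ct tables and SNP matrices as CSV; ground
truth and fitted parameters as YAML.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .expression import GeneSet
from .morphometrics import AlignedShapeSet, LandmarkConfiguration

__all__ = [
    "write_landmarks_csv",
    "read_landmarks_csv",
    "write_landmarks_tps",
    "read_landmarks_tps",
    "write_aligned_csv",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_gmt",
    "write_yaml",
    "read_yaml",
]


def write_landmarks_csv(configs: Sequence[LandmarkConfiguration], path) -> None:
    rows = []
    for c in configs:
        row = {
            "specimen_id": c.specimen_id,
            "genotype": c.genotype,
            "lab": c.lab,
            "stage": c.stage,
            "size_covariate": c.size_covariate,
        }
        flat = c.coords.reshape(-1)
        for i in range(c.coords.shape[0]):
            row[f"x{i + 1}"] = flat[3 * i]
            row[f"y{i + 1}"] = flat[3 * i + 1]
            row[f"z{i + 1}"] = flat[3 * i + 2]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_landmarks_csv(path) -> list[LandmarkConfiguration]:
    df = pd.read_csv(path)
    coord_cols = [c for c in df.columns if c[0] in "xyz" and c[1:].isdigit()]
    k = len(coord_cols) // 3
    if k * 3 != len(coord_cols):
        raise ValueError("coordinate columns not a multiple of 3")
    ordered = [f"{ax}{i + 1}" for i in range(k) for ax in "xyz"]
    out = []
    for _, row in df.iterrows():
        coords = row[ordered].to_numpy(dtype=float).reshape(k, 3)
        out.append(
            LandmarkConfiguration(
                specimen_id=str(row["specimen_id"]),
                coords=coords,
                genotype=str(row.get("genotype", "")),
                lab=str(row.get("lab", "")),
                stage=None if pd.isna(row.get("stage")) else float(row["stage"]),
                size_covariate=None
                if pd.isna(row.get("size_covariate"))
                else float(row["size_covariate"]),
            )
        )
    return out


def write_landmarks_tps(configs: Sequence[LandmarkConfiguration], path) -> None:
    """TPS with LM3 records (3D landmarks), IDs in the ID field."""
    with open(path, "w") as fh:
        for c in configs:
            fh.write(f"LM3={c.coords.shape[0]}\n")
            for p in c.coords:
                fh.write(f"{p[0]:.10g} {p[1]:.10g} {p[2]:.10g}\n")
            fh.write(f"ID={c.specimen_id}\n")


def read_landmarks_tps(path) -> list[LandmarkConfiguration]:
    out: list[LandmarkConfiguration] = []
    coords: list[list[float]] = []
    expected = 0
    sid = ""
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.upper().startswith("LM3="):
                expected = int(line.split("=", 1)[1])
                coords = []
            elif line.upper().startswith("ID="):
                sid = line.split("=", 1)[1]
                if len(coords) != expected:
                    raise ValueError(f"specimen {sid}: expected {expected} landmarks")
                out.append(
                    LandmarkConfiguration(specimen_id=sid, coords=np.array(coords))
                )
            elif line[0] in "-0123456789.":
                coords.append([float(v) for v in line.split()])
    return out


def write_aligned_csv(aligned: AlignedShapeSet, path) -> None:
    k = aligned.k
    cols = [f"{ax}{i + 1}" for i in range(k) for ax in "xyz"]
    df = pd.concat(
        [
            aligned.metadata.reset_index(drop=True),
            pd.DataFrame(aligned.shapes, columns=cols),
        ],
        axis=1,
    )
    df.insert(len(aligned.metadata.columns), "centroid_size", aligned.centroid_sizes)
    df.to_csv(path, index=False)


def read_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError("duplicate gene ids in counts matrix")
    if (df.to_numpy() < 0).any():
        raise ValueError("negative entries in counts matrix")
    return df


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t")


def read_gmt(path) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets.append(GeneSet(name=parts[0], members=tuple(parts[2:])))
    return sets


def write_yaml(obj, path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def read_yaml(path):
    return yaml.safe_load(Path(path).read_text())
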