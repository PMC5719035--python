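#!/usr/bin/env python
"""Generate the synthetic allelic-series datasets used by every later step.

Writes landmark configurations (wide CSV + TPS), triplicate qPCR Ct
tables, an RNA-seq style count matrix with known responsive genes, a
near-isogenic SNP panel, and the ground-truth sidecar, all under
``results/data/``.
"""

from pathlib import Path

from gpmap import default_gene_models, default_series
from gpmap.io import write_counts_tsv, write_landmarks_csv, write_landmarks_tps, write_yaml
from gpmap.synthetic import sample_counts, sample_landmarks, sample_qpcr, sample_snp_panel

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    series = default_series(seed=SEED)

    configs, truth = sample_landmarks(series)
    write_landmarks_csv(configs, OUT / "landmarks.csv")
    write_landmarks_tps(configs, OUT / "landmarks.tps")
    truth.to_csv(OUT / "ground_truth.csv", index=False)

    ct, ct_truth = sample_qpcr(series, seed=SEED + 1)
    ct.to_csv(OUT / "qpcr_ct.csv", index=False)
    ct_truth.to_csv(OUT / "qpcr_truth.csv", index=False)

    genes = default_gene_models()
    counts, meta = sample_counts(series, genes, seed=SEED + 2)
    write_counts_tsv(counts, OUT / "counts.tsv")
    meta.to_csv(OUT / "counts_meta.csv", index=False)

    snps, lines = sample_snp_panel(5, 2000, within_line_het=0.02, seed=SEED + 3)
    panel = snps.copy()
    panel.loc["line"] = lines.values
    panel.to_csv(OUT / "snp_panel.csv")

    write_yaml(
        {
            "seed": SEED,
            "genotypes": [
                {
                    "name": g.name,
                    "mean_expression": g.mean_expression,
                    "expression_sd": g.expression_sd,
                    "n_individuals": g.n_individuals,
                    "lab": g.lab,
                }
                for g in series.genotypes
            ],
            "curve": {"L_m": series.curve.L_m, "L_0": series.curve.L_0,
                      "k": series.curve.k},
            "landmark_noise_sd": series.landmark_noise_sd,
            "gene_classes": {
                cls: sum(m.response_class == cls for m in genes)
                for cls in sorted({m.response_class for m in genes})
            },
        },
        OUT / "series_config.yaml",
    )
    print(f"wrote {len(configs)} specimens, {counts.shape} counts, "
          f"{snps.shape} SNP panel to {OUT}")


if __name__ == "__main__":
    main()
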