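#!/usr/bin/env python
"""ANOVA-filtered PCA and group-centroid attenuation ratios.

Screens genes with a one-way ANOVA over the experimental groups (Storey
q < 0.05), projects replicate-averaged group profiles onto principal
components, and reports, per region, the PC1-PC2 distance from spaceflight
to ground control under saline (d_sal) and under the antioxidant (d_buoe).
A ratio d_buoe / d_sal below one indicates the antioxidant pulled the
flight transcriptome toward ground control.
"""

import argparse
from pathlib import Path

from dsp_attenuation.io import read_count_matrix, write_table
from dsp_attenuation.normalization import q3_normalize
from dsp_attenuation.pca import anova_filter, centroid_distances, run_pca


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--datadir", type=Path, default=Path("results/data"))
    parser.add_argument("--outdir", type=Path, default=Path("results/pca"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    matrix, annotations = read_count_matrix(
        args.datadir / "counts.tsv", args.datadir / "metadata.tsv"
    )
    norm = q3_normalize(matrix)
    grouping = [f"{a.region}_{a.condition}-{a.treatment}" for a in annotations]
    anova = anova_filter(norm, grouping)
    write_table(anova, args.outdir / "anova_qvalues.tsv")
    kept = set(anova.loc[anova["q_value"] < 0.05, "gene"])

    pca = run_pca(norm, annotations, kept, average_replicates=True)
    write_table(pca.to_frame(), args.outdir / "pca_coordinates.tsv")
    report = centroid_distances(pca)
    write_table(report, args.outdir / "distance_report.tsv")

    print(f"ANOVA kept {len(kept)} of {len(norm.genes)} genes (q < 0.05)")
    print(
        "explained variance (PC1, PC2): "
        f"{pca.explained_variance[0]:.2f}, {pca.explained_variance[1]:.2f}"
    )
    for row in report.itertuples():
        print(
            f"{row.region}: d_sal={row.d_sal:.2f}, d_buoe={row.d_buoe:.2f}, "
            f"ratio={row.attenuation_ratio:.2f}"
        )


if __name__ == "__main__":
    main()
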