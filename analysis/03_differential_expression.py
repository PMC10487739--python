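#!/usr/bin/env python
"""Per-region differential expression for the three contrasts.

For each brain region, runs the flight contrast (FLT-SAL vs GC-SAL), the
antioxidant-in-flight contrast (FLT-BuOE vs FLT-SAL) and the
antioxidant-in-ground contrast (GC-BuOE vs GC-SAL) on log2 Q3-normalized
values: Welch t-test, permutation q-values (1000 label permutations or full
enumeration), and DEG calls at q < 0.05, |log2FC| > 0.585. Writes one table
per (contrast, region) under results/de/ and prints the DEG counts.
"""

import argparse
import warnings
from pathlib import Path

from dsp_attenuation.diffexpr import (
    BUOE_CONTRAST,
    FLIGHT_CONTRAST,
    GROUND_BUOE_CONTRAST,
    de_analysis,
)
from dsp_attenuation.io import read_count_matrix, write_table
from dsp_attenuation.normalization import q3_normalize


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-perm", type=int, default=1000)
    parser.add_argument("--datadir", type=Path, default=Path("results/data"))
    parser.add_argument("--outdir", type=Path, default=Path("results/de"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    matrix, annotations = read_count_matrix(
        args.datadir / "counts.tsv", args.datadir / "metadata.tsv"
    )
    norm = q3_normalize(matrix)
    regions = sorted({a.region for a in annotations})
    for ri, region in enumerate(regions):
        counts = {}
        for ci, (tag, contrast) in enumerate(
            [
                ("flight", FLIGHT_CONTRAST(region)),
                ("buoe_flight", BUOE_CONTRAST(region)),
                ("buoe_ground", GROUND_BUOE_CONTRAST(region)),
            ]
        ):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # full enumeration at small n
                table = de_analysis(
                    norm, annotations, contrast,
                    n_perm=args.n_perm, seed=args.seed + 10 * ri + ci,
                )
            write_table(table, args.outdir / f"de_{tag}_{region}.tsv")
            counts[contrast.label] = int(table["is_deg"].sum())
        summary = ", ".join(f"{label}: {n} DEGs" for label, n in counts.items())
        print(f"{region}: {summary}")


if __name__ == "__main__":
    main()
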