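#!/usr/bin/env python
"""Direction-concordance attenuation statistics per region.

Intersects each region's flight DEGs with its antioxidant-in-flight DEGs,
partitions the overlap by fold-change sign agreement, and assesses it two
ways: Fisher's exact test on the N-complemented 2x2 contingency matrix, and
the 1000-fold gene-shuffling permutation null that preserves the real BuOE
DEG direction counts. Also writes the per-gene fold-change juxtaposition
used to flag flight-specific antioxidant responses.
"""

import argparse
from pathlib import Path

import pandas as pd

from dsp_attenuation.attenuation import attenuation_summary
from dsp_attenuation.io import write_table
from dsp_attenuation.pipeline import summarize_attenuation


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-perm", type=int, default=1000)
    parser.add_argument("--dedir", type=Path, default=Path("results/de"))
    parser.add_argument("--outdir", type=Path, default=Path("results/attenuation"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    regions = sorted(
        p.name.removeprefix("de_flight_").removesuffix(".tsv")
        for p in args.dedir.glob("de_flight_*.tsv")
    )
    summaries = []
    for ri, region in enumerate(regions):
        space = pd.read_csv(args.dedir / f"de_flight_{region}.tsv", sep="\t")
        buoe = pd.read_csv(args.dedir / f"de_buoe_flight_{region}.tsv", sep="\t")
        ground = pd.read_csv(args.dedir / f"de_buoe_ground_{region}.tsv", sep="\t")
        summaries.append(
            attenuation_summary(region, space, buoe, B=args.n_perm, seed=args.seed + ri)
        )
        genes = summarize_attenuation(space, buoe, ground)
        write_table(genes, args.outdir / f"attenuation_genes_{region}.tsv")
    summary = pd.concat(summaries, ignore_index=True)
    write_table(summary, args.outdir / "attenuation_summary.tsv")
    for row in summary.itertuples():
        print(
            f"{row.region}: {row.n_opposite} opposite / {row.n_same} same of "
            f"N={row.N}; Fisher p={row.fisher_p:.3g}, permutation p={row.perm_empirical_p:.3g}"
        )


if __name__ == "__main__":
    main()
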