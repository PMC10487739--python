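#!/usr/bin/env python
"""Gene-set over-representation and disease-association lookup.

Tests each region's flight DEGs against the synthetic pathway collection
(hypergeometric ORA with BH adjustment; the analyzed gene universe as
background) and intersects the pooled flight DEGs with the synthetic
gene-disease association table, case-insensitively. The region-seeded
synthetic pathways should surface at small adjusted p in their own region.
"""

import argparse
from pathlib import Path

import pandas as pd

from dsp_attenuation.enrichment import disease_hits, disease_summary, ora
from dsp_attenuation.io import read_association_table, read_gmt, write_table


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--datadir", type=Path, default=Path("results/data"))
    parser.add_argument("--dedir", type=Path, default=Path("results/de"))
    parser.add_argument("--outdir", type=Path, default=Path("results/enrichment"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    sets = read_gmt(args.datadir / "pathways_synthetic.gmt")
    assoc = read_association_table(args.datadir / "disease_associations_synthetic.tsv")

    all_degs: set[str] = set()
    universe: set[str] = set()
    for path in sorted(args.dedir.glob("de_flight_*.tsv")):
        region = path.name.removeprefix("de_flight_").removesuffix(".tsv")
        de = pd.read_csv(path, sep="\t")
        universe = set(de["gene"])
        degs = set(de.loc[de["is_deg"], "gene"])
        all_degs |= degs
        if not degs:
            print(f"{region}: no DEGs, skipping ORA")
            continue
        table = ora(degs, sets, universe)
        write_table(table, args.outdir / f"enrichment_flight_{region}.tsv")
        top = table.iloc[0]
        print(
            f"{region}: top set {top['set_name']} "
            f"(overlap {top['overlap_count']}/{top['set_size']}, adj p={top['adj_p']:.2g})"
        )

    hits = disease_hits(all_degs, assoc)
    write_table(hits, args.outdir / "disease_hits.tsv")
    summary = disease_summary(hits)
    write_table(summary, args.outdir / "disease_summary.tsv")
    print(f"{hits['gene'].nunique()} of {len(all_degs)} pooled flight DEGs have a disease association")


if __name__ == "__main__":
    main()
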