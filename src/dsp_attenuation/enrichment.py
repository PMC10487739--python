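"""Local gene-set over-representation and disease-association lookup.

Over-representation analysis (ORA) tests each user-supplied gene set
(e.g. KEGG pathways from a GMT file) against a DEG list with the one-sided
hypergeometric upper-tail probability of the observed overlap, with the
analyzed gene universe as background, then applies Benjamini-Hochberg
adjustment across sets. Disease association is a plain case-insensitive
intersection of the DEG list with a (gene, disease) table — mouse DEG
symbols are matched to human resource symbols regardless of casing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError
from .io import AssociationTable, GeneSetCollection

__all__ = ["ora", "disease_hits", "disease_summary"]

ORA_COLUMNS = [
    "set_name",
    "overlap_count",
    "set_size",
    "list_size",
    "universe_size",
    "p_value",
    "adj_p",
    "overlap_genes",
]


def ora(
    deg_list: set[str] | list[str],
    sets: GeneSetCollection,
    universe: set[str] | list[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``deg_list`` in each gene set.

    Sets are intersected with the universe before testing; the p-value for a
    set with ``K`` universe members and overlap ``k`` with a list of size
    ``n`` drawn from a universe of size ``M`` is ``P[X >= k]`` for
    ``X ~ Hypergeom(M, K, n)``. BH adjustment is applied across sets and
    rows are sorted by p-value.
    """
    universe = set(universe)
    deg = set(deg_list)
    if not universe:
        raise DataError("universe is empty")
    if not deg:
        raise DataError("DEG list is empty")
    if not deg <= universe:
        raise DataError(f"{len(deg - universe)} DEG(s) are outside the universe")

    rows = []
    for name, members in sets.sets.items():
        members_in = members & universe
        if not members_in:
            continue
        overlap = sorted(deg & members_in)
        k, K, n, M = len(overlap), len(members_in), len(deg), len(universe)
        p = float(stats.hypergeom.sf(k - 1, M, K, n))
        rows.append(
            {
                "set_name": name,
                "overlap_count": k,
                "set_size": K,
                "list_size": n,
                "universe_size": M,
                "p_value": min(p, 1.0),
                "overlap_genes": ",".join(overlap),
            }
        )
    if not rows:
        return pd.DataFrame(columns=ORA_COLUMNS)
    df = pd.DataFrame(rows)
    df["adj_p"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    df["adj_p"] = np.maximum(df["adj_p"], df["p_value"])
    df = df.sort_values(["p_value", "set_name"], kind="stable").reset_index(drop=True)
    return df[ORA_COLUMNS]


def disease_hits(deg_list: set[str] | list[str], assoc: AssociationTable) -> pd.DataFrame:
    """Case-insensitive intersection of a DEG list with (gene, disease) pairs.

    Returns one row per hit with the DEG's own casing preserved.
    """
    by_upper: dict[str, str] = {}
    for g in deg_list:
        by_upper.setdefault(g.upper(), g)
    rows = [
        {"gene": by_upper[gene.upper()], "disease": disease}
        for gene, disease in assoc.rows
        if gene.upper() in by_upper
    ]
    df = pd.DataFrame(rows, columns=["gene", "disease"])
    return df.sort_values(["disease", "gene"], kind="stable").reset_index(drop=True)


def disease_summary(hits: pd.DataFrame) -> pd.DataFrame:
    """Per-disease counts of distinct associated DEGs."""
    if hits.empty:
        return pd.DataFrame(columns=["disease", "n_genes"])
    out = (
        hits.groupby("disease")["gene"]
        .nunique()
        .reset_index()
        .rename(columns={"gene": "n_genes"})
        .sort_values(["n_genes", "disease"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    return out
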