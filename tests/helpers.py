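"""Shared test construction helpers (kept out of conftest so they can be imported)."""

import numpy as np
import pandas as pd

from dsp_attenuation.normalization import NormalizedMatrix


def make_normalized(log2_values, genes=None, aois=None) -> NormalizedMatrix:
    """Build a NormalizedMatrix directly from log2 values (for closed-form tests)."""
    log2_values = np.asarray(log2_values, dtype=float)
    n_genes, n_aois = log2_values.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    aois = aois or [f"a{j}" for j in range(n_aois)]
    values = np.power(2.0, log2_values) - 1.0
    return NormalizedMatrix(
        genes=genes,
        aois=aois,
        values=values,
        q3_factors=np.ones(n_aois),
        log2_values=log2_values,
    )


def make_de_table(universe, deg_signs: dict[str, int], lfc_magnitude: float = 1.0) -> pd.DataFrame:
    """Minimal DE result table: DEGs given as gene -> +1/-1 sign."""
    rows = []
    for g in universe:
        sign = deg_signs.get(g, 0)
        rows.append(
            {
                "gene": g,
                "log2FC": sign * lfc_magnitude,
                "t_stat": float(sign),
                "p_value": 0.001 if sign else 0.5,
                "q_value": 0.001 if sign else 0.5,
                "is_deg": bool(sign),
                "direction": {1: "up", -1: "down", 0: "none"}[sign],
            }
        )
    return pd.DataFrame(rows)
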