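"""Q3 (third-quartile) normalization of digital spatial profiling counts.

Each AOI's counts are divided by a scale factor proportional to that AOI's
75th percentile over all genes, rescaled so the factors have geometric mean
one (the standard GeoMx convention):

    factor_a = Q3_a / geometric_mean(Q3 over all AOIs)
    values[g, a] = counts[g, a] / factor_a

After normalization every AOI shares the same 75th percentile (the geometric
mean of the raw Q3s). Percentiles use linear interpolation between order
statistics. Downstream statistics work on ``log2(value + 1)``; the +1
pseudocount keeps zero counts at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateAOIError
from .io import CountMatrix


@dataclass
class NormalizedMatrix:
    """Q3-normalized expression values plus their log2(x+1) transform."""

    genes: list[str]
    aois: list[str]
    values: np.ndarray
    q3_factors: np.ndarray
    log2_values: np.ndarray

    def to_frame(self, log2: bool = False) -> pd.DataFrame:
        data = self.log2_values if log2 else self.values
        return pd.DataFrame(data, index=self.genes, columns=self.aois)


def q3_factors(counts: CountMatrix) -> np.ndarray:
    """Per-AOI Q3 scale factors with geometric mean one.

    Raises :class:`DegenerateAOIError` naming the first AOI whose 75th
    percentile is zero (such an AOI carries no usable signal).
    """
    q3 = np.percentile(counts.counts, 75, axis=0, method="linear")
    zero = np.nonzero(q3 <= 0)[0]
    if zero.size:
        raise DegenerateAOIError(
            f"AOI {counts.aois[zero[0]]!r} has a zero 75th-percentile count"
        )
    geo_mean = np.exp(np.mean(np.log(q3)))
    return q3 / geo_mean


def q3_normalize(counts: CountMatrix) -> NormalizedMatrix:
    """Scale each AOI by its Q3 factor and attach the log2(x+1) transform."""
    factors = q3_factors(counts)
    values = counts.counts / factors[np.newaxis, :]
    return NormalizedMatrix(
        genes=list(counts.genes),
        aois=list(counts.aois),
        values=values,
        q3_factors=factors,
        log2_values=np.log2(values + 1.0),
    )
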