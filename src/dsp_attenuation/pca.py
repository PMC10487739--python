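"""ANOVA-filtered PCA and group-centroid distances.

Genes are first screened with a one-way ANOVA on log2 Q3-normalized values,
using the experimental group (region x condition x treatment) as the factor;
q-values come from the Storey procedure with a fixed lambda of 0.5. Genes
with q < 0.05 enter a PCA of the gene-centered log2 matrix. Following the
group-averaged view of the data, replicate AOIs can be averaged per group
before projection so each group contributes a single point.

Attenuation is then read off the PC1-PC2 plane: per region,

    d_sal  = ||centroid(FLT-SAL) - centroid(GC-SAL)||
    d_buoe = ||centroid(FLT-BuOE) - centroid(GC-BuOE)||

and ``attenuation_ratio = d_buoe / d_sal``. A ratio below one means the
antioxidant moved the flight transcriptome toward its ground control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .errors import DataError, DesignError, FilterError
from .io import AOIAnnotation
from .normalization import NormalizedMatrix

__all__ = [
    "PCAResult",
    "storey_qvalues",
    "anova_filter",
    "run_pca",
    "centroid_distances",
]


@dataclass
class PCAResult:
    """PCA coordinates plus the metadata needed to locate group centroids."""

    coordinates: np.ndarray  # samples (or group centroids) x components
    explained_variance: np.ndarray  # fraction per component, nonincreasing
    sample_labels: list[str]
    sample_groups: list[tuple[str, str, str]]  # (region, condition, treatment)
    kept_genes: list[str]
    averaged: bool

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coordinates,
            columns=[f"PC{i + 1}" for i in range(self.coordinates.shape[1])],
        )
        df.insert(0, "sample", self.sample_labels)
        regions, conds, trts = zip(*self.sample_groups)
        df.insert(1, "region", regions)
        df.insert(2, "condition", conds)
        df.insert(3, "treatment", trts)
        return df


def storey_qvalues(p_values: np.ndarray, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with a fixed pi0 estimate at lambda = ``lam``.

    pi0 = min(1, #{p > lam} / (m (1 - lam))); q(i) for the i-th smallest p is
    min_{j >= i} pi0 * m * p_(j) / j.
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    pi0 = min(1.0, (p > lam).sum() / (m * (1.0 - lam)))
    if pi0 == 0.0:
        pi0 = 1.0 / m  # all p below lambda; keep the estimate positive
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1, dtype=float)
    q_sorted = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def anova_filter(
    norm: NormalizedMatrix, grouping: list[str]
) -> pd.DataFrame:
    """One-way ANOVA per gene on log2 values over the given factor labels.

    Returns a frame with columns gene, F, p_value, q_value. Requires at
    least two factor levels with at least two AOIs each. Genes that are
    constant within every level get F = 0, p = 1.
    """
    if len(grouping) != len(norm.aois):
        raise DesignError("grouping must assign one label per AOI")
    levels = sorted(set(grouping))
    groups = []
    for level in levels:
        idx = [i for i, g in enumerate(grouping) if g == level]
        if len(idx) < 2:
            raise DesignError(f"factor level {level!r} has fewer than 2 AOIs")
        groups.append(norm.log2_values[:, idx])
    if len(levels) < 2:
        raise DesignError("ANOVA needs at least 2 factor levels")
    with np.errstate(invalid="ignore", divide="ignore"):
        f_stat, p = stats.f_oneway(*groups, axis=1)
    # constant-everywhere genes yield nan: no variance, no evidence
    nan = ~np.isfinite(f_stat)
    f_stat = np.where(nan, 0.0, f_stat)
    p = np.where(nan, 1.0, p)
    q = storey_qvalues(p)
    return pd.DataFrame(
        {"gene": norm.genes, "F": f_stat, "p_value": p, "q_value": q}
    )


def run_pca(
    norm: NormalizedMatrix,
    annotations: list[AOIAnnotation],
    kept_genes: set[str] | list[str],
    average_replicates: bool = True,
    n_components: int | None = None,
) -> PCAResult:
    """Project samples (or group averages) onto principal components.

    The input is the log2 matrix restricted to ``kept_genes``, centered per
    gene. With ``average_replicates`` each (region, condition, treatment)
    group contributes one averaged profile, matching a group-centroid view.
    """
    kept = [g for g in norm.genes if g in set(kept_genes)]
    if not kept:
        raise FilterError("kept_genes is empty after intersection with the matrix")
    gene_idx = [i for i, g in enumerate(norm.genes) if g in set(kept)]
    X = norm.log2_values[gene_idx, :].T  # samples x genes

    if average_replicates:
        keys: list[tuple[str, str, str]] = []
        for a in annotations:
            key = (a.region, a.condition, a.treatment)
            if key not in keys:
                keys.append(key)
        rows = []
        for key in keys:
            idx = [
                i
                for i, a in enumerate(annotations)
                if (a.region, a.condition, a.treatment) == key
            ]
            rows.append(X[idx].mean(axis=0))
        X = np.vstack(rows)
        labels = ["_".join(k) for k in keys]
        groups = keys
    else:
        labels = [a.aoi_id for a in annotations]
        groups = [(a.region, a.condition, a.treatment) for a in annotations]

    max_components = min(X.shape[0], X.shape[1])
    k = max_components if n_components is None else min(n_components, max_components)
    if len(kept) < k:
        raise FilterError(f"{len(kept)} kept genes cannot support {k} components")
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(X)
    return PCAResult(
        coordinates=coords,
        explained_variance=pca.explained_variance_ratio_,
        sample_labels=labels,
        sample_groups=groups,
        kept_genes=kept,
        averaged=average_replicates,
    )


def centroid_distances(pca: PCAResult) -> pd.DataFrame:
    """Per-region Euclidean distances between group centroids in PC1-PC2.

    Columns: region, d_sal (FLT-SAL to GC-SAL), d_buoe (FLT-BuOE to
    GC-BuOE), attenuation_ratio = d_buoe / d_sal (NaN when d_sal = 0).
    """
    if pca.coordinates.shape[1] < 2:
        raise DataError("centroid distances need at least 2 components")
    coords = pca.coordinates[:, :2]
    regions = sorted({g[0] for g in pca.sample_groups})
    rows = []
    for region in regions:
        centroids: dict[tuple[str, str], np.ndarray] = {}
        for (cond, trt) in [("GC", "SAL"), ("GC", "BuOE"), ("FLT", "SAL"), ("FLT", "BuOE")]:
            idx = [
                i
                for i, g in enumerate(pca.sample_groups)
                if g == (region, cond, trt)
            ]
            if not idx:
                raise DataError(f"group {cond}-{trt} missing in region {region}")
            centroids[(cond, trt)] = coords[idx].mean(axis=0)
        d_sal = float(np.linalg.norm(centroids[("FLT", "SAL")] - centroids[("GC", "SAL")]))
        d_buoe = float(np.linalg.norm(centroids[("FLT", "BuOE")] - centroids[("GC", "BuOE")]))
        ratio = d_buoe / d_sal if d_sal > 0 else float("nan")
        rows.append(
            {"region": region, "d_sal": d_sal, "d_buoe": d_buoe, "attenuation_ratio": ratio}
        )
    return pd.DataFrame(rows, columns=["region", "d_sal", "d_buoe", "attenuation_ratio"])
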