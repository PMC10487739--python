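"""Per-region differential expression with permutation-based q-values.

For one contrast within one brain region (e.g. FLT-SAL vs GC-SAL), each
gene's log2 Q3-normalized values are compared between the two groups with an
unpaired Welch t-test; log2 fold change is the difference of group means on
the log2 scale (test minus reference). False-discovery q-values come from a
label-permutation null: group labels are permuted within the region, per-gene
p-values are recomputed for each permutation, and

    q(g) = mean_over_permutations #{null p <= p_g} / #{observed p <= p_g}

clipped to [0, 1] and made monotone nondecreasing in p-rank. When fewer
distinct label assignments exist than requested permutations (e.g. C(6,3)=20
for 3 vs 3), all distinct assignments are enumerated instead.

A gene is called differentially expressed when q < 0.05 and |log2 FC| >
0.585 (fold change above 1.5x), both inequalities strict.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContrastError
from .io import AOIAnnotation
from .normalization import NormalizedMatrix

__all__ = [
    "Contrast",
    "DE_COLUMNS",
    "FLIGHT_CONTRAST",
    "BUOE_CONTRAST",
    "GROUND_BUOE_CONTRAST",
    "group_columns",
    "log2_fold_change",
    "welch_t",
    "t_test",
    "permutation_qvalues",
    "call_degs",
    "de_analysis",
]

#: DEG thresholds: q < 0.05 and |log2 FC| > 0.585 (strict).
Q_THRESHOLD = 0.05
LFC_THRESHOLD = 0.585

#: Variance floor avoiding division by zero at constant genes.
_VAR_FLOOR = 1e-12

DE_COLUMNS = ["gene", "log2FC", "t_stat", "p_value", "q_value", "is_deg", "direction"]


@dataclass(frozen=True)
class Contrast:
    """A two-group comparison within one region; sign convention is
    test minus reference."""

    region: str
    reference_group: tuple[str, str]  # (condition, treatment)
    test_group: tuple[str, str]
    label: str = ""

    def __post_init__(self) -> None:
        if self.reference_group == self.test_group:
            raise ContrastError("reference and test group are identical")
        if not self.label:
            object.__setattr__(
                self,
                "label",
                f"{'-'.join(self.test_group)} vs {'-'.join(self.reference_group)}",
            )


def FLIGHT_CONTRAST(region: str) -> Contrast:
    """Spaceflight contrast: FLT-SAL vs GC-SAL (reference GC-SAL)."""
    return Contrast(region, reference_group=("GC", "SAL"), test_group=("FLT", "SAL"))


def BUOE_CONTRAST(region: str) -> Contrast:
    """Antioxidant-in-flight contrast: FLT-BuOE vs FLT-SAL (reference FLT-SAL)."""
    return Contrast(region, reference_group=("FLT", "SAL"), test_group=("FLT", "BuOE"))


def GROUND_BUOE_CONTRAST(region: str) -> Contrast:
    """Antioxidant-in-ground contrast: GC-BuOE vs GC-SAL."""
    return Contrast(region, reference_group=("GC", "SAL"), test_group=("GC", "BuOE"))


def group_columns(
    annotations: list[AOIAnnotation], region: str, condition: str, treatment: str
) -> np.ndarray:
    """Column indices of the AOIs belonging to one region x group."""
    idx = [
        i
        for i, a in enumerate(annotations)
        if a.region == region and a.condition == condition and a.treatment == treatment
    ]
    return np.asarray(idx, dtype=int)


def _contrast_columns(
    annotations: list[AOIAnnotation], contrast: Contrast
) -> tuple[np.ndarray, np.ndarray]:
    test = group_columns(annotations, contrast.region, *contrast.test_group)
    ref = group_columns(annotations, contrast.region, *contrast.reference_group)
    if test.size == 0 or ref.size == 0:
        raise ContrastError(
            f"contrast {contrast.label!r} in region {contrast.region!r} has an empty group"
        )
    return test, ref


def log2_fold_change(
    norm: NormalizedMatrix, annotations: list[AOIAnnotation], contrast: Contrast
) -> np.ndarray:
    """Per-gene difference of group means of log2 values (test minus reference)."""
    test, ref = _contrast_columns(annotations, contrast)
    return norm.log2_values[:, test].mean(axis=1) - norm.log2_values[:, ref].mean(axis=1)


def welch_t(test: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Welch t-test along the last axis; vectorized over leading axes.

    Per-group variances are floored at 1e-12 so constant genes yield t = 0,
    p = 1 when the group means agree and an extreme (p near 0) statistic when
    they do not.
    """
    n1, n2 = test.shape[-1], ref.shape[-1]
    if n1 < 2 or n2 < 2:
        raise ContrastError("each group needs at least 2 AOIs for a t-test")
    m1, m2 = test.mean(axis=-1), ref.mean(axis=-1)
    v1 = np.maximum(test.var(axis=-1, ddof=1), _VAR_FLOOR)
    v2 = np.maximum(ref.var(axis=-1, ddof=1), _VAR_FLOOR)
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / np.sqrt(se2)
    df = se2**2 / (v1**2 / (n1**2 * (n1 - 1)) + v2**2 / (n2**2 * (n2 - 1)))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, p


def t_test(
    norm: NormalizedMatrix, annotations: list[AOIAnnotation], contrast: Contrast
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene (t statistic, two-sided p) for a contrast on log2 values."""
    test, ref = _contrast_columns(annotations, contrast)
    return welch_t(norm.log2_values[:, test], norm.log2_values[:, ref])


def _label_assignments(n_total: int, n_test: int, n_perm: int, seed: int) -> np.ndarray:
    """Rows of test-group column index sets, one per permutation.

    Enumerates all C(n_total, n_test) distinct assignments when there are no
    more of them than ``n_perm`` (with a warning); otherwise draws ``n_perm``
    random label permutations.
    """
    n_distinct = comb(n_total, n_test)
    if n_distinct <= n_perm:
        warnings.warn(
            f"only {n_distinct} distinct label assignments (< {n_perm} requested); "
            "enumerating all of them",
            stacklevel=3,
        )
        return np.array(list(combinations(range(n_total), n_test)), dtype=int)
    rng = np.random.default_rng(seed)
    return np.array([rng.permutation(n_total)[:n_test] for _ in range(n_perm)], dtype=int)


def permutation_qvalues(
    norm: NormalizedMatrix,
    annotations: list[AOIAnnotation],
    contrast: Contrast,
    n_perm: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Permutation q-values for every gene under one contrast.

    Pools per-gene null p-values across label permutations and plugs them
    into the FDR estimate described in the module docstring.
    """
    test, ref = _contrast_columns(annotations, contrast)
    # canonical column order so that swapping test/reference yields bitwise
    # identical statistics (Welch p is symmetric under the swap)
    cols = np.sort(np.concatenate([test, ref]))
    data = norm.log2_values[:, cols]
    n_total, n_test = cols.size, test.size
    obs_mask = np.isin(cols, test)

    _, p_obs = welch_t(data[:, obs_mask], data[:, ~obs_mask])

    assignments = _label_assignments(n_total, n_test, n_perm, seed)
    # the observed labeling (and, for equal group sizes, its complement —
    # the same two-group partition) carries no null information: a null that
    # contains the observed p's verbatim floors q at 2/n_assignments and can
    # never call anything at small n; drop it
    obs_set = frozenset(np.flatnonzero(obs_mask))
    null_ps = []
    for row in assignments:
        row_set = frozenset(int(i) for i in row)
        if row_set == obs_set or (n_total - n_test == n_test and
                                  row_set == frozenset(range(n_total)) - obs_set):
            continue
        mask = np.zeros(n_total, dtype=bool)
        mask[row] = True
        _, p_null = welch_t(data[:, mask], data[:, ~mask])
        null_ps.append(p_null)
    null_p = np.sort(np.concatenate(null_ps))
    n_perm_eff = len(null_ps)

    order = np.argsort(p_obs, kind="stable")
    p_sorted = p_obs[order]
    # mean over permutations of #{null p <= p_g}
    mean_null_count = np.searchsorted(null_p, p_sorted, side="right") / n_perm_eff
    # ties: every gene with the same p shares the largest rank among them
    obs_count = np.searchsorted(p_sorted, p_sorted, side="right").astype(float)
    q_sorted = np.clip(mean_null_count / obs_count, 0.0, 1.0)
    # enforce monotone nondecreasing in p-rank (cumulative min from the top)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def call_degs(
    genes: list[str],
    log2fc: np.ndarray,
    t_stat: np.ndarray,
    p_value: np.ndarray,
    q_value: np.ndarray,
    q_threshold: float = Q_THRESHOLD,
    lfc_threshold: float = LFC_THRESHOLD,
) -> pd.DataFrame:
    """Assemble the per-gene result table and apply the DEG thresholds.

    Both thresholds are strict: q must be below ``q_threshold`` and |log2FC|
    strictly above ``lfc_threshold``.
    """
    is_deg = (q_value < q_threshold) & (np.abs(log2fc) > lfc_threshold)
    direction = np.where(is_deg, np.where(log2fc > 0, "up", "down"), "none")
    return pd.DataFrame(
        {
            "gene": genes,
            "log2FC": log2fc,
            "t_stat": t_stat,
            "p_value": p_value,
            "q_value": q_value,
            "is_deg": is_deg,
            "direction": direction,
        },
        columns=DE_COLUMNS,
    )


def de_analysis(
    norm: NormalizedMatrix,
    annotations: list[AOIAnnotation],
    contrast: Contrast,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Full differential-expression table for one contrast."""
    lfc = log2_fold_change(norm, annotations, contrast)
    t, p = t_test(norm, annotations, contrast)
    q = permutation_qvalues(norm, annotations, contrast, n_perm=n_perm, seed=seed)
    return call_degs(norm.genes, lfc, t, p, q)
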