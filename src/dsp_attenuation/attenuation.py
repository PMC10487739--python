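"""Direction-concordance statistics for antioxidant attenuation.

If the antioxidant BuOE attenuates spaceflight-induced expression changes,
genes it regulates during flight should move in the *opposite* direction to
the flight effect. This module quantifies that: spaceflight-induced DEGs
(FLT-SAL vs GC-SAL) are intersected with BuOE-induced DEGs (FLT-BuOE vs
FLT-SAL) and partitioned by log2-fold-change sign agreement.

Two significance assessments are provided:

1. A 2x2 contingency matrix built, with N = (# spaceflight DEGs) +
   (# BuOE DEGs), as::

       X11 = n_opposite    X12 = N - X11
       X21 = n_same        X22 = N - X21

   followed by a two-sided Fisher's exact test. Note the construction
   complements each row against N rather than against the overlap — it is
   reproduced here exactly as defined, and its rows are not independent
   samples; :func:`direction_independence_table` offers a conventional
   independence cross-tabulation alongside.

2. A gene-shuffling permutation null: the analyzed gene list is shuffled,
   the top N_up / bottom N_down genes of the shuffled list are taken as
   pseudo up-/down-regulated BuOE DEGs (N_up, N_down = the real BuOE DEG
   direction counts), and the opposite-direction overlap with the real
   spaceflight DEGs is recounted. Repeating B times gives
   empirical_p = (1 + #{null >= observed}) / (1 + B).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, ConfigError

__all__ = [
    "OverlapCounts",
    "ContingencyMatrix",
    "PermutationNullResult",
    "overlap_directions",
    "build_contingency",
    "direction_independence_table",
    "fisher_exact",
    "permutation_null",
    "expected_null_opposite",
]


@dataclass(frozen=True)
class OverlapCounts:
    """Direction-partitioned overlap of spaceflight and BuOE DEG sets."""

    n_opposite: int
    n_same: int
    n_space_degs: int
    n_buoe_degs: int

    def __post_init__(self) -> None:
        if min(self.n_opposite, self.n_same, self.n_space_degs, self.n_buoe_degs) < 0:
            raise ValueError("overlap counts must be non-negative")
        if self.n_opposite + self.n_same > min(self.n_space_degs, self.n_buoe_degs):
            raise ValueError("overlap exceeds the smaller DEG set")

    @property
    def N(self) -> int:
        """Total DEG count: spaceflight DEGs plus BuOE DEGs."""
        return self.n_space_degs + self.n_buoe_degs


@dataclass
class ContingencyMatrix:
    """The 2x2 matrix [[X11, X12], [X21, X22]] with both row sums equal to N."""

    X11: int
    X12: int
    X21: int
    X22: int
    fisher_p: float | None = None

    def as_array(self) -> np.ndarray:
        return np.array([[self.X11, self.X12], [self.X21, self.X22]], dtype=np.int64)


@dataclass
class PermutationNullResult:
    observed_opposite: int
    null_counts: np.ndarray
    empirical_p: float
    N_up: int
    N_down: int
    seed: int


def _deg_directions(de: pd.DataFrame) -> dict[str, int]:
    """gene -> +1/-1 log2FC sign for the DEG rows of a result table."""
    degs = de[de["is_deg"]]
    return {g: (1 if fc > 0 else -1) for g, fc in zip(degs["gene"], degs["log2FC"])}


def _check_alignment(space_de: pd.DataFrame, buoe_de: pd.DataFrame) -> None:
    a, b = set(space_de["gene"]), set(buoe_de["gene"])
    if a != b:
        raise AlignmentError(
            f"gene universes differ (symmetric difference of {len(a ^ b)} genes)"
        )


def overlap_directions(space_de: pd.DataFrame, buoe_de: pd.DataFrame) -> OverlapCounts:
    """Partition the DEG-set intersection by fold-change sign agreement."""
    _check_alignment(space_de, buoe_de)
    space = _deg_directions(space_de)
    buoe = _deg_directions(buoe_de)
    shared = set(space) & set(buoe)
    n_opposite = sum(1 for g in shared if space[g] != buoe[g])
    return OverlapCounts(
        n_opposite=n_opposite,
        n_same=len(shared) - n_opposite,
        n_space_degs=len(space),
        n_buoe_degs=len(buoe),
    )


def build_contingency(overlap: OverlapCounts) -> ContingencyMatrix:
    """X11 = n_opposite, X12 = N - X11, X21 = n_same, X22 = N - X21."""
    N = overlap.N
    return ContingencyMatrix(
        X11=overlap.n_opposite,
        X12=N - overlap.n_opposite,
        X21=overlap.n_same,
        X22=N - overlap.n_same,
    )


def direction_independence_table(
    space_de: pd.DataFrame, buoe_de: pd.DataFrame
) -> np.ndarray:
    """Conventional 2x2 cross-tabulation of DEG directions among overlapping genes.

    Rows: spaceflight DEG up/down; columns: BuOE DEG up/down. Off-diagonal
    cells are the opposite-direction overlaps. Offered as the orthodox
    independence table next to the bespoke :func:`build_contingency` matrix.
    """
    _check_alignment(space_de, buoe_de)
    space = _deg_directions(space_de)
    buoe = _deg_directions(buoe_de)
    table = np.zeros((2, 2), dtype=np.int64)
    for g in set(space) & set(buoe):
        table[0 if space[g] > 0 else 1, 0 if buoe[g] > 0 else 1] += 1
    return table


def fisher_exact(m: ContingencyMatrix) -> float:
    """Two-sided Fisher's exact p for the contingency matrix.

    With margins fixed, sums hypergeometric probabilities of all tables no
    more probable than the observed one. Fills ``m.fisher_p`` as a side
    effect and returns the p-value.
    """
    table = m.as_array()
    if (table < 0).any():
        raise ValueError("contingency cells must be non-negative")
    if table.sum() == 0:
        warnings.warn("all-zero contingency matrix; p = 1", stacklevel=2)
        m.fisher_p = 1.0
        return 1.0
    _, p = stats.fisher_exact(table, alternative="two-sided")
    m.fisher_p = float(p)
    return m.fisher_p


def expected_null_opposite(
    n_space_up: int, n_space_down: int, n_up: int, n_down: int, universe_size: int
) -> float:
    """Closed-form mean opposite-direction overlap under gene shuffling:
    ``n_space_up * N_down / G + n_space_down * N_up / G``."""
    return n_space_up * n_down / universe_size + n_space_down * n_up / universe_size


def permutation_null(
    space_de: pd.DataFrame,
    buoe_de: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
) -> PermutationNullResult:
    """Gene-shuffling null for the opposite-direction overlap count.

    Every iteration preserves the real BuOE DEG direction counts N_up and
    N_down exactly; pseudo-DEG direction is assigned by block membership
    (top block of the shuffle = up, bottom block = down).
    """
    if B < 1:
        raise ConfigError("B must be >= 1")
    _check_alignment(space_de, buoe_de)
    genes = list(space_de["gene"])
    G = len(genes)

    space = _deg_directions(space_de)
    buoe = _deg_directions(buoe_de)
    n_up = sum(1 for s in buoe.values() if s > 0)
    n_down = len(buoe) - n_up
    if n_up + n_down > G:
        raise ConfigError("BuOE DEG count exceeds the gene universe")

    observed = sum(
        1 for g in set(space) & set(buoe) if space[g] != buoe[g]
    )

    space_up = np.zeros(G, dtype=bool)
    space_down = np.zeros(G, dtype=bool)
    index = {g: i for i, g in enumerate(genes)}
    for g, s in space.items():
        (space_up if s > 0 else space_down)[index[g]] = True

    rng = np.random.default_rng(seed)
    null_counts = np.empty(B, dtype=np.int64)
    for b in range(B):
        perm = rng.permutation(G)
        pseudo_up = perm[:n_up]
        pseudo_down = perm[G - n_down :] if n_down else perm[:0]
        null_counts[b] = space_down[pseudo_up].sum() + space_up[pseudo_down].sum()

    empirical_p = (1 + int((null_counts >= observed).sum())) / (1 + B)
    return PermutationNullResult(
        observed_opposite=observed,
        null_counts=null_counts,
        empirical_p=empirical_p,
        N_up=n_up,
        N_down=n_down,
        seed=seed,
    )


def attenuation_summary(
    region: str,
    space_de: pd.DataFrame,
    buoe_de: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """One-row summary per region: overlap counts, contingency cells, Fisher
    and permutation p-values."""
    overlap = overlap_directions(space_de, buoe_de)
    m = build_contingency(overlap)
    fisher_p = fisher_exact(m)
    null = permutation_null(space_de, buoe_de, B=B, seed=seed)
    return pd.DataFrame(
        [
            {
                "region": region,
                "n_space_degs": overlap.n_space_degs,
                "n_buoe_degs": overlap.n_buoe_degs,
                "n_opposite": overlap.n_opposite,
                "n_same": overlap.n_same,
                "N": overlap.N,
                "X11": m.X11,
                "X12": m.X12,
                "X21": m.X21,
                "X22": m.X22,
                "fisher_p": fisher_p,
                "perm_observed": null.observed_opposite,
                "perm_null_mean": float(null.null_counts.mean()),
                "perm_empirical_p": null.empirical_p,
            }
        ]
    )
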