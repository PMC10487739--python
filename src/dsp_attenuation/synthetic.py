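"""Synthetic GeoMx-like count data with known ground truth.

The generator emulates the study design the pipeline targets: four brain
regions (CA, DG, FCT, CT), a 2x2 group layout (ground control vs spaceflight,
saline vs BuOE antioxidant), and a few replicate AOIs per region x group.
Counts are negative-binomial with AOI-level log-normal size factors, so the
Q3 normalization stage has real work to do, and a planted set of
flight-responsive genes per region carries signed log2 effects. A
BuOE-by-flight interaction reverses a tunable fraction ``attenuation_alpha``
of each flight effect — the structure the attenuation statistics downstream
are built to detect.

Generative model, on the log2 scale, for gene ``g`` in region ``r`` and an AOI
of group ``(condition, treatment)``::

    m = b_g + [FLT] * delta_{g,r}
            - [FLT and BuOE] * alpha_g * delta_{g,r}
            + [GC and BuOE] * eps_g

with per-AOI mean ``mu = 2**m * s_a`` and counts ~ NB(mean mu, dispersion
theta), variance ``mu + mu**2 / theta``. ``s_a`` is log-normal, ``b_g``
uniform on ``baseline_log_mean_range``, and non-planted genes have
``delta = 0``. A single seeded RNG stream makes the whole dataset
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import AOIAnnotation, CountMatrix, REGIONS

__all__ = ["SimulationConfig", "GroundTruth", "simulate_dataset", "truth_summary"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic dataset; defaults are the reference study
    conditions (4 regions x 4 groups x 3 replicate AOIs)."""

    n_genes: int = 5000
    regions: tuple[str, ...] = REGIONS
    n_replicates: int = 3
    baseline_log_mean_range: tuple[float, float] = (3.0, 9.0)
    dispersion: float = 10.0
    size_factor_sd: float = 0.3
    n_flight_degs_per_region: int = 200
    flight_effect_size: float = 2.0
    attenuation_alpha: float = 0.5
    buoe_ground_effect: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be positive")
        bad = [r for r in self.regions if r not in REGIONS]
        if bad or not self.regions:
            raise ConfigError(f"regions must be a non-empty subset of {REGIONS}, got {self.regions}")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be positive")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be > 0")
        if self.size_factor_sd < 0:
            raise ConfigError("size_factor_sd must be >= 0")
        if not 0 <= self.n_flight_degs_per_region <= self.n_genes:
            raise ConfigError("n_flight_degs_per_region must be in [0, n_genes]")
        if self.flight_effect_size < 0:
            raise ConfigError("flight_effect_size must be >= 0")
        if not 0.0 <= self.attenuation_alpha <= 1.0:
            raise ConfigError("attenuation_alpha must be in [0, 1]")
        if self.buoe_ground_effect < 0:
            raise ConfigError("buoe_ground_effect must be >= 0")
        lo, hi = self.baseline_log_mean_range
        if not lo <= hi:
            raise ConfigError("baseline_log_mean_range must be (lo, hi) with lo <= hi")


@dataclass
class GroundTruth:
    """Simulator-emitted truth used by tests and acceptance experiments."""

    genes: list[str]
    regions: tuple[str, ...]
    baseline_log2: np.ndarray  # per-gene b_g
    flight_effects: dict[str, dict[str, float]]  # region -> gene -> signed delta
    alpha: dict[str, float]  # gene -> attenuation fraction (planted genes)
    ground_effects: dict[str, float]  # gene -> signed BuOE effect in GC animals
    size_factors: np.ndarray = None  # per-AOI true scale factors s_a

    def flight_deg_set(self, region: str) -> set[str]:
        return set(self.flight_effects[region])

    def mean_log2(self, gene: str, region: str, condition: str, treatment: str) -> float:
        """Model log2 mean (before size factors and sampling noise)."""
        g = self.genes.index(gene)
        m = float(self.baseline_log2[g])
        delta = self.flight_effects[region].get(gene, 0.0)
        if condition == "FLT":
            m += delta
            if treatment == "BuOE":
                m -= self.alpha.get(gene, 0.0) * delta
        elif treatment == "BuOE":
            m += self.ground_effects.get(gene, 0.0)
        return m


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[CountMatrix, list[AOIAnnotation], GroundTruth]:
    """Draw one synthetic dataset; fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    genes = [f"G{i:05d}" for i in range(G)]

    lo, hi = config.baseline_log_mean_range
    baseline = rng.uniform(lo, hi, size=G)

    # Planted flight DEGs per region: signs alternate along the sorted selection
    # (even index up, odd down) for a reproducible ~50/50 split.
    flight_effects: dict[str, dict[str, float]] = {}
    delta = np.zeros((len(config.regions), G))
    for ri, region in enumerate(config.regions):
        chosen = np.sort(rng.choice(G, size=config.n_flight_degs_per_region, replace=False))
        signs = np.where(np.arange(chosen.size) % 2 == 0, 1.0, -1.0)
        delta[ri, chosen] = signs * config.flight_effect_size
        flight_effects[region] = {genes[g]: float(delta[ri, g]) for g in chosen}

    planted_any = sorted({g for eff in flight_effects.values() for g in eff})
    alpha = {g: config.attenuation_alpha for g in planted_any}
    eps = np.zeros(G)
    ground_effects: dict[str, float] = {}
    if config.buoe_ground_effect > 0:
        for i, g in enumerate(planted_any):
            sign = 1.0 if i % 2 == 0 else -1.0
            ground_effects[g] = sign * config.buoe_ground_effect
            eps[genes.index(g)] = ground_effects[g]

    groups = [("GC", "SAL"), ("GC", "BuOE"), ("FLT", "SAL"), ("FLT", "BuOE")]
    aois: list[str] = []
    annotations: list[AOIAnnotation] = []
    mean_log2_cols: list[np.ndarray] = []
    for ri, region in enumerate(config.regions):
        for cond, trt in groups:
            for rep in range(1, config.n_replicates + 1):
                aoi_id = f"{region}_{cond}-{trt}_{rep:02d}"
                aois.append(aoi_id)
                annotations.append(
                    AOIAnnotation(
                        aoi_id=aoi_id,
                        region=region,
                        condition=cond,
                        treatment=trt,
                        replicate=rep,
                        mouse_id=f"{cond}-{trt}-m{rep}",
                    )
                )
                m = baseline.copy()
                if cond == "FLT":
                    m += delta[ri]
                    if trt == "BuOE":
                        m -= config.attenuation_alpha * delta[ri]
                elif trt == "BuOE":
                    m += eps
                mean_log2_cols.append(m)

    size_factors = np.exp(rng.normal(0.0, config.size_factor_sd, size=len(aois)))
    mu = np.power(2.0, np.column_stack(mean_log2_cols)) * size_factors[np.newaxis, :]
    p = config.dispersion / (config.dispersion + mu)
    counts = rng.negative_binomial(config.dispersion, p)

    matrix = CountMatrix(genes=genes, aois=aois, counts=counts)
    truth = GroundTruth(
        genes=genes,
        regions=tuple(config.regions),
        baseline_log2=baseline,
        flight_effects=flight_effects,
        alpha=alpha,
        ground_effects=ground_effects,
        size_factors=size_factors,
    )
    return matrix, annotations, truth


def truth_summary(truth: GroundTruth) -> pd.DataFrame:
    """Per-region counts of planted up/down DEGs, mean |effect| and mean alpha."""
    rows = []
    for region in truth.regions:
        effects = truth.flight_effects[region]
        ups = sum(1 for v in effects.values() if v > 0)
        downs = sum(1 for v in effects.values() if v < 0)
        mean_abs = float(np.mean([abs(v) for v in effects.values()])) if effects else 0.0
        mean_alpha = (
            float(np.mean([truth.alpha[g] for g in effects])) if effects else 0.0
        )
        rows.append(
            {
                "region": region,
                "n_up": ups,
                "n_down": downs,
                "n_total": len(effects),
                "mean_abs_log2_effect": mean_abs,
                "mean_alpha": mean_alpha,
            }
        )
    return pd.DataFrame(rows, columns=[
        "region", "n_up", "n_down", "n_total", "mean_abs_log2_effect", "mean_alpha"
    ])
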