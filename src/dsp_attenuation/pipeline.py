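"""End-to-end pipeline orchestration.

Runs the full analysis — simulate (or ingest) counts, Q3-normalize,
differential expression per region and contrast, attenuation statistics,
ANOVA-filtered PCA with centroid distances, and optional enrichment — from
one configuration and one seed, writing every intermediate and final table
plus a JSON manifest. Identical config + seed produces byte-identical
output trees.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .attenuation import attenuation_summary
from .diffexpr import (
    BUOE_CONTRAST,
    FLIGHT_CONTRAST,
    GROUND_BUOE_CONTRAST,
    LFC_THRESHOLD,
    Q_THRESHOLD,
    de_analysis,
)
from .errors import AlignmentError, ConfigError
from .io import (
    read_association_table,
    read_count_matrix,
    read_gmt,
    write_count_matrix,
    write_table,
)
from .normalization import q3_normalize
from .pca import anova_filter, centroid_distances, run_pca
from .enrichment import disease_hits, disease_summary, ora
from .synthetic import SimulationConfig, simulate_dataset, truth_summary

__all__ = ["PipelineConfig", "run_pipeline", "summarize_attenuation"]


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; see the CLI for the YAML mirror."""

    mode: str = "simulate"  # "simulate" | "files"
    simulation: SimulationConfig | None = None
    counts_path: str | None = None
    metadata_path: str | None = None
    gmt_path: str | None = None
    association_path: str | None = None
    n_perm: int = 1000
    q_threshold: float = Q_THRESHOLD
    lfc_threshold: float = LFC_THRESHOLD
    outdir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "files"):
            raise ConfigError(f"mode must be 'simulate' or 'files', got {self.mode!r}")
        if self.n_perm < 1:
            raise ConfigError("n_perm must be >= 1")
        if self.q_threshold <= 0 or self.lfc_threshold <= 0:
            raise ConfigError("thresholds must be positive")
        if self.mode == "files":
            for label, path in [("counts", self.counts_path), ("metadata", self.metadata_path)]:
                if path is None:
                    raise ConfigError(f"files mode needs a {label} path")
                if not Path(path).exists():
                    raise ConfigError(f"{label} file not found: {path}")
        else:
            if self.simulation is None:
                self.simulation = SimulationConfig(seed=self.seed)
        for label, path in [("gmt", self.gmt_path), ("associations", self.association_path)]:
            if path is not None and not Path(path).exists():
                raise ConfigError(f"{label} file not found: {path}")


def summarize_attenuation(
    space_de: pd.DataFrame, buoe_de: pd.DataFrame, gc_buoe_de: pd.DataFrame
) -> pd.DataFrame:
    """Per spaceflight-DEG juxtaposition of the three contrast fold changes.

    One row per spaceflight DEG: its flight, BuOE-in-flight and
    BuOE-in-ground log2 fold changes, an ``opposite`` flag (BuOE-in-flight
    change opposes the flight change, regardless of significance) and a
    ``flight_specific_buoe`` flag (the gene is a BuOE DEG during flight but
    not on the ground).
    """
    universes = [set(t["gene"]) for t in (space_de, buoe_de, gc_buoe_de)]
    if not (universes[0] == universes[1] == universes[2]):
        raise AlignmentError("the three DE tables cover different gene universes")
    buoe = buoe_de.set_index("gene")
    gc_buoe = gc_buoe_de.set_index("gene")
    rows = []
    for row in space_de[space_de["is_deg"]].itertuples():
        b = buoe.loc[row.gene]
        g = gc_buoe.loc[row.gene]
        rows.append(
            {
                "gene": row.gene,
                "log2FC_flight": row.log2FC,
                "log2FC_buoe_flight": b["log2FC"],
                "log2FC_buoe_ground": g["log2FC"],
                "opposite": bool(np.sign(b["log2FC"]) * np.sign(row.log2FC) < 0),
                "flight_specific_buoe": bool(b["is_deg"] and not g["is_deg"]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "log2FC_flight",
            "log2FC_buoe_flight",
            "log2FC_buoe_ground",
            "opposite",
            "flight_specific_buoe",
        ],
    )


def _stage_seeds(seed: int, n: int) -> list[int]:
    """Derive independent per-stage seeds reproducibly from the master seed."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute every stage and return the run manifest (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "mode": config.mode,
        "n_perm": config.n_perm,
        "outputs": {},
    }

    def record(name: str, path: Path, rows: int) -> None:
        manifest["outputs"][name] = {"path": path.name, "rows": int(rows)}

    timer = [time.perf_counter()]

    def log_stage(name: str) -> None:
        now = time.perf_counter()
        print(f"[{name}] done in {now - timer[0]:.2f}s", file=sys.stderr)
        timer[0] = now

    # --- ingest or simulate -------------------------------------------------
    if config.mode == "simulate":
        matrix, annotations, truth = simulate_dataset(config.simulation)
        write_count_matrix(
            matrix, annotations, outdir / "counts.tsv", outdir / "metadata.tsv"
        )
        record("counts", outdir / "counts.tsv", len(matrix.genes))
        record("metadata", outdir / "metadata.tsv", len(annotations))
        summary = truth_summary(truth)
        write_table(summary, outdir / "truth_summary.tsv")
        record("truth_summary", outdir / "truth_summary.tsv", len(summary))
    else:
        matrix, annotations = read_count_matrix(config.counts_path, config.metadata_path)

    regions = sorted({a.region for a in annotations})
    log_stage("ingest")

    # --- normalize ----------------------------------------------------------
    norm = q3_normalize(matrix)
    norm_df = norm.to_frame(log2=True).reset_index(names="gene")
    write_table(norm_df, outdir / "normalized_log2.tsv")
    record("normalized_log2", outdir / "normalized_log2.tsv", len(norm_df))
    factors = pd.DataFrame({"aoi_id": norm.aois, "q3_factor": norm.q3_factors})
    write_table(factors, outdir / "q3_factors.tsv")
    record("q3_factors", outdir / "q3_factors.tsv", len(factors))
    log_stage("normalize")

    # --- differential expression per region ---------------------------------
    seeds = _stage_seeds(config.seed, 3 * len(regions) + len(regions) + 2)
    seed_iter = iter(seeds)
    de_tables: dict[tuple[str, str], pd.DataFrame] = {}
    for region in regions:
        for tag, contrast in [
            ("flight", FLIGHT_CONTRAST(region)),
            ("buoe_flight", BUOE_CONTRAST(region)),
            ("buoe_ground", GROUND_BUOE_CONTRAST(region)),
        ]:
            table = de_analysis(
                norm, annotations, contrast, n_perm=config.n_perm, seed=next(seed_iter)
            )
            de_tables[(region, tag)] = table
            path = outdir / f"de_{tag}_{region}.tsv"
            write_table(table, path)
            record(f"de_{tag}_{region}", path, len(table))
    log_stage("differential-expression")

    # --- attenuation statistics ---------------------------------------------
    atten_rows = []
    for region in regions:
        atten_rows.append(
            attenuation_summary(
                region,
                de_tables[(region, "flight")],
                de_tables[(region, "buoe_flight")],
                B=config.n_perm,
                seed=next(seed_iter),
            )
        )
        gene_table = summarize_attenuation(
            de_tables[(region, "flight")],
            de_tables[(region, "buoe_flight")],
            de_tables[(region, "buoe_ground")],
        )
        path = outdir / f"attenuation_genes_{region}.tsv"
        write_table(gene_table, path)
        record(f"attenuation_genes_{region}", path, len(gene_table))
    atten = pd.concat(atten_rows, ignore_index=True)
    write_table(atten, outdir / "attenuation_summary.tsv")
    record("attenuation_summary", outdir / "attenuation_summary.tsv", len(atten))
    log_stage("attenuation")

    # --- ANOVA-filtered PCA and centroid distances --------------------------
    grouping = [f"{a.region}_{a.condition}-{a.treatment}" for a in annotations]
    anova = anova_filter(norm, grouping)
    write_table(anova, outdir / "anova_qvalues.tsv")
    record("anova_qvalues", outdir / "anova_qvalues.tsv", len(anova))
    kept = set(anova.loc[anova["q_value"] < config.q_threshold, "gene"])
    if kept:
        pca = run_pca(norm, annotations, kept, average_replicates=True)
        coords = pca.to_frame()
        write_table(coords, outdir / "pca_coordinates.tsv")
        record("pca_coordinates", outdir / "pca_coordinates.tsv", len(coords))
        distances = centroid_distances(pca)
        write_table(distances, outdir / "distance_report.tsv")
        record("distance_report", outdir / "distance_report.tsv", len(distances))

    log_stage("pca-distances")

    # --- enrichment (optional inputs) ----------------------------------------
    if config.gmt_path:
        sets = read_gmt(config.gmt_path)
        universe = set(matrix.genes)
        for region in regions:
            degs = set(
                de_tables[(region, "flight")].loc[
                    de_tables[(region, "flight")]["is_deg"], "gene"
                ]
            )
            if not degs:
                continue
            table = ora(degs, sets, universe)
            path = outdir / f"enrichment_flight_{region}.tsv"
            write_table(table, path)
            record(f"enrichment_flight_{region}", path, len(table))
    if config.association_path:
        assoc = read_association_table(config.association_path)
        all_degs = sorted(
            {
                g
                for region in regions
                for g in de_tables[(region, "flight")].loc[
                    de_tables[(region, "flight")]["is_deg"], "gene"
                ]
            }
        )
        hits = disease_hits(all_degs, assoc)
        write_table(hits, outdir / "disease_hits.tsv")
        record("disease_hits", outdir / "disease_hits.tsv", len(hits))
        summary = disease_summary(hits)
        write_table(summary, outdir / "disease_summary.tsv")
        record("disease_summary", outdir / "disease_summary.tsv", len(summary))

    with open(outdir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return manifest
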