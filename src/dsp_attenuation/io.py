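"""Shared data model and readers/writers for the pipeline's external formats.

The raw input is a gene x AOI (area of illumination) matrix of deduplicated
digital counts, as produced by GeoMx-style digital spatial profiling, plus a
metadata table annotating each AOI with its brain region (CA, DG, FCT, CT),
condition (GC = ground control, FLT = spaceflight), treatment (SAL = saline,
BuOE = the SOD-mimic antioxidant MnTnBuOE-2-PyP5+) and replicate. Gene-set
collections come in as GMT files and gene-disease associations as two-column
TSVs.

Counts are validated as non-negative integers on input; normalized values
live in a distinct type (:class:`~dsp_attenuation.normalization.NormalizedMatrix`)
and are never written back into a :class:`CountMatrix`, which prevents silent
double-normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, LinkageError

REGIONS = ("CA", "DG", "FCT", "CT")
CONDITIONS = ("GC", "FLT")
TREATMENTS = ("SAL", "BuOE")

#: Fixed float format for every table the pipeline writes; scientific with six
#: significant digits so reruns under the same seed are byte-identical.
FLOAT_FORMAT = "%.5e"

METADATA_COLUMNS = ["aoi_id", "region", "condition", "treatment", "replicate", "mouse_id"]


@dataclass(frozen=True)
class AOIAnnotation:
    """Annotation of one area of illumination (AOI)."""

    aoi_id: str
    region: str
    condition: str
    treatment: str
    replicate: int
    mouse_id: str

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise FormatError(f"unknown region {self.region!r} for AOI {self.aoi_id!r}")
        if self.condition not in CONDITIONS:
            raise FormatError(f"unknown condition {self.condition!r} for AOI {self.aoi_id!r}")
        if self.treatment not in TREATMENTS:
            raise FormatError(f"unknown treatment {self.treatment!r} for AOI {self.aoi_id!r}")
        if int(self.replicate) < 1:
            raise FormatError(f"replicate must be a positive integer for AOI {self.aoi_id!r}")

    @property
    def group(self) -> str:
        """Experimental group label, e.g. ``'FLT-SAL'``."""
        return f"{self.condition}-{self.treatment}"


@dataclass
class CountMatrix:
    """Gene x AOI matrix of non-negative integer digital counts."""

    genes: list[str]
    aois: list[str]
    counts: np.ndarray  # shape (len(genes), len(aois)), integer dtype

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self.aois = list(self.aois)
        self.counts = np.asarray(self.counts)
        dup = _first_duplicate(self.genes)
        if dup is not None:
            raise FormatError(f"duplicate gene symbol {dup!r}")
        dup = _first_duplicate(self.aois)
        if dup is not None:
            raise FormatError(f"duplicate AOI id {dup!r}")
        if self.counts.shape != (len(self.genes), len(self.aois)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"({len(self.genes)} genes, {len(self.aois)} AOIs)"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            frac, _ = np.modf(self.counts.astype(float))
            bad = np.argwhere(frac != 0)
            if bad.size:
                g, a = bad[0]
                raise FormatError(
                    f"non-integer count at gene {self.genes[g]!r}, AOI {self.aois[a]!r}"
                )
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            g, a = np.argwhere(self.counts < 0)[0]
            raise FormatError(
                f"negative count at gene {self.genes[g]!r}, AOI {self.aois[a]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.genes, columns=self.aois)


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. pathways) with free-text provenance."""

    sets: dict[str, set[str]]
    source: str = ""
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class AssociationTable:
    """Unique (gene symbol, disease name) association pairs.

    Matching against mouse gene lists is case-insensitive because the source
    resources catalogue human symbols (upper case) while mouse symbols are
    capitalized.
    """

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        unique: list[tuple[str, str]] = []
        for gene, disease in self.rows:
            key = (gene.upper(), disease.upper())
            if key not in seen:
                seen.add(key)
                unique.append((gene, disease))
        self.rows = unique


def _first_duplicate(items: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for item in items:
        if item in seen:
            return item
        seen.add(item)
    return None


def read_count_matrix(
    path: str | Path, metadata_path: str | Path
) -> tuple[CountMatrix, list[AOIAnnotation]]:
    """Read a counts TSV (genes x AOIs) and its AOI metadata TSV.

    The counts file has a header row of AOI ids and gene symbols in the first
    column; the metadata file has the six named columns in
    :data:`METADATA_COLUMNS`. Raises :class:`FormatError` on duplicates or
    invalid counts and :class:`LinkageError` when an AOI in the matrix has no
    metadata row.
    """
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")[1:]
    dup = _first_duplicate(header)
    if dup is not None:
        raise FormatError(f"duplicate AOI id {dup!r} in header of {path}")
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    genes = [str(g) for g in df.index]
    aois = [str(a) for a in df.columns]
    try:
        counts = df.to_numpy(dtype=np.float64)
    except ValueError as exc:
        raise FormatError(f"non-numeric count in {path}: {exc}") from exc
    matrix = CountMatrix(genes, aois, counts)

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise FormatError(f"metadata file {metadata_path} missing columns {missing_cols}")
    annotations = {
        row.aoi_id: AOIAnnotation(
            aoi_id=row.aoi_id,
            region=row.region,
            condition=row.condition,
            treatment=row.treatment,
            replicate=int(row.replicate),
            mouse_id=row.mouse_id,
        )
        for row in meta.itertuples()
    }
    if len(annotations) != len(meta):
        raise LinkageError(f"duplicate aoi_id rows in metadata file {metadata_path}")
    orphans = [a for a in matrix.aois if a not in annotations]
    if orphans:
        raise LinkageError(f"AOIs present in counts but missing from metadata: {orphans}")
    keys = [
        (annotations[a].region, annotations[a].condition, annotations[a].treatment,
         annotations[a].replicate)
        for a in matrix.aois
    ]
    dup_key = _first_duplicate([str(k) for k in keys])
    if dup_key is not None:
        raise LinkageError(f"duplicate (region, condition, treatment, replicate) tuple {dup_key}")
    return matrix, [annotations[a] for a in matrix.aois]


def write_count_matrix(
    matrix: CountMatrix,
    annotations: Iterable[AOIAnnotation],
    path: str | Path,
    metadata_path: str | Path,
) -> None:
    """Write counts + metadata TSVs; the inverse of :func:`read_count_matrix`."""
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene", lineterminator="\n")
    rows = [
        [a.aoi_id, a.region, a.condition, a.treatment, a.replicate, a.mouse_id]
        for a in annotations
    ]
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(
        metadata_path, sep="\t", index=False, lineterminator="\n"
    )


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>members...``."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, description, *members = fields
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            sets[name] = set(members)
            descriptions[name] = description
    return GeneSetCollection(sets=sets, source=str(path), descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as handle:
        for name in collection.sets:
            desc = collection.descriptions.get(name, "")
            members = sorted(collection.sets[name])
            handle.write("\t".join([name, desc, *members]) + "\n")


def read_association_table(path: str | Path) -> AssociationTable:
    """Read a two-column (gene, disease) TSV with a header row."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"association table {path} needs at least 2 columns")
    rows = [(str(g), str(d)) for g, d in zip(df.iloc[:, 0], df.iloc[:, 1])]
    return AssociationTable(rows=rows)


def write_association_table(table: AssociationTable, path: str | Path) -> None:
    pd.DataFrame(table.rows, columns=["gene", "disease"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def write_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV with deterministic formatting.

    Column order is taken from the frame; floats use :data:`FLOAT_FORMAT` so
    that identical results serialize to byte-identical files.
    """
    rows.to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FORMAT, lineterminator="\n"
    )
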