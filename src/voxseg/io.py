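"""Readers for platform transcript tables and writers for downstream formats.

Input: delimited or parquet transcript tables in the column dialects of
10X Xenium, Vizgen MERSCOPE and NanoString CosMx (plus a plain "generic"
dialect). Output: a MatrixMarket cell-by-gene count matrix with sidecar
gene/cell lists, a cell-metadata CSV, cell boundary polygons as GeoJSON,
and a per-transcript CSV with observed and inferred positions.
"""

from __future__ import annotations

import fnmatch
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


@dataclass
class TranscriptTable:
    """In-memory transcript set: genes, observed and inferred positions
    (μm), and the optional per-transcript nuclear cell label (-1 = none)."""

    gene: np.ndarray  # (M,) int32 indices into gene_names
    gene_names: list[str]
    observed: np.ndarray  # (M, 3) μm
    inferred: np.ndarray  # (M, 3) μm, starts equal to observed
    nuclear: np.ndarray  # (M,) int64 original nuclear label ids, -1 = none
    quality: np.ndarray | None = None

    def __post_init__(self):
        if not np.all(np.isfinite(self.observed)):
            raise ValueError("non-finite transcript coordinates")

    @property
    def M(self) -> int:
        return len(self.gene)

    @property
    def m(self) -> int:
        return len(self.gene_names)


@dataclass
class DialectSpec:
    """Column-name map and conventions for one platform's transcript table."""

    name: str
    gene_col: str
    x_col: str
    y_col: str
    z_col: str | None = None
    cell_col: str | None = None
    nucleus_flag_col: str | None = None  # truthy value marks nuclear transcripts
    quality_col: str | None = None
    unassigned_values: tuple = (-1, "-1", "UNASSIGNED", 0, "0", "")
    scale: float = 1.0  # multiply x/y/z by this to get μm
    negative_patterns: tuple = ()


DIALECTS: dict[str, DialectSpec] = {
    "generic": DialectSpec(
        name="generic",
        gene_col="gene",
        x_col="x",
        y_col="y",
        z_col="z",
        cell_col="nucleus",
        quality_col="quality",
        unassigned_values=(-1, "-1", ""),
        negative_patterns=("NegControl*", "BLANK*"),
    ),
    "xenium": DialectSpec(
        name="xenium",
        gene_col="feature_name",
        x_col="x_location",
        y_col="y_location",
        z_col="z_location",
        cell_col="cell_id",
        nucleus_flag_col="overlaps_nucleus",
        quality_col="qv",
        unassigned_values=(-1, "-1", "UNASSIGNED"),
        negative_patterns=(
            "NegControl*",
            "BLANK*",
            "UnassignedCodeword*",
            "DeprecatedCodeword*",
        ),
    ),
    "merscope": DialectSpec(
        name="merscope",
        gene_col="gene",
        x_col="global_x",
        y_col="global_y",
        z_col="global_z",
        cell_col="cell_id",
        unassigned_values=(-1, "-1", ""),
        negative_patterns=("Blank-*",),
    ),
    "cosmx": DialectSpec(
        name="cosmx",
        gene_col="target",
        x_col="x_global_px",
        y_col="y_global_px",
        z_col="z",
        cell_col="cell_ID",
        nucleus_flag_col="CellComp",
        unassigned_values=(0, "0", ""),
        scale=0.12028,  # μm per pixel on current instruments; override if needed
        negative_patterns=("NegPrb*", "Negative*", "SystemControl*"),
    ),
}


def read_transcripts(
    path,
    dialect: str | DialectSpec = "generic",
    quality_threshold: float | None = None,
    scale: float | None = None,
) -> TranscriptTable:
    """Read a transcript table, map columns per dialect, drop negative
    controls and (optionally) low-quality rows, and build the gene
    vocabulary. Missing z is filled with 0; coordinates are converted to
    μm using the dialect's scale factor."""
    spec = DIALECTS[dialect] if isinstance(dialect, str) else dialect
    path = Path(path)
    if path.suffix == ".parquet":
        df = pd.read_parquet(path)
    else:
        sep = "\t" if path.suffix in (".tsv", ".txt") else ","
        df = pd.read_csv(path, sep=sep)
    for col in (spec.gene_col, spec.x_col, spec.y_col):
        if col not in df.columns:
            raise ValueError(f"dialect {spec.name!r}: missing column {col!r}")

    genes = df[spec.gene_col].astype(str)
    drop = np.zeros(len(df), dtype=bool)
    for pat in spec.negative_patterns:
        drop |= np.array([fnmatch.fnmatch(g, pat) for g in genes])
    if quality_threshold is not None and spec.quality_col in df.columns:
        drop |= df[spec.quality_col].to_numpy() < quality_threshold
    df = df.loc[~drop]
    genes = genes.loc[~drop]

    s = spec.scale if scale is None else scale
    x = df[spec.x_col].to_numpy(float) * s
    y = df[spec.y_col].to_numpy(float) * s
    if spec.z_col is not None and spec.z_col in df.columns:
        z = df[spec.z_col].to_numpy(float) * s
    else:
        z = np.zeros(len(df))
    pos = np.column_stack([x, y, z])

    nuclear = np.full(len(df), -1, dtype=np.int64)
    if spec.cell_col is not None and spec.cell_col in df.columns:
        raw = df[spec.cell_col]
        assigned = ~raw.isin(spec.unassigned_values).to_numpy() & raw.notna().to_numpy()
        if spec.nucleus_flag_col is not None and spec.nucleus_flag_col in df.columns:
            flag = df[spec.nucleus_flag_col]
            if flag.dtype == object:
                assigned &= (flag == "Nuclear").to_numpy()
            else:
                assigned &= flag.to_numpy().astype(bool)
        codes, _ = pd.factorize(raw.astype(str))
        nuclear[assigned] = codes[assigned]

    vocab = sorted(genes.unique())
    lookup = {g: i for i, g in enumerate(vocab)}
    gidx = np.array([lookup[g] for g in genes], dtype=np.int32)
    qual = None
    if spec.quality_col is not None and spec.quality_col in df.columns:
        qual = df[spec.quality_col].to_numpy(float)
    return TranscriptTable(
        gene=gidx,
        gene_names=list(vocab),
        observed=pos,
        inferred=pos.copy(),
        nuclear=nuclear,
        quality=qual,
    )


def write_transcripts(table: TranscriptTable, path) -> None:
    """Write a table in the generic dialect (used by `simulate` and for
    round-tripping)."""
    df = pd.DataFrame(
        {
            "gene": [table.gene_names[g] for g in table.gene],
            "x": table.observed[:, 0],
            "y": table.observed[:, 1],
            "z": table.observed[:, 2],
            "nucleus": table.nuclear,
        }
    )
    if table.quality is not None:
        df["quality"] = table.quality
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# result writers


def write_count_matrix(result, outdir) -> None:
    """MatrixMarket counts (genes as rows, cells as columns — the common
    single-cell convention) plus gene and cell sidecar lists."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = sparse.coo_matrix(result.counts.X)
    spio.mmwrite(outdir / "counts.mtx", X, comment="rows: genes, cols: cells")
    (outdir / "genes.txt").write_text("".join(f"{g}\n" for g in result.gene_names))
    (outdir / "cells.txt").write_text("".join(f"cell-{c}\n" for c in result.cell_ids))


def write_cell_outputs(result, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.cell_meta.to_csv(outdir / "cell_metadata.csv", index=False)

    features = []
    for (cell_id, z), rings in sorted(result.polygons.items()):
        for ring in rings:
            coords = np.asarray(ring)
            if not np.array_equal(coords[0], coords[-1]):
                coords = np.vstack([coords, coords[:1]])
            features.append(
                {
                    "type": "Feature",
                    "properties": {"cell": int(cell_id), "z_layer": int(z)},
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [coords.tolist()],
                    },
                }
            )
    geo = {"type": "FeatureCollection", "features": features}
    (outdir / "cell_boundaries.geojson").write_text(json.dumps(geo))

    df = pd.DataFrame(
        {
            "gene": [result.gene_names[g] for g in result.gene],
            "observed_x": result.observed_positions[:, 0],
            "observed_y": result.observed_positions[:, 1],
            "observed_z": result.observed_positions[:, 2],
            "inferred_x": result.inferred_positions[:, 0],
            "inferred_y": result.inferred_positions[:, 1],
            "inferred_z": result.inferred_positions[:, 2],
            "cell": result.assignment,
            "status": result.status,
        }
    )
    df.to_csv(outdir / "transcripts.csv", index=False)


def write_voxel_raster(lattice, path) -> None:
    """Debug export: per-voxel (x, y, z, cell) table in μm voxel centers."""
    idx = np.argwhere(np.ones(lattice.dims, dtype=bool))
    centers = lattice.origin + (idx + 0.5) * lattice.voxel_size
    pd.DataFrame(
        {
            "x": centers[:, 0],
            "y": centers[:, 1],
            "z": centers[:, 2],
            "cell": lattice.state.reshape(-1),
        }
    ).to_csv(path, index=False)
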