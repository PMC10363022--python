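"""Readers for the two supported input dialects and writers for result tables.

Supported inputs:

* a SpaceRanger-style directory: MatrixMarket triplet matrix with
  barcodes/features companion files (gzipped or plain) plus a tissue
  positions CSV keyed by barcode;
* a CSV pair: raw count matrix (spots × genes) and a metadata CSV with
  columns literally named ``x`` and ``y``.

Identifier matching is always by key join, never by file order.
"""

from __future__ import annotations

import gzip
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .dataset import SpatialDataset

log = logging.getLogger(__name__)

__all__ = ["load_visium", "load_csv", "write_association_table"]

_ROW_SPACING = math.sqrt(3.0) / 2.0


def _find_companion(directory: Path, stems: list[str]) -> Path:
    """Locate a file by any stem, allowing a .gz variant, searching one level deep."""
    for stem in stems:
        for suffix in ("", ".gz"):
            hits = sorted(directory.glob(f"**/{stem}{suffix}"))
            if hits:
                return hits[0]
    raise FileNotFoundError(
        f"missing companion file: none of {stems} found under {directory}"
    )


def _read_lines(path: Path) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def _read_positions(path: Path) -> pd.DataFrame:
    cols = ["barcode", "in_tissue", "array_row", "array_col", "pixel_row", "pixel_col"]
    head = pd.read_csv(path, nrows=1, header=None)
    has_header = isinstance(head.iloc[0, 1], str)  # old-style lists have no header
    df = pd.read_csv(path, header=0 if has_header else None)
    df.columns = cols[: df.shape[1]]
    return df.set_index("barcode")


def load_visium(path) -> SpatialDataset:
    """Load a SpaceRanger output directory, restricted to in-tissue spots.

    The matrix is transposed to spots × genes. Spot coordinates are derived
    from the array indices of the positions file using hexagonal geometry
    (``x = array_col / 2``, ``y = array_row * sqrt(3)/2``), which places the
    six immediate lattice neighbors of an interior spot at equal Euclidean
    distance; pixel coordinates are kept in ``spot_meta`` for plotting.
    """
    directory = Path(path)
    mtx_path = _find_companion(directory, ["matrix.mtx"])
    barcodes_path = _find_companion(directory, ["barcodes.tsv"])
    features_path = _find_companion(directory, ["features.tsv", "genes.tsv"])
    positions_path = _find_companion(
        directory, ["tissue_positions.csv", "tissue_positions_list.csv"]
    )

    matrix = sp.csr_matrix(scipy.io.mmread(str(mtx_path)).T)  # -> spots x genes
    barcodes = [line.split("\t")[0] for line in _read_lines(barcodes_path)]
    feature_rows = [line.split("\t") for line in _read_lines(features_path)]
    gene_ids = [row[1] if len(row) > 1 else row[0] for row in feature_rows]
    gene_ids = _deduplicate(gene_ids)

    if matrix.shape != (len(barcodes), len(gene_ids)):
        raise ValueError(
            f"matrix shape {matrix.shape} does not match "
            f"{len(barcodes)} barcodes x {len(gene_ids)} features"
        )

    positions = _read_positions(positions_path)
    unmatched = [b for b in barcodes if b not in positions.index]
    if unmatched:
        raise ValueError(
            f"{len(unmatched)} barcode(s) in matrix absent from positions file "
            f"(first: {unmatched[:5]})"
        )

    positions = positions.loc[barcodes]  # key join, matrix barcode order
    in_tissue = positions["in_tissue"].to_numpy().astype(int) == 1
    matrix = matrix[in_tissue]
    positions = positions.loc[in_tissue]
    kept = [b for b, keep in zip(barcodes, in_tissue) if keep]

    coords = np.column_stack(
        [
            positions["array_col"].to_numpy(float) / 2.0,
            positions["array_row"].to_numpy(float) * _ROW_SPACING,
        ]
    )
    spot_meta = positions.copy()
    spot_meta.index.name = "spot_id"
    log.info(
        "loaded %d in-tissue spots (%d total barcodes), %d genes from %s",
        in_tissue.sum(), len(barcodes), len(gene_ids), directory,
    )
    return SpatialDataset(
        counts=matrix,
        coords=coords,
        gene_ids=gene_ids,
        spot_ids=kept,
        spot_meta=spot_meta,
    )


def _deduplicate(names: list[str]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for name in names:
        if name in seen:
            seen[name] += 1
            out.append(f"{name}.{seen[name]}")
        else:
            seen[name] = 0
            out.append(name)
    return out


def load_csv(counts_path, meta_path, transpose: bool = False) -> SpatialDataset:
    """Load a CSV count matrix plus a metadata CSV with ``x``/``y`` columns.

    Counts default to spots as rows and genes as columns; pass
    ``transpose=True`` for the other orientation. Rows of the two files are
    matched by identifier (first column), not position.
    """
    counts = pd.read_csv(counts_path, index_col=0)
    if transpose:
        counts = counts.T
    meta = pd.read_csv(meta_path, index_col=0)
    missing_cols = [c for c in ("x", "y") if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"missing coordinate column(s) in metadata: {missing_cols}")

    counts.index = counts.index.astype(str)
    meta.index = meta.index.astype(str)
    only_counts = counts.index.difference(meta.index)
    only_meta = meta.index.difference(counts.index)
    if len(only_counts) or len(only_meta):
        raise ValueError(
            "row-key mismatch between counts and metadata: "
            f"{len(only_counts)} spot(s) only in counts, "
            f"{len(only_meta)} only in metadata"
        )
    meta = meta.loc[counts.index]

    values = counts.to_numpy()
    if not np.all(values == np.round(values)):
        raise ValueError("counts matrix contains non-integer entries (not raw counts)")

    return SpatialDataset(
        counts=values.astype(np.int64),
        coords=meta[["x", "y"]].to_numpy(float),
        gene_ids=list(counts.columns.astype(str)),
        spot_ids=list(counts.index),
        spot_meta=meta,
    )


def write_association_table(result, path) -> None:
    """Write per-pair global L / p / q as CSV, sorted by (q, pair_a, pair_b)."""
    df = result.to_frame()
    df = df.sort_values(["q_value", "pair_a", "pair_b"], kind="mergesort")
    df.to_csv(path, index=False, columns=["pair_a", "pair_b", "global_L", "p_value", "q_value"])
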