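"""Core in-memory containers for spot-resolved expression data.

A :class:`SpatialDataset` holds a spots × genes raw count matrix together
with per-spot 2-D coordinates and per-spot / per-gene metadata tables. It is
the carrier object passed through every analysis stage; derived matrices
(log-CPM, cell-type scores, module scores) live in named ``layers`` so the
raw counts are never overwritten.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["SpatialDataset", "MarkerDictionary"]


def _is_integral(values: np.ndarray) -> bool:
    if np.issubdtype(values.dtype, np.integer):
        return True
    finite = values[np.isfinite(values)] if values.dtype.kind == "f" else values
    return bool(np.all(finite == np.round(finite)))


class SpatialDataset:
    """Spot × gene count matrix with aligned spatial coordinates.

    Parameters
    ----------
    counts
        Non-negative integer matrix, shape (n_spots, n_genes). Dense
        ndarray or any scipy sparse matrix (stored as CSR).
    coords
        Real (x, y) coordinates per spot, shape (n_spots, 2). Units are
        arbitrary but must be consistent (the neighbor graph is Euclidean).
    gene_ids, spot_ids
        Unique string identifiers.
    layers
        Named real matrices aligned to (n_spots, n_genes) or, for score
        layers such as ``"group_scores"``, (n_spots, n_columns) with column
        names tracked in ``uns``.
    gene_meta, spot_meta
        Per-gene / per-spot annotation tables (indexed by the ids).
    uns
        Unstructured metadata (layer column names, provenance, warnings).
    """

    def __init__(
        self,
        counts,
        coords,
        gene_ids,
        spot_ids,
        layers: dict[str, np.ndarray] | None = None,
        gene_meta: pd.DataFrame | None = None,
        spot_meta: pd.DataFrame | None = None,
        uns: dict | None = None,
        validate: bool = True,
    ):
        if sp.issparse(counts):
            counts = sp.csr_matrix(counts)
        else:
            counts = np.asarray(counts)
        self.counts = counts
        self.coords = np.asarray(coords, dtype=float)
        self.gene_ids = np.asarray(gene_ids, dtype=object)
        self.spot_ids = np.asarray(spot_ids, dtype=object)
        self.layers: dict[str, np.ndarray] = dict(layers or {})
        self.gene_meta = (
            gene_meta
            if gene_meta is not None
            else pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id"))
        )
        self.spot_meta = (
            spot_meta
            if spot_meta is not None
            else pd.DataFrame(index=pd.Index(self.spot_ids, name="spot_id"))
        )
        self.uns: dict = dict(uns or {})
        if validate:
            self.validate()

    # ------------------------------------------------------------------
    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def validate(self) -> None:
        n, g = self.counts.shape
        if self.coords.shape != (n, 2):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match {n} spots"
            )
        if len(self.spot_ids) != n or len(self.gene_ids) != g:
            raise ValueError("spot_ids/gene_ids lengths do not match counts shape")
        if len(set(self.spot_ids)) != n:
            raise ValueError("duplicate spot_ids")
        if len(set(self.gene_ids)) != g:
            raise ValueError("duplicate gene_ids")
        data = self.counts.data if sp.issparse(self.counts) else self.counts
        data = np.asarray(data)
        if data.size:
            if data.min() < 0:
                raise ValueError("counts contain negative entries")
            if not _is_integral(data):
                raise ValueError("counts contain non-integer entries (not raw counts)")
        for name, layer in self.layers.items():
            if layer.shape[0] != n:
                raise ValueError(f"layer {name!r} has {layer.shape[0]} rows, expected {n}")
        if len(self.gene_meta) != g or len(self.spot_meta) != n:
            raise ValueError("metadata tables do not match counts shape")

    # ------------------------------------------------------------------
    def counts_dense(self) -> np.ndarray:
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense())
        return np.asarray(self.counts)

    def gene_index(self, names) -> np.ndarray:
        """Positions of ``names`` in gene_ids; raises on unknown genes."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [n for n in names if n not in lookup]
        if missing:
            raise KeyError(f"genes not in dataset: {missing[:10]}")
        return np.array([lookup[n] for n in names], dtype=int)

    def subset(self, spot_mask=None, gene_mask=None) -> "SpatialDataset":
        """Return a new dataset restricted to the given boolean masks."""
        spot_mask = (
            np.ones(self.n_spots, bool) if spot_mask is None else np.asarray(spot_mask)
        )
        gene_mask = (
            np.ones(self.n_genes, bool) if gene_mask is None else np.asarray(gene_mask)
        )
        counts = self.counts[spot_mask][:, gene_mask]
        layers = {
            k: (v[spot_mask][:, gene_mask] if v.shape[1] == self.n_genes else v[spot_mask])
            for k, v in self.layers.items()
        }
        return SpatialDataset(
            counts=counts,
            coords=self.coords[spot_mask],
            gene_ids=self.gene_ids[gene_mask],
            spot_ids=self.spot_ids[spot_mask],
            layers=layers,
            gene_meta=self.gene_meta.loc[gene_mask].copy(),
            spot_meta=self.spot_meta.loc[spot_mask].copy(),
            uns=dict(self.uns),
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"SpatialDataset({self.n_spots} spots x {self.n_genes} genes, "
            f"layers={sorted(self.layers)})"
        )


@dataclass
class MarkerDictionary:
    """Named cell types mapped to ordered marker gene lists."""

    mapping: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.mapping.items():
            if not genes:
                raise ValueError(f"marker list for {name!r} is empty")
        if len(set(self.mapping)) != len(self.mapping):  # pragma: no cover
            raise ValueError("duplicate cell-type names")

    @property
    def cell_types(self) -> list[str]:
        return list(self.mapping)

    @classmethod
    def from_json(cls, path) -> "MarkerDictionary":
        with open(path) as fh:
            return cls(dict(json.load(fh)))

    @classmethod
    def from_csv(cls, path) -> "MarkerDictionary":
        """Two-column CSV: cell_type, gene (one marker per row)."""
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ValueError("marker CSV needs two columns (cell_type, gene)")
        ct_col, gene_col = df.columns[:2]
        mapping: dict[str, list[str]] = {}
        for ct, sub in df.groupby(ct_col, sort=False):
            mapping[str(ct)] = [str(g) for g in sub[gene_col]]
        return cls(mapping)
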