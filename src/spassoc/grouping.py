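"""Cell-type scores from marker gene sets, feeding cell-type colocalization.

Marker lists are collapsed into one per-spot score per cell type — by
default the mean of the z-scored log-CPM of the markers present in the
dataset — so the L-index machinery can measure colocalization or exclusion
of cell types exactly as it does for gene pairs. Z-scoring before
averaging prevents a single highly expressed marker from dominating the
signature; plain mean and sum are available as alternatives.

A small fallback dictionary of canonical human immune markers (B cells,
T cells, Macrophages, Neutrophils, NK) ships with the package as an
editable JSON config; users studying other tissues should supply their own
dictionary.
"""

from __future__ import annotations

import logging
from importlib import resources

import numpy as np

from .dataset import MarkerDictionary, SpatialDataset
from .lindex import AssociationResult, pairwise_association
from .weights import SpatialWeights

log = logging.getLogger(__name__)

__all__ = ["default_immune_markers", "group_scores", "celltype_association", "aggregate_scores"]


def default_immune_markers() -> MarkerDictionary:
    """The bundled fallback immune marker dictionary."""
    ref = resources.files("spassoc.data") / "immune_markers_default.json"
    with resources.as_file(ref) as path:
        return MarkerDictionary.from_json(path)


def aggregate_scores(
    ds: SpatialDataset, gene_lists: dict[str, list[str]], method: str = "zmean"
) -> tuple[np.ndarray, dict]:
    """Collapse each gene list to one per-spot score column.

    ``method``: ``"zmean"`` (mean of z-scored log-CPM, default), ``"mean"``
    or ``"sum"`` of raw log-CPM. Genes absent from the dataset are dropped
    with a warning; a list with no present genes is an error. Returns the
    score matrix (spots × lists) and a presence report per list.
    """
    if "logcpm" not in ds.layers:
        raise ValueError("logcpm layer missing: run normalize_logcpm first")
    if method not in ("zmean", "mean", "sum"):
        raise ValueError(f"unknown aggregation method {method!r}")
    gene_set = set(ds.gene_ids)
    report: dict[str, dict] = {}
    columns = []

    seen: dict[str, str] = {}
    for name, genes in gene_lists.items():
        present = [g for g in dict.fromkeys(genes) if g in gene_set]
        absent = [g for g in genes if g not in gene_set]
        if not present:
            raise ValueError(f"cell type {name!r} has no markers present in the dataset")
        if absent:
            log.warning("%s: %d marker(s) absent from dataset: %s", name, len(absent), absent)
        for g in present:
            if g in seen and seen[g] != name:
                log.warning("marker %s shared by %s and %s", g, seen[g], name)
            seen.setdefault(g, name)
        report[name] = {"present": present, "absent": absent}

        expr = ds.layers["logcpm"][:, ds.gene_index(present)]
        if method == "zmean":
            sd = expr.std(axis=0)
            zero_var = sd == 0
            if zero_var.any():
                log.warning(
                    "%s: %d constant marker(s) contribute zero", name, int(zero_var.sum())
                )
            sd = np.where(zero_var, 1.0, sd)
            z = (expr - expr.mean(axis=0)) / sd
            z[:, zero_var] = 0.0
            columns.append(z.mean(axis=1))
        elif method == "mean":
            columns.append(expr.mean(axis=1))
        else:
            columns.append(expr.sum(axis=1))
    return np.column_stack(columns), report


def group_scores(
    ds: SpatialDataset, markers: MarkerDictionary | None = None, method: str = "zmean"
) -> SpatialDataset:
    """Add a ``"group_scores"`` layer with one column per cell type."""
    markers = markers if markers is not None else default_immune_markers()
    scores, report = aggregate_scores(ds, markers.mapping, method=method)
    ds.layers["group_scores"] = scores
    ds.uns["group_names"] = list(markers.mapping)
    ds.uns["group_markers"] = report
    ds.uns["group_method"] = method
    return ds


def celltype_association(
    ds: SpatialDataset,
    w: SpatialWeights,
    markers: MarkerDictionary | None = None,
    n_permutations: int = 999,
    seed: int | None = None,
    method: str = "zmean",
    perm_mode: str = "joint",
) -> AssociationResult:
    """Pairwise spatial association (global L, p, q) between cell-type scores."""
    if "group_scores" not in ds.layers or markers is not None:
        group_scores(ds, markers, method=method)
    names = ds.uns["group_names"]
    if len(names) < 2:
        raise ValueError("need at least two cell types for colocalization analysis")
    return pairwise_association(
        ds, names, w,
        n_permutations=n_permutations, seed=seed,
        perm_mode=perm_mode, layer="group_scores",
    )
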