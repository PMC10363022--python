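"""Spatial gene-module discovery by silhouette-maximizing hierarchical clustering.

The pairwise global-L matrix is treated as a similarity between genes:
distance d = 1 - L (clipped to [0, 2]) feeds average-linkage hierarchical
clustering, the tree is cut at every candidate cluster count k in
[k_min, k_max], and the cut maximizing the mean silhouette score (computed
on the same precomputed distance) is returned — ties resolve to the
smallest k. Module ids m0, m1, ... are ordered by descending module size,
ties by the lexicographically first member gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .dataset import SpatialDataset
from .grouping import aggregate_scores
from .lindex import AssociationResult

log = logging.getLogger(__name__)

__all__ = ["ModuleAssignment", "detect_modules", "module_scores"]


@dataclass
class ModuleAssignment:
    """Gene → module labels with the silhouette trace over candidate k."""

    labels: pd.Series  # gene_id -> "m0", "m1", ...
    k_selected: int
    silhouette_trace: list[tuple[int, float]]
    linkage_method: str

    @property
    def module_ids(self) -> list[str]:
        return sorted(set(self.labels), key=lambda m: int(m[1:]))

    def genes_in(self, module_id: str) -> list[str]:
        return list(self.labels.index[self.labels == module_id])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.labels.index, "module": self.labels.to_numpy()})


def _relabel_by_size(raw: np.ndarray, genes: list[str]) -> pd.Series:
    """Map raw cluster ids to m0, m1, ... by descending size, ties by first gene."""
    order = []
    for cid in np.unique(raw):
        members = sorted(g for g, r in zip(genes, raw) if r == cid)
        order.append((-len(members), members[0], cid))
    mapping = {cid: f"m{rank}" for rank, (_, _, cid) in enumerate(sorted(order))}
    return pd.Series(
        [mapping[r] for r in raw], index=pd.Index(genes, name="gene_id"), name="module"
    )


def detect_modules(
    assoc: AssociationResult,
    k_min: int = 2,
    k_max: int = 10,
    linkage_method: str = "average",
) -> ModuleAssignment:
    """Cluster genes on the global-L similarity, selecting k by silhouette.

    ``assoc`` must cover all unordered pairs of at least three genes.
    ``k_max`` is clamped to (number of genes - 1) so the silhouette is
    defined at every candidate cut.
    """
    lmat = assoc.l_matrix()
    genes = sorted(lmat.index)  # fixed order: invariant to input order
    g = len(genes)
    if g < 3:
        raise ValueError(f"need at least 3 genes to detect modules, got {g}")
    expected = g * (g - 1) // 2
    if len(assoc.pairs) < expected:
        raise ValueError(
            f"association result covers {len(assoc.pairs)} pairs; "
            f"all {expected} unordered pairs required"
        )
    if k_min < 2:
        raise ValueError("k_min must be >= 2")
    if k_max >= g:
        log.warning("k_max=%d clamped to %d (number of genes - 1)", k_max, g - 1)
        k_max = g - 1
    if k_min > k_max:
        raise ValueError(f"k_min={k_min} exceeds k_max={k_max}")

    lmat = lmat.loc[genes, genes]
    dist = np.clip(1.0 - lmat.to_numpy(), 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    off_diag = dist[~np.eye(g, dtype=bool)]
    if np.allclose(off_diag, off_diag[0]):
        raise ValueError("degenerate distance: all pairwise L equal")

    link = sch.linkage(squareform(dist, checks=False), method=linkage_method)
    trace: list[tuple[int, float]] = []
    cuts: dict[int, np.ndarray] = {}
    for k in range(k_min, k_max + 1):
        labels = sch.fcluster(link, t=k, criterion="maxclust")
        cuts[k] = labels
        n_found = len(np.unique(labels))
        if 2 <= n_found <= g - 1:
            sil = float(silhouette_score(dist, labels, metric="precomputed"))
        else:  # a cut that failed to split: silhouette undefined
            sil = float("nan")
        trace.append((k, sil))

    finite = [(k, s) for k, s in trace if np.isfinite(s)]
    if finite:
        best_sil = max(s for _, s in finite)
        k_selected = min(k for k, s in finite if s == best_sil)
    else:  # forced single candidate that did not split cleanly
        k_selected = k_min
    labels = _relabel_by_size(cuts[k_selected], genes)
    log.info(
        "selected k=%d modules (silhouette=%.3f) from candidates %d..%d",
        k_selected, dict(trace).get(k_selected, float("nan")), k_min, k_max,
    )
    return ModuleAssignment(
        labels=labels,
        k_selected=k_selected,
        silhouette_trace=trace,
        linkage_method=linkage_method,
    )


def module_scores(
    ds: SpatialDataset, modules: ModuleAssignment, method: str = "zmean"
) -> SpatialDataset:
    """Add a ``"module_scores"`` layer: per-spot mean z-scored log-CPM per module."""
    gene_lists = {m: modules.genes_in(m) for m in modules.module_ids}
    for mid, genes in gene_lists.items():
        if not genes:
            raise ValueError(f"module {mid} is empty")
    scores, _ = aggregate_scores(ds, gene_lists, method=method)
    ds.layers["module_scores"] = scores
    ds.uns["module_names"] = list(gene_lists)
    return ds
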