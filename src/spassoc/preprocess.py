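"""Quality control and library-size normalization.

QC removes genes detected in too few spots and spots with too few total
UMIs (defaults: genes observed in fewer than 10 spots, spots with fewer
than 150 UMI counts). Both masks are computed on the raw input matrix and
applied simultaneously — no iteration to a fixed point, so the operation
is deterministic; a warning is emitted if the joint application leaves
entities below threshold.

Normalization converts raw counts to log-scaled counts-per-million:
``log(1 + 1e6 * count / spot_total)`` (natural log by default).
"""

from __future__ import annotations

import logging

import numpy as np
import scipy.sparse as sp

from .dataset import SpatialDataset

log = logging.getLogger(__name__)

__all__ = ["qc_filter", "normalize_logcpm"]


def _gene_detection(counts) -> np.ndarray:
    """Number of spots where each gene has count > 0."""
    if sp.issparse(counts):
        return np.asarray((counts > 0).sum(axis=0)).ravel()
    return (counts > 0).sum(axis=0)


def _spot_totals(counts) -> np.ndarray:
    if sp.issparse(counts):
        return np.asarray(counts.sum(axis=1)).ravel()
    return counts.sum(axis=1)


def qc_filter(
    ds: SpatialDataset,
    min_spots_per_gene: int = 10,
    min_umi_per_spot: int = 150,
) -> SpatialDataset:
    """Filter genes by detection breadth and spots by total UMI.

    A gene is kept when it is detected (count > 0) in at least
    ``min_spots_per_gene`` spots; a spot is kept when its total UMI count is
    at least ``min_umi_per_spot``. Both criteria are evaluated on the raw
    input matrix and applied jointly.
    """
    detection = _gene_detection(ds.counts)
    totals = _spot_totals(ds.counts)
    gene_mask = detection >= min_spots_per_gene
    spot_mask = totals >= min_umi_per_spot

    if not gene_mask.any():
        raise ValueError(
            f"QC removed all {ds.n_genes} genes "
            f"(min_spots_per_gene={min_spots_per_gene})"
        )
    if not spot_mask.any():
        raise ValueError(
            f"QC removed all {ds.n_spots} spots (min_umi_per_spot={min_umi_per_spot})"
        )

    out = ds.subset(spot_mask, gene_mask)
    out.spot_meta["total_umi"] = _spot_totals(out.counts)
    out.gene_meta["n_spots_detected"] = _gene_detection(out.counts)

    # joint application can drop an entity below threshold afterwards
    post_gene = _gene_detection(out.counts)
    post_spot = _spot_totals(out.counts)
    n_below = int((post_gene < min_spots_per_gene).sum() + (post_spot < min_umi_per_spot).sum())
    if n_below:
        log.warning(
            "%d gene(s)/spot(s) fell below QC thresholds after joint filtering; "
            "rerun qc_filter to tighten", n_below,
        )
    log.info(
        "QC: kept %d/%d spots (UMI >= %d) and %d/%d genes (detected in >= %d spots)",
        spot_mask.sum(), ds.n_spots, min_umi_per_spot,
        gene_mask.sum(), ds.n_genes, min_spots_per_gene,
    )
    out.uns["qc"] = {
        "min_spots_per_gene": min_spots_per_gene,
        "min_umi_per_spot": min_umi_per_spot,
        "spots_removed": int((~spot_mask).sum()),
        "genes_removed": int((~gene_mask).sum()),
    }
    return out


def normalize_logcpm(ds: SpatialDataset, base: float | None = None) -> SpatialDataset:
    """Add a ``"logcpm"`` layer: log(1 + CPM), natural log unless ``base`` given.

    Raw counts are retained. Fails on spots with zero total counts (which
    cannot occur after :func:`qc_filter`).
    """
    totals = _spot_totals(ds.counts).astype(float)
    if (totals == 0).any():
        raise ValueError(f"{int((totals == 0).sum())} spot(s) have zero total counts")
    dense = ds.counts_dense().astype(float)
    cpm = dense * (1e6 / totals)[:, None]
    logcpm = np.log1p(cpm)
    if base is not None:
        logcpm /= np.log(base)
    ds.layers["logcpm"] = logcpm
    return ds
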