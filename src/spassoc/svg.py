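"""Spatially variable gene (SVG) detection via Moran's I.

Moran's I scores the spatial autocorrelation of one variable:

    I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2,   z = x - mean(x)

where S0 is the sum of all weights (the number of non-isolated spots for
row-standardized W). Under spatial randomness E[I] = -1/(n-1); smooth
spatial patterns push I toward +1. Genes are selected either as the top-K
by I or by an I threshold (default 0.3, strict inequality).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import SpatialDataset
from .weights import SpatialWeights

log = logging.getLogger(__name__)

__all__ = ["SvgResult", "morans_i", "morans_i_matrix", "select_svgs"]

DEFAULT_I_THRESHOLD = 0.3


@dataclass
class SvgResult:
    """Per-gene Moran's I with the selection mask and criterion used."""

    morans_i: pd.Series
    selected: pd.Series
    criterion: dict

    @property
    def svg_names(self) -> list[str]:
        return list(self.selected.index[self.selected])


def morans_i(x: np.ndarray, w: SpatialWeights) -> float:
    """Moran's I of one variable over the spot graph."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] != w.n_spots:
        raise ValueError("x length does not match weight matrix")
    z = x - x.mean()
    denom = z @ z
    if denom == 0:
        raise ValueError("zero variance: Moran's I undefined for constant input")
    return float(len(x) / w.s0 * (z @ w.lag(z)) / denom)


def morans_i_matrix(X: np.ndarray, w: SpatialWeights, block: int = 512) -> np.ndarray:
    """Moran's I for each column of a spots × variables matrix.

    Zero-variance columns get NaN. Processes columns in blocks to bound
    memory on wide matrices.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    out = np.empty(X.shape[1])
    for start in range(0, X.shape[1], block):
        Z = X[:, start : start + block] - X[:, start : start + block].mean(axis=0)
        denom = np.einsum("ij,ij->j", Z, Z)
        num = np.einsum("ij,ij->j", Z, w.w @ Z)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[start : start + Z.shape[1]] = np.where(
                denom > 0, n / w.s0 * num / denom, np.nan
            )
    return out


def select_svgs(
    ds: SpatialDataset,
    w: SpatialWeights,
    topK: int | None = None,
    i_threshold: float | None = None,
    inclusive: bool = False,
) -> SvgResult:
    """Score every gene's Moran's I on the log-CPM layer and select SVGs.

    Exactly one of ``topK`` / ``i_threshold`` may be given; with neither,
    the documented default threshold of 0.3 applies. ``inclusive`` switches
    the threshold comparison from strict ``>`` to ``>=``. Top-K ties at the
    boundary break by gene id. Results are also written into
    ``ds.gene_meta`` (columns ``morans_i``, ``is_svg``).
    """
    if "logcpm" not in ds.layers:
        raise ValueError("logcpm layer missing: run normalize_logcpm first")
    if topK is not None and i_threshold is not None:
        raise ValueError("give exactly one of topK / i_threshold, not both")
    if topK is None and i_threshold is None:
        i_threshold = DEFAULT_I_THRESHOLD

    values = morans_i_matrix(ds.layers["logcpm"], w)
    i_series = pd.Series(values, index=pd.Index(ds.gene_ids, name="gene_id"), name="morans_i")

    if topK is not None:
        if topK <= 0:
            raise ValueError(f"topK must be positive, got {topK}")
        order = sorted(
            i_series.index, key=lambda g: (-np.nan_to_num(i_series[g], nan=-np.inf), g)
        )
        chosen = set(order[:topK])
        selected = pd.Series([g in chosen for g in i_series.index], index=i_series.index)
        criterion = {"topK": int(topK)}
    else:
        cmp = i_series.ge if inclusive else i_series.gt
        selected = cmp(i_threshold).fillna(False)
        criterion = {"i_threshold": float(i_threshold), "inclusive": bool(inclusive)}

    ds.gene_meta["morans_i"] = i_series.to_numpy()
    ds.gene_meta["is_svg"] = selected.to_numpy()
    log.info("selected %d/%d SVGs with criterion %s", int(selected.sum()), len(selected), criterion)
    return SvgResult(morans_i=i_series, selected=selected, criterion=criterion)
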