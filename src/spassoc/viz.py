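"""Visualization of spatial association results.

Every plot writes the figure (PNG/PDF by extension) plus a companion CSV
holding exactly the values handed to the renderer, so tests and downstream
pipelines can check the plotted data rather than pixels.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import seaborn as sns
from scipy.spatial.distance import squareform

from .dataset import SpatialDataset
from .lindex import AssociationResult, LocalLField, local_l
from .modules import ModuleAssignment
from .weights import SpatialWeights, build_knn_weights

log = logging.getLogger(__name__)

__all__ = ["volcano", "hotspot", "clustermap", "module_maps"]


def _companion_csv(out: Path) -> Path:
    return out.with_suffix(out.suffix + ".csv") if out.suffix != ".csv" else out


def volcano(assoc: AssociationResult, out, q_line: float = 0.05, dpi: int = 150) -> pd.DataFrame:
    """Volcano plot: global L versus -log10 of the BH-adjusted q per pair.

    q-values are floored at the permutation resolution 1/(n_permutations+1)
    before the log so the p-floor pairs remain finite.
    """
    out = Path(out)
    floor = 1.0 / (assoc.n_permutations + 1.0)
    q = np.maximum(assoc.q_value, floor)
    data = assoc.to_frame()
    data["neg_log10_q"] = -np.log10(q)
    data["significant"] = assoc.q_value < q_line

    fig, ax = plt.subplots(figsize=(5, 4))
    colors = np.where(data["significant"], "#c0392b", "#7f8c8d")
    ax.scatter(data["global_L"], data["neg_log10_q"], c=colors, s=12, alpha=0.8)
    ax.axhline(-np.log10(q_line), ls="--", lw=0.8, color="k")
    ax.axvline(0, ls=":", lw=0.6, color="k")
    ax.set_xlabel("global L")
    ax.set_ylabel(r"$-\log_{10}$ q (BH)")
    ax.set_title("Spatial association volcano")
    fig.tight_layout()
    fig.savefig(out, dpi=dpi)
    plt.close(fig)
    data.to_csv(_companion_csv(out), index=False)
    return data


def hotspot(
    ds: SpatialDataset, field: LocalLField, out, dpi: int = 150, size: float = 18.0
) -> pd.DataFrame:
    """Spatial map of one pair's local L, diverging scale symmetric about 0.

    The y axis is flipped so low array rows (tissue top) appear at the top.
    """
    out = Path(out)
    values = np.asarray(field.values, dtype=float)
    limit = float(np.abs(values).max()) or 1.0  # constant-zero field -> midpoint colors
    data = pd.DataFrame(
        {"x": ds.coords[:, 0], "y": ds.coords[:, 1], "local_L": values}
    )

    fig, ax = plt.subplots(figsize=(5, 4.5))
    sc = ax.scatter(
        data["x"], data["y"], c=data["local_L"],
        cmap="RdBu_r", vmin=-limit, vmax=limit, s=size,
    )
    ax.invert_yaxis()
    ax.set_aspect("equal")
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    ax.set_title(f"local L: {field.pair[0]} vs {field.pair[1]}")
    fig.colorbar(sc, ax=ax, label="local L")
    fig.tight_layout()
    fig.savefig(out, dpi=dpi)
    plt.close(fig)
    data.to_csv(_companion_csv(out), index=False)
    return data


def clustermap(
    assoc: AssociationResult, out, linkage_method: str = "average", dpi: int = 150
) -> pd.DataFrame:
    """Clustered heat map of the symmetric global-L matrix (diagonal 1).

    Row/column ordering uses average linkage on distance 1 - L, the same
    contract as module detection, so the dendrogram matches module splits.
    """
    out = Path(out)
    lmat = assoc.l_matrix()
    lmat = lmat.loc[sorted(lmat.index), sorted(lmat.index)]
    dist = np.clip(1.0 - lmat.to_numpy(), 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    link = sch.linkage(squareform(dist, checks=False), method=linkage_method)

    grid = sns.clustermap(
        lmat, row_linkage=link, col_linkage=link,
        cmap="RdBu_r", vmin=-1, vmax=1, figsize=(6, 6),
    )
    grid.savefig(out, dpi=dpi)
    plt.close(grid.fig)

    order = sch.leaves_list(link)
    rendered = lmat.iloc[order, order]
    rendered.to_csv(_companion_csv(out))
    return rendered


def module_maps(
    ds: SpatialDataset,
    modules: ModuleAssignment,
    out_dir,
    weights: SpatialWeights | None = None,
    fmt: str = "png",
    dpi: int = 150,
) -> list[Path]:
    """One spatial map per module score plus one local-L hotspot per module pair.

    File names are deterministic: ``module_<id>_pattern.<fmt>`` and
    ``modules_<a>_<b>_hotspot.<fmt>``. Module scores are computed on demand;
    pair hotspots need spatial weights (default: k=6 kNN on the dataset
    coordinates).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ids = modules.module_ids
    if not ids:
        raise ValueError("no modules to plot")
    if "module_scores" not in ds.layers or ds.uns.get("module_names") != ids:
        from .modules import module_scores as _module_scores

        _module_scores(ds, modules)
    if weights is None:
        weights = build_knn_weights(ds.coords, k=min(6, ds.n_spots - 1))

    scores = ds.layers["module_scores"]
    files: list[Path] = []
    for j, mid in enumerate(ids):
        path = out_dir / f"module_{mid}_pattern.{fmt}"
        data = pd.DataFrame(
            {"x": ds.coords[:, 0], "y": ds.coords[:, 1], "score": scores[:, j]}
        )
        fig, ax = plt.subplots(figsize=(5, 4.5))
        sc = ax.scatter(data["x"], data["y"], c=data["score"], cmap="viridis", s=18)
        ax.invert_yaxis()
        ax.set_aspect("equal")
        ax.set_title(f"module {mid} score")
        fig.colorbar(sc, ax=ax, label="mean z(log-CPM)")
        fig.tight_layout()
        fig.savefig(path, dpi=dpi)
        plt.close(fig)
        data.to_csv(_companion_csv(path), index=False)
        files.append(path)

    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = ids[i], ids[j]
            field = local_l(scores[:, i], scores[:, j], weights, pair=(a, b))
            path = out_dir / f"modules_{a}_{b}_hotspot.{fmt}"
            hotspot(ds, field, path, dpi=dpi)
            files.append(path)
    return files
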