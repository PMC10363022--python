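"""Local and global L-index: bivariate spatial association with permutation tests.

The L-index combines the correlation of two variables with their spatial
clustering. With z-scores z_x, z_y (population standard deviation) and a
row-standardized neighborhood matrix W, the local statistic at spot i is
the product of the two spatial lags,

    L_i(x, y) = (W z_x)_i * (W z_y)_i,

and the global statistic is the mean of the local values over all spots,

    L(x, y) = (1/n) * sum_i L_i(x, y).

The mean-of-local identity holds by construction, and with identity
weights (each spot its own neighborhood) L reduces exactly to the Pearson
correlation of x and y. For row-standardized W the Cauchy-Schwarz
inequality gives |L(x, y)| <= sqrt(L(x,x) L(y,y)) <= 1. A positive L means
the two variables cluster in the same tissue regions (colocalization), a
negative L means they occupy disjoint regions (exclusion).

Significance is assessed by a permutation test: the spot labels of both
variables are shuffled with one shared permutation per round, which
destroys the spatial arrangement while preserving the per-spot (x, y)
value coupling, so the null hypothesis is "no spatial structure", not "no
expression correlation". Two-sided add-one p-values are corrected across
all tested pairs by Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .dataset import SpatialDataset
from .weights import SpatialWeights

log = logging.getLogger(__name__)

__all__ = [
    "LocalLField",
    "AssociationResult",
    "zscore",
    "local_l",
    "global_l",
    "pairwise_association",
]

# permutation rounds are processed in blocks; each block materializes an
# (n_spots, n_vars * block) matrix, so cap its element count
_PERM_BLOCK_ELEMENTS = 20_000_000


def zscore(x: np.ndarray) -> np.ndarray:
    """Population-standard-deviation z-scores; errors on constant input."""
    x = np.asarray(x, dtype=float)
    sd = x.std()  # population sd (ddof=0)
    if sd == 0:
        raise ValueError("zero variance: cannot z-score a constant variable")
    return (x - x.mean()) / sd


@dataclass
class LocalLField:
    """Per-spot local L values for one variable pair."""

    values: np.ndarray
    pair: tuple[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("local L field contains non-finite values")


@dataclass
class AssociationResult:
    """Global L, permutation p and BH q per pair, plus per-spot local fields."""

    pairs: list[tuple[str, str]]
    global_l: np.ndarray
    p_value: np.ndarray
    q_value: np.ndarray
    local_l: np.ndarray  # spots × pairs
    n_permutations: int
    seed: int
    names: list[str] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pair_a": [a for a, _ in self.pairs],
                "pair_b": [b for _, b in self.pairs],
                "global_L": self.global_l,
                "p_value": self.p_value,
                "q_value": self.q_value,
            }
        )

    def local_field(self, pair: tuple[str, str]) -> LocalLField:
        lookup = {p: i for i, p in enumerate(self.pairs)}
        key = pair if pair in lookup else (pair[1], pair[0])
        if key not in lookup:
            raise KeyError(f"pair {pair} not in result")
        return LocalLField(values=self.local_l[:, lookup[key]], pair=key)

    def l_matrix(self) -> pd.DataFrame:
        """Symmetric global-L matrix over all tested names, diagonal set to 1."""
        names = self.names or sorted({n for p in self.pairs for n in p})
        mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
        for (a, b), l in zip(self.pairs, self.global_l):
            mat.loc[a, b] = mat.loc[b, a] = l
        return mat


def local_l(x: np.ndarray, y: np.ndarray, w: SpatialWeights, pair=("x", "y")) -> LocalLField:
    """Per-spot products of spatially lagged z-scores.

    Isolated spots (zero weight rows) have zero lag and hence local L = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] != y.shape[0] or x.shape[0] != w.n_spots:
        raise ValueError(
            f"length mismatch: x={x.shape[0]}, y={y.shape[0]}, weights={w.n_spots}"
        )
    values = w.lag(zscore(x)) * w.lag(zscore(y))
    return LocalLField(values=values, pair=tuple(pair))


def global_l(field: LocalLField) -> float:
    """Arithmetic mean of the local L field over all spots."""
    if field.values.size == 0:
        raise ValueError("empty local L field")
    return float(field.values.mean())


def _resolve_variables(
    ds: SpatialDataset, names: list[str], layer: str | None
) -> np.ndarray:
    """Column-stack the named variables from gene or score layers."""
    if layer is None:
        group_names = ds.uns.get("group_names", [])
        if group_names and all(n in group_names for n in names):
            layer = "group_scores"
        else:
            layer = "logcpm"
    if layer == "logcpm":
        if "logcpm" not in ds.layers:
            raise ValueError("logcpm layer missing: run normalize_logcpm first")
        idx = ds.gene_index(names)
        return ds.layers["logcpm"][:, idx]
    columns = ds.uns.get(f"{layer.split('_')[0]}_names") or ds.uns.get("group_names")
    if layer not in ds.layers:
        raise ValueError(f"layer {layer!r} not found")
    lookup = {n: i for i, n in enumerate(columns or [])}
    missing = [n for n in names if n not in lookup]
    if missing:
        raise KeyError(f"names not in layer {layer!r}: {missing}")
    return ds.layers[layer][:, [lookup[n] for n in names]]


def pairwise_association(
    ds: SpatialDataset,
    names: list[str],
    w: SpatialWeights,
    n_permutations: int = 999,
    seed: int | None = None,
    perm_mode: str = "joint",
    layer: str | None = None,
) -> AssociationResult:
    """Global L with permutation p and BH q for all unordered pairs of ``names``.

    Parameters
    ----------
    names
        Gene ids (resolved on the log-CPM layer) or score column names
        (e.g. cell types after :func:`~spassoc.grouping.group_scores`).
    n_permutations
        Permutation rounds shared by every pair (determinism and
        vectorization; valid because each pair's test is marginal).
    seed
        Mandatory RNG seed; identical seeds give bit-identical p and q.
    perm_mode
        ``"joint"`` (default) permutes both variables with one shared
        permutation per round, testing "no spatial arrangement" while
        keeping the per-spot value coupling. ``"single"`` permutes only the
        second variable of each pair, additionally breaking the value
        coupling.
    """
    if seed is None:
        raise ValueError("seed is mandatory for pairwise_association")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if perm_mode not in ("joint", "single"):
        raise ValueError(f"unknown perm_mode {perm_mode!r}")
    names = list(names)
    if len(names) < 2:
        raise ValueError("need at least two variables")

    X = np.asarray(_resolve_variables(ds, names, layer), dtype=float)
    n = X.shape[0]

    sds = X.std(axis=0)
    skipped = [nm for nm, sd in zip(names, sds) if sd == 0]
    if skipped:
        log.warning("skipping constant variable(s): %s", skipped)
        keep = sds > 0
        X = X[:, keep]
        names = [nm for nm, k in zip(names, keep) if k]
        if len(names) < 2:
            raise ValueError("fewer than two non-constant variables remain")

    Z = (X - X.mean(axis=0)) / X.std(axis=0)
    lag = w.w @ Z
    m = Z.shape[1]
    l_obs = lag.T @ lag / n  # m × m global L matrix
    abs_obs = np.abs(l_obs)

    rng = np.random.default_rng(seed)
    exceed = np.zeros((m, m), dtype=np.int64)
    block = max(1, min(n_permutations, _PERM_BLOCK_ELEMENTS // max(1, n * m)))
    done = 0
    while done < n_permutations:
        c = min(block, n_permutations - done)
        perms = np.empty((c, n), dtype=np.intp)
        for j in range(c):
            perms[j] = rng.permutation(n)
        zp = Z[perms]  # (c, n, m)
        zp2d = np.moveaxis(zp, 0, 1).reshape(n, c * m)
        lag_p = (w.w @ zp2d).reshape(n, c, m)
        if perm_mode == "joint":
            l_perm = np.einsum("ncj,nck->cjk", lag_p, lag_p) / n
        else:
            l_perm = np.einsum("nj,nck->cjk", lag, lag_p) / n
        exceed += (np.abs(l_perm) >= abs_obs[None, :, :]).sum(axis=0)
        done += c

    pairs = list(combinations(names, 2))
    idx_a = np.array([names.index(a) for a, _ in pairs])
    idx_b = np.array([names.index(b) for _, b in pairs])
    if perm_mode == "joint":
        n_exceed = exceed[idx_a, idx_b]
    else:
        # asymmetric null: variable b permuted against fixed a
        n_exceed = exceed[idx_a, idx_b]
    p = (1.0 + n_exceed) / (n_permutations + 1.0)
    q = multipletests(p, method="fdr_bh")[1] if len(p) else np.array([])

    local = lag[:, idx_a] * lag[:, idx_b]
    return AssociationResult(
        pairs=pairs,
        global_l=l_obs[idx_a, idx_b],
        p_value=p,
        q_value=q,
        local_l=local,
        n_permutations=n_permutations,
        seed=seed,
        names=names,
        skipped=skipped,
    )
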