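"""Synthetic Visium-like datasets with planted spatial structure.

Generates hexagonal-offset spot lattices and negative-binomial counts with
planted spatial expression patterns (Gaussian bumps, linear gradients, or
pure noise), so every analysis stage can be exercised and validated
without external downloads. The same generator writes the SpaceRanger and
CSV dialects the readers consume, enabling byte-level round-trip tests.

Count model: gene g at spot i is NB distributed with mean
``mu = base_mean * intensity_g(i) * libsize_i`` and overdispersion ``alpha``
(variance mu + alpha * mu^2; alpha = 0 degenerates to Poisson). Defaults:
``base_mean = 10`` counts, ``alpha = 0.5``, library-size factors uniform in
[0.7, 1.3] — overdispersion and depth variation typical of spot-level
spatial transcriptomics. A planted bump multiplies the local mean by up to
``1 + amplitude`` (default amplitude 8, a strong but realistic regional
marker enrichment).
"""

from __future__ import annotations

import gzip
import math
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .dataset import SpatialDataset

__all__ = [
    "make_lattice",
    "plant_patterns",
    "plant_modules",
    "write_visium_dir",
    "write_csv_pair",
    "bump",
    "gradient",
    "noise",
]

ROW_SPACING = math.sqrt(3.0) / 2.0

DEFAULT_BASE_MEAN = 10.0
DEFAULT_DISPERSION = 0.5  # alpha in var = mu + alpha mu^2
DEFAULT_LIBSIZE_RANGE = (0.7, 1.3)
DEFAULT_AMPLITUDE = 10.0
DEFAULT_BACKGROUND = 0.02  # marker-like dropout outside the planted domain


def make_lattice(rows: int, cols: int) -> np.ndarray:
    """Hexagonal-offset lattice coordinates, row-major spot order.

    Odd rows are shifted by 0.5 in x; rows are spaced sqrt(3)/2 apart, so
    every interior spot has six nearest neighbors at unit distance.
    """
    r, c = np.divmod(np.arange(rows * cols), cols)
    x = c + 0.5 * (r % 2)
    y = r * ROW_SPACING
    return np.column_stack([x.astype(float), y.astype(float)])


def lattice_spot_ids(rows: int, cols: int) -> list[str]:
    return [f"s{r:03d}c{c:03d}" for r in range(rows) for c in range(cols)]


# ---------------------------------------------------------------- patterns
def bump(
    center,
    radius: float,
    amplitude: float = DEFAULT_AMPLITUDE,
    background: float = DEFAULT_BACKGROUND,
) -> dict:
    """Regional marker: intensity background + amplitude * exp(-(d/radius)^2).

    The low background emulates the near-dropout expression real marker
    genes show outside their tissue domain; inside the domain the mean is
    amplified up to ``amplitude``-fold over the dataset base mean.
    """
    return {"kind": "bump", "center": [float(c) for c in center],
            "radius": float(radius), "amplitude": float(amplitude),
            "background": float(background)}


def gradient(direction, amplitude: float = DEFAULT_AMPLITUDE) -> dict:
    """Linear ramp along ``direction``, scaled to [1, 1 + amplitude]."""
    return {"kind": "gradient", "direction": [float(d) for d in direction],
            "amplitude": float(amplitude)}


def noise() -> dict:
    """Spatially unstructured gene (intensity 1 everywhere)."""
    return {"kind": "noise"}


def _intensity(pattern: dict, coords: np.ndarray) -> np.ndarray:
    kind = pattern.get("kind")
    if kind == "noise":
        return np.ones(coords.shape[0])
    if kind == "bump":
        center = np.asarray(pattern["center"], dtype=float)
        radius = float(pattern["radius"])
        if radius <= 0:
            raise ValueError("bump radius must be positive")
        d = np.linalg.norm(coords - center, axis=1)
        background = float(pattern.get("background", DEFAULT_BACKGROUND))
        return background + float(pattern["amplitude"]) * np.exp(-((d / radius) ** 2))
    if kind == "gradient":
        direction = np.asarray(pattern["direction"], dtype=float)
        norm = np.linalg.norm(direction)
        if norm == 0:
            raise ValueError("gradient direction must be nonzero")
        proj = coords @ (direction / norm)
        span = proj.max() - proj.min()
        ramp = (proj - proj.min()) / span if span > 0 else np.zeros_like(proj)
        return 1.0 + float(pattern["amplitude"]) * ramp
    raise ValueError(f"unknown pattern kind {pattern.get('kind')!r}")


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    if alpha <= 0:
        return rng.poisson(mu)
    size = 1.0 / alpha
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def plant_patterns(
    lattice: np.ndarray,
    spec: dict[str, dict],
    seed: int,
    base_mean: float = DEFAULT_BASE_MEAN,
    dispersion: float = DEFAULT_DISPERSION,
    libsize_range: tuple[float, float] = DEFAULT_LIBSIZE_RANGE,
    rows_cols: tuple[int, int] | None = None,
) -> SpatialDataset:
    """Draw NB counts for the genes in ``spec`` over the lattice.

    ``spec`` maps gene name → pattern dict (see :func:`bump`,
    :func:`gradient`, :func:`noise`). A fixed seed gives bit-identical
    output. When ``rows_cols`` is given (lattice built by
    :func:`make_lattice`), array indices are stored in ``spot_meta`` so the
    dataset can be written in the SpaceRanger dialect.
    """
    coords = np.asarray(lattice, dtype=float)
    if not spec:
        raise ValueError("empty pattern spec")
    n = coords.shape[0]
    rng = np.random.default_rng(seed)
    libsize = rng.uniform(*libsize_range, size=n)

    gene_ids = list(spec)
    intensity = np.column_stack([_intensity(p, coords) for p in spec.values()])
    mu = base_mean * intensity * libsize[:, None]
    counts = _nb_counts(rng, mu, dispersion)

    if rows_cols is not None:
        rows, cols = rows_cols
        if rows * cols != n:
            raise ValueError("rows_cols inconsistent with lattice size")
        spot_ids = lattice_spot_ids(rows, cols)
        r, c = np.divmod(np.arange(n), cols)
        spot_meta = pd.DataFrame(
            {"array_row": r, "array_col": 2 * c + (r % 2)},
            index=pd.Index(spot_ids, name="spot_id"),
        )
    else:
        spot_ids = [f"s{i:04d}" for i in range(n)]
        spot_meta = None

    return SpatialDataset(
        counts=counts.astype(np.int64),
        coords=coords,
        gene_ids=gene_ids,
        spot_ids=spot_ids,
        spot_meta=spot_meta,
        uns={"generator": {
            "seed": seed, "base_mean": base_mean, "dispersion": dispersion,
            "libsize_range": list(libsize_range), "spec": spec,
        }},
    )


def _module_centers(n_modules: int, coords: np.ndarray) -> tuple[np.ndarray, float]:
    """Pairwise-disjoint bump centers on a coarse grid over the lattice."""
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    g = math.ceil(math.sqrt(n_modules))
    cell = (hi - lo) / g
    centers = []
    for m in range(n_modules):
        gy, gx = divmod(m, g)
        centers.append(lo + cell * (np.array([gx, gy]) + 0.5))
    radius = 0.30 * float(min(cell)) if min(cell) > 0 else 1.0
    return np.asarray(centers), radius


def plant_modules(
    lattice: np.ndarray,
    n_modules: int,
    genes_per_module: int,
    seed: int,
    amplitude: float = DEFAULT_AMPLITUDE,
    **kwargs,
) -> tuple[SpatialDataset, pd.Series]:
    """Dataset where each module's genes share one bump, bumps pairwise disjoint.

    Returns the dataset and the ground-truth gene → module labels for
    recovery checks (adjusted Rand index).
    """
    if n_modules < 1 or genes_per_module < 1:
        raise ValueError("n_modules and genes_per_module must be positive")
    coords = np.asarray(lattice, dtype=float)
    centers, radius = _module_centers(n_modules, coords)
    spec = {}
    truth = {}
    for m in range(n_modules):
        for j in range(genes_per_module):
            gene = f"g_m{m}_{j:02d}"
            spec[gene] = bump(centers[m], radius, amplitude)
            truth[gene] = f"m{m}"
    ds = plant_patterns(coords, spec, seed=seed, **kwargs)
    labels = pd.Series(truth, name="module")
    labels.index.name = "gene_id"
    return ds, labels


def standard_pair_fixture(
    layout: str,
    seed: int,
    rows: int = 20,
    cols: int = 20,
    n_noise: int = 18,
    radius: float = 4.0,
    amplitude: float = DEFAULT_AMPLITUDE,
    **kwargs,
) -> SpatialDataset:
    """The reference two-gene test bed: genes ``a``/``b`` plus noise genes.

    ``layout="colocalized"`` puts both genes on one off-center bump;
    ``"exclusive"`` puts them on two disjoint bumps; ``"noise"`` makes both
    spatially unstructured. Defaults (20×20 lattice, radius 4, amplitude
    10, 18 noise genes) are the study conditions every planted-pattern
    simulation in the test suite cites.
    """
    lattice = make_lattice(rows, cols)
    lo, hi = lattice.min(axis=0), lattice.max(axis=0)
    center_a = lo + 0.25 * (hi - lo)
    center_b = lo + 0.75 * (hi - lo)
    if layout == "colocalized":
        spec = {"a": bump(center_a, radius, amplitude), "b": bump(center_a, radius, amplitude)}
    elif layout == "exclusive":
        spec = {"a": bump(center_a, radius, amplitude), "b": bump(center_b, radius, amplitude)}
    elif layout == "noise":
        spec = {"a": noise(), "b": noise()}
    else:
        raise ValueError(f"unknown layout {layout!r}")
    spec.update({f"n{i:02d}": noise() for i in range(n_noise)})
    return plant_patterns(lattice, spec, seed=seed, rows_cols=(rows, cols), **kwargs)


# ---------------------------------------------------------------- writers
def _write_text(path: Path, lines: list[str], use_gzip: bool) -> None:
    if use_gzip:
        with gzip.open(path, "wt") as fh:
            fh.write("\n".join(lines) + "\n")
    else:
        path.write_text("\n".join(lines) + "\n")


def write_visium_dir(ds: SpatialDataset, path, use_gzip: bool = False) -> Path:
    """Write the dataset in the SpaceRanger dialect the Visium reader consumes.

    Requires ``array_row``/``array_col`` in ``spot_meta`` (set by
    :func:`plant_patterns` with ``rows_cols``). All spots are written as
    in-tissue unless ``spot_meta['in_tissue']`` says otherwise.
    """
    directory = Path(path)
    (directory / "spatial").mkdir(parents=True, exist_ok=True)
    suffix = ".gz" if use_gzip else ""

    mtx = sp.coo_matrix(ds.counts.T)  # genes × barcodes, 10X orientation
    mtx_path = directory / f"matrix.mtx{suffix}"
    if use_gzip:
        with gzip.open(mtx_path, "wb") as fh:
            scipy.io.mmwrite(fh, mtx, field="integer")
    else:
        scipy.io.mmwrite(str(directory / "matrix.mtx"), mtx, field="integer")

    _write_text(directory / f"barcodes.tsv{suffix}", list(ds.spot_ids), use_gzip)
    _write_text(
        directory / f"features.tsv{suffix}",
        [f"{g}\t{g}\tGene Expression" for g in ds.gene_ids],
        use_gzip,
    )

    meta = ds.spot_meta
    if not {"array_row", "array_col"}.issubset(meta.columns):
        raise ValueError("spot_meta lacks array_row/array_col; cannot write Visium dialect")
    in_tissue = (
        meta["in_tissue"].to_numpy().astype(int)
        if "in_tissue" in meta.columns
        else np.ones(ds.n_spots, dtype=int)
    )
    positions = pd.DataFrame(
        {
            "barcode": ds.spot_ids,
            "in_tissue": in_tissue,
            "array_row": meta["array_row"].to_numpy().astype(int),
            "array_col": meta["array_col"].to_numpy().astype(int),
            "pixel_row": np.round(ds.coords[:, 1] * 100).astype(int),
            "pixel_col": np.round(ds.coords[:, 0] * 100).astype(int),
        }
    )
    positions.to_csv(directory / "spatial" / "tissue_positions.csv", index=False)
    return directory


def write_csv_pair(ds: SpatialDataset, counts_path, meta_path) -> None:
    """Write the CSV dialect: counts (spots × genes) and x/y metadata."""
    pd.DataFrame(
        ds.counts_dense(), index=ds.spot_ids, columns=ds.gene_ids
    ).to_csv(counts_path)
    pd.DataFrame(
        {"x": ds.coords[:, 0], "y": ds.coords[:, 1]}, index=ds.spot_ids
    ).to_csv(meta_path)
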