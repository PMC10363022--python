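import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from spassoc import SpatialDataset, build_knn_weights, normalize_logcpm, qc_filter
from spassoc import simulate as sim

settings.register_profile("default", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("default")


def processed(ds: SpatialDataset) -> SpatialDataset:
    """Minimal QC + log-CPM for synthetic fixtures (keep everything nonzero)."""
    return normalize_logcpm(qc_filter(ds, min_spots_per_gene=1, min_umi_per_spot=1))


@pytest.fixture(scope="session")
def coloc_ds() -> SpatialDataset:
    """Two genes sharing one planted bump plus 18 noise genes, 20x20 lattice."""
    return processed(sim.standard_pair_fixture("colocalized", seed=11))


@pytest.fixture(scope="session")
def coloc_weights(coloc_ds):
    return build_knn_weights(coloc_ds.coords, k=6)


@pytest.fixture()
def small_ds() -> SpatialDataset:
    """Deterministic 12-spot, 4-gene dataset on a 3x4 lattice."""
    rng = np.random.default_rng(7)
    lattice = sim.make_lattice(3, 4)
    counts = rng.integers(1, 40, size=(12, 4))
    ds = SpatialDataset(
        counts=counts,
        coords=lattice,
        gene_ids=[f"g{i}" for i in range(4)],
        spot_ids=[f"s{i}" for i in range(12)],
    )
    return normalize_logcpm(ds)


@pytest.fixture()
def qc_fixture() -> SpatialDataset:
    """Hand-countable QC example: 20 spots x 5 genes.

    Gene g4 is detected in only 3 spots; spot s7 totals 40 UMI; every other
    gene is detected in all 20 spots and every other spot totals >= 150 UMI.
    Default QC must therefore return shape (19, 4).
    """
    counts = np.full((20, 5), 50, dtype=int)
    counts[:, 4] = 0
    counts[[0, 1, 2], 4] = 5     # g4 in 3 spots only
    counts[7, :4] = 10           # s7 total = 40
    counts[7, 4] = 0
    return SpatialDataset(
        counts=counts,
        coords=sim.make_lattice(4, 5),
        gene_ids=[f"g{i}" for i in range(5)],
        spot_ids=[f"s{i}" for i in range(20)],
    )


def random_geometry(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random spot coordinates in general position (no distance ties)."""
    return rng.uniform(0, 10, size=(n, 2)) + rng.normal(0, 1e-3, size=(n, 2))


def expression_frame(ds) -> pd.DataFrame:
    return pd.DataFrame(ds.layers["logcpm"], index=ds.spot_ids, columns=ds.gene_ids)
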