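import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spassoc import (
    SpatialDataset,
    build_knn_weights,
    global_l,
    local_l,
    pairwise_association,
)
from spassoc import simulate as sim
from spassoc.weights import SpatialWeights
from conftest import processed, random_geometry
from oracles import bh_brute, global_l_brute, local_l_brute


def _noise_ds(n: int, m: int, seed: int) -> SpatialDataset:
    rng = np.random.default_rng(seed)
    return SpatialDataset(
        np.ones((n, m), dtype=int),
        coords=random_geometry(rng, n),
        gene_ids=[f"g{i}" for i in range(m)],
        spot_ids=[f"s{i}" for i in range(n)],
        layers={"logcpm": rng.normal(size=(n, m))},
    )


class TestLocalL:
    def test_self_pair_is_squared_lag(self, coloc_ds, coloc_weights):
        x = coloc_ds.layers["logcpm"][:, 0]
        field = local_l(x, x, coloc_weights)
        assert (field.values >= 0).all()

    def test_negation_antisymmetry(self, coloc_ds, coloc_weights):
        x = coloc_ds.layers["logcpm"][:, 0]
        y = coloc_ds.layers["logcpm"][:, 1]
        plus = local_l(x, y, coloc_weights)
        minus = local_l(x, -y, coloc_weights)
        np.testing.assert_allclose(minus.values, -plus.values, atol=1e-12)

    def test_four_spot_path_matches_brute_force(self):
        coords = np.array([[0.0, 0], [1.0, 0], [2.0, 0], [3.0, 0]])
        w = build_knn_weights(coords, k=1)
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([4.0, 3.0, 2.0, 1.0])
        field = local_l(x, y, w)
        np.testing.assert_allclose(
            field.values, local_l_brute(x, y, w.w.toarray()), atol=1e-10
        )

    def test_constant_input_errors(self, coloc_weights):
        n = coloc_weights.n_spots
        with pytest.raises(ValueError, match="zero variance"):
            local_l(np.ones(n), np.arange(n, dtype=float), coloc_weights)

    def test_length_mismatch_errors(self, coloc_weights):
        with pytest.raises(ValueError, match="mismatch"):
            local_l(np.arange(3.0), np.arange(3.0), coloc_weights)

    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_equivalence_random_small_lattices(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(8, 31))
        w = build_knn_weights(random_geometry(rng, n), k=int(rng.integers(1, 4)))
        x, y = rng.normal(size=(2, n))
        field = local_l(x, y, w)
        np.testing.assert_allclose(field.values, local_l_brute(x, y, w.w.toarray()), atol=1e-10)
        assert global_l(field) == pytest.approx(global_l_brute(x, y, w.w.toarray()), abs=1e-10)


class TestGlobalL:
    def test_identity_weights_reduce_to_pearson(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=(2, 50))
        w = SpatialWeights.identity_like(50)
        assert global_l(local_l(x, y, w)) == pytest.approx(
            np.corrcoef(x, y)[0, 1], abs=1e-12
        )

    def test_identity_weights_self_pair_is_one(self):
        x = np.random.default_rng(6).normal(size=30)
        w = SpatialWeights.identity_like(30)
        assert global_l(local_l(x, x, w)) == pytest.approx(1.0, abs=1e-12)

    def test_empty_field_errors(self):
        from spassoc.lindex import LocalLField

        with pytest.raises(ValueError, match="empty"):
            global_l(LocalLField(values=np.array([]), pair=("a", "b")))

    @pytest.mark.parametrize("seed", range(20))
    def test_shared_bump_gives_strong_positive_l(self, seed):
        """Two genes on one planted bump: global L > 0.5 on every seed."""
        ds = processed(sim.standard_pair_fixture("colocalized", seed=seed))
        w = build_knn_weights(ds.coords, k=6)
        x, y = ds.layers["logcpm"][:, 0], ds.layers["logcpm"][:, 1]
        assert global_l(local_l(x, y, w)) > 0.5

    @given(seed=st.integers(0, 200))
    def test_symmetry_and_cauchy_schwarz_bound(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 60))
        w = build_knn_weights(random_geometry(rng, n), k=3)
        x, y = rng.normal(size=(2, n))
        lxy = global_l(local_l(x, y, w))
        lyx = global_l(local_l(y, x, w))
        assert lxy == lyx
        lxx = global_l(local_l(x, x, w))
        lyy = global_l(local_l(y, y, w))
        assert abs(lxy) <= np.sqrt(lxx * lyy) + 1e-12
        assert abs(lxy) <= 1 + 1e-12


class TestPairwiseAssociation:
    def test_mean_of_local_identity(self, coloc_ds, coloc_weights):
        names = list(coloc_ds.gene_ids[:5])
        assoc = pairwise_association(
            coloc_ds, names, coloc_weights, n_permutations=19, seed=0
        )
        np.testing.assert_allclose(
            assoc.local_l.mean(axis=0), assoc.global_l, atol=1e-10
        )

    def test_p_floor_when_observed_exceeds_all_permutations(self):
        ds = processed(sim.standard_pair_fixture("colocalized", seed=1))
        w = build_knn_weights(ds.coords, k=6)
        assoc = pairwise_association(ds, ["a", "b"], w, n_permutations=99, seed=4)
        assert assoc.p_value[0] == pytest.approx(1 / 100)

    def test_q_matches_bh_oracle(self, coloc_ds, coloc_weights):
        names = list(coloc_ds.gene_ids[:6])
        assoc = pairwise_association(
            coloc_ds, names, coloc_weights, n_permutations=49, seed=2
        )
        np.testing.assert_allclose(assoc.q_value, bh_brute(assoc.p_value), atol=1e-12)

    def test_bh_step_up_hand_example(self):
        """m=10 raw p = 0.001..0.010 all adjust to exactly 0.01."""
        p = np.arange(1, 11) / 1000
        np.testing.assert_allclose(bh_brute(p), np.full(10, 0.01), atol=1e-15)
        from statsmodels.stats.multitest import multipletests

        np.testing.assert_allclose(
            multipletests(p, method="fdr_bh")[1], bh_brute(p), atol=1e-12
        )

    def test_seed_reproducibility_bitwise(self, coloc_ds, coloc_weights):
        names = list(coloc_ds.gene_ids[:4])
        a = pairwise_association(coloc_ds, names, coloc_weights, n_permutations=99, seed=7)
        b = pairwise_association(coloc_ds, names, coloc_weights, n_permutations=99, seed=7)
        assert (a.p_value == b.p_value).all() and (a.q_value == b.q_value).all()

    def test_different_seeds_change_null(self, coloc_ds, coloc_weights):
        names = list(coloc_ds.gene_ids[2:8])  # noise genes
        a = pairwise_association(coloc_ds, names, coloc_weights, n_permutations=99, seed=1)
        b = pairwise_association(coloc_ds, names, coloc_weights, n_permutations=99, seed=2)
        assert (a.p_value != b.p_value).any()

    def test_seed_mandatory(self, coloc_ds, coloc_weights):
        with pytest.raises(ValueError, match="seed"):
            pairwise_association(coloc_ds, ["a", "b"], coloc_weights, n_permutations=9)

    def test_invalid_permutation_count(self, coloc_ds, coloc_weights):
        with pytest.raises(ValueError, match="n_permutations"):
            pairwise_association(coloc_ds, ["a", "b"], coloc_weights, n_permutations=0, seed=1)

    def test_constant_variable_skipped_with_warning(self, coloc_weights, caplog):
        n = coloc_weights.n_spots
        rng = np.random.default_rng(3)
        ds = SpatialDataset(
            np.ones((n, 3), dtype=int),
            coords=np.zeros((n, 2)),
            gene_ids=["ga", "gb", "gflat"],
            spot_ids=[f"s{i}" for i in range(n)],
            layers={"logcpm": np.column_stack([rng.normal(size=(n, 2)), np.ones(n)])},
        )
        with caplog.at_level("WARNING"):
            assoc = pairwise_association(ds, ["ga", "gb", "gflat"], coloc_weights,
                                         n_permutations=9, seed=0)
        assert assoc.skipped == ["gflat"]
        assert assoc.pairs == [("ga", "gb")]

    def test_perm_mode_single_supported(self, coloc_ds, coloc_weights):
        assoc = pairwise_association(
            coloc_ds, ["a", "b"], coloc_weights,
            n_permutations=99, seed=0, perm_mode="single",
        )
        assert assoc.p_value[0] <= 0.05  # planted signal survives either null

    @pytest.mark.parametrize("layout,sign", [("colocalized", 1), ("exclusive", -1)])
    def test_sign_recovery_planted_patterns(self, layout, sign):
        """Colocalized pairs give L > 0, exclusive pairs L < 0, across 20 seeds."""
        for seed in range(20):
            ds = processed(sim.standard_pair_fixture(layout, seed=seed))
            w = build_knn_weights(ds.coords, k=6)
            assoc = pairwise_association(ds, ["a", "b"], w, n_permutations=19, seed=seed)
            assert sign * assoc.global_l[0] > 0
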