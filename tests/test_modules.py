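import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from spassoc import build_knn_weights, detect_modules, module_scores, morans_i, pairwise_association
from spassoc import simulate as sim
from spassoc.lindex import AssociationResult
from conftest import processed


def _assoc_from_matrix(lmat: np.ndarray, names: list[str]) -> AssociationResult:
    """Wrap a hand-built symmetric global-L matrix as an association result."""
    pairs, values = [], []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pairs.append((names[i], names[j]))
            values.append(lmat[i, j])
    k = len(pairs)
    return AssociationResult(
        pairs=pairs,
        global_l=np.asarray(values, dtype=float),
        p_value=np.full(k, 0.01),
        q_value=np.full(k, 0.01),
        local_l=np.zeros((2, k)),
        n_permutations=9,
        seed=0,
        names=list(names),
    )


def _planted_assoc(seed: int):
    lattice = sim.make_lattice(20, 20)
    ds, truth = sim.plant_modules(lattice, n_modules=3, genes_per_module=10, seed=seed)
    ds = processed(ds)
    w = build_knn_weights(ds.coords, k=6)
    assoc = pairwise_association(ds, list(ds.gene_ids), w, n_permutations=19, seed=seed)
    return ds, truth, assoc


class TestDetectModules:
    def test_two_ideal_blocks(self):
        """Within-block L = 1, between -1: k=2 selected with silhouette 1."""
        names = [f"g{i}" for i in range(6)]
        lmat = -np.ones((6, 6))
        lmat[:3, :3] = 1.0
        lmat[3:, 3:] = 1.0
        result = detect_modules(_assoc_from_matrix(lmat, names))
        assert result.k_selected == 2
        assert dict(result.silhouette_trace)[2] == pytest.approx(1.0)
        assert set(result.genes_in("m0")) in ({"g0", "g1", "g2"}, {"g3", "g4", "g5"})

    def test_forced_k_returns_exactly_k(self):
        rng = np.random.default_rng(0)
        names = [f"g{i}" for i in range(8)]
        lmat = rng.uniform(-0.5, 0.5, size=(8, 8))
        lmat = (lmat + lmat.T) / 2
        np.fill_diagonal(lmat, 1.0)
        result = detect_modules(_assoc_from_matrix(lmat, names), k_min=4, k_max=4)
        assert result.k_selected == 4
        assert len(set(result.labels)) == 4
        assert len(result.silhouette_trace) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_planted_partition_recovered(self, seed):
        """3 planted modules x 10 genes: k=3 and perfect label agreement."""
        _, truth, assoc = _planted_assoc(seed)
        result = detect_modules(assoc)
        assert result.k_selected == 3
        assert adjusted_rand_score(truth.loc[result.labels.index], result.labels) == 1.0

    def test_gene_order_invariance(self, coloc_ds, coloc_weights):
        names = sorted(coloc_ds.gene_ids[:8])
        assoc_fwd = pairwise_association(coloc_ds, names, coloc_weights, n_permutations=9, seed=0)
        assoc_rev = pairwise_association(coloc_ds, names[::-1], coloc_weights, n_permutations=9, seed=0)
        a = detect_modules(assoc_fwd, k_max=4)
        b = detect_modules(assoc_rev, k_max=4)
        assert (a.labels.sort_index() == b.labels.sort_index()).all()

    def test_silhouette_trace_bounded(self):
        _, _, assoc = _planted_assoc(3)
        result = detect_modules(assoc)
        values = [s for _, s in result.silhouette_trace if np.isfinite(s)]
        assert all(-1 <= s <= 1 for s in values)
        best = max(values)
        assert dict(result.silhouette_trace)[result.k_selected] == best

    def test_module_ids_ordered_by_size(self):
        names = [f"g{i}" for i in range(7)]
        lmat = -np.ones((7, 7))
        lmat[:5, :5] = 1.0   # big module first
        lmat[5:, 5:] = 1.0
        np.fill_diagonal(lmat, 1.0)
        result = detect_modules(_assoc_from_matrix(lmat, names))
        assert len(result.genes_in("m0")) == 5
        assert len(result.genes_in("m1")) == 2

    def test_too_few_genes_fails(self):
        lmat = np.array([[1.0, 0.2], [0.2, 1.0]])
        with pytest.raises(ValueError, match="at least 3"):
            detect_modules(_assoc_from_matrix(lmat, ["a", "b"]))

    def test_degenerate_distance_fails(self):
        lmat = np.full((4, 4), 0.5)
        np.fill_diagonal(lmat, 1.0)
        with pytest.raises(ValueError, match="degenerate"):
            detect_modules(_assoc_from_matrix(lmat, list("abcd")))

    def test_incomplete_pair_coverage_fails(self):
        assoc = _assoc_from_matrix(np.eye(4), list("abcd"))
        assoc.pairs = assoc.pairs[:-1]
        with pytest.raises(ValueError, match="pairs"):
            detect_modules(assoc)


class TestModuleScores:
    def test_single_gene_module_score_is_zscore(self):
        ds, truth, assoc = _planted_assoc(4)
        result = detect_modules(assoc)
        # shrink one module to a single gene by reassigning labels
        gene = result.genes_in("m0")[0]
        from spassoc.modules import ModuleAssignment
        import pandas as pd

        single = ModuleAssignment(
            labels=pd.Series({gene: "m0"}, name="module"),
            k_selected=1, silhouette_trace=[(1, float("nan"))], linkage_method="average",
        )
        module_scores(ds, single)
        x = ds.layers["logcpm"][:, list(ds.gene_ids).index(gene)]
        np.testing.assert_allclose(
            ds.layers["module_scores"][:, 0], (x - x.mean()) / x.std(), atol=1e-12
        )

    def test_planted_module_scores_spatially_variable(self):
        ds, _, assoc = _planted_assoc(5)
        result = detect_modules(assoc)
        module_scores(ds, result)
        w = build_knn_weights(ds.coords, k=6)
        for j in range(ds.layers["module_scores"].shape[1]):
            assert morans_i(ds.layers["module_scores"][:, j], w) > 0.3

    def test_module_pair_sign_structure(self):
        """Disjoint planted modules are mutually exclusive: negative pairwise L."""
        ds, _, assoc = _planted_assoc(6)
        result = detect_modules(assoc)
        module_scores(ds, result)
        w = build_knn_weights(ds.coords, k=6)
        mod_assoc = pairwise_association(
            ds, ds.uns["module_names"], w, n_permutations=19, seed=0, layer="module_scores"
        )
        assert (mod_assoc.global_l < 0).all()
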