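import numpy as np
import pytest

from oncorepurpose.chem import Molecule
from oncorepurpose.features import (
    DegenerateInputError,
    amfp_score,
    build_feature_table,
    fit_amfp,
    fit_pca,
    impute_features,
    pca_project,
)
from oncorepurpose.matrices import from_entries


def _dti_from_dense(dense, prefix="d"):
    n, t = dense.shape
    rows = [f"{prefix}{i}" for i in range(n)]
    cols = [f"t{j}" for j in range(t)]
    entries = [(rows[i], cols[j]) for i, j in zip(*np.nonzero(dense))]
    return from_entries(rows, cols, entries, "DTI")


def _planted_two_block(n=200, p_in=0.3, p_out=0.02, seed=0):
    rng = np.random.default_rng(seed)
    comm = np.array([0] * (n // 2) + [1] * (n - n // 2))
    ids = [f"N{i:03d}" for i in range(n)]
    edges = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < (p_in if comm[i] == comm[j] else p_out)
    ]
    return ids, comm, edges


class TestPca:
    def test_rank_one_data_explains_everything(self):
        base = np.array([1, 0, 1, 0, 1], dtype=float)
        dense = np.outer([1, 0, 1, 1, 0, 1], base)
        model = fit_pca(_dti_from_dense(dense), k=1)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_full_rank_cumulative_ratio_is_one(self, rng):
        dense = (rng.random((12, 6)) < 0.4).astype(float)
        model = fit_pca(_dti_from_dense(dense), k=6)
        assert model.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-8)

    def test_ratios_match_eigendecomposition_oracle(self, rng):
        """Top-k variance ratios equal covariance eigenvalues / trace."""
        dense = (rng.random((50, 30)) < 0.3).astype(float)
        model = fit_pca(_dti_from_dense(dense), k=10)
        cov = np.cov(dense, rowvar=False, ddof=1)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        expected = eig[:10] / eig.sum()
        np.testing.assert_allclose(
            model.explained_variance_ratio, expected, atol=1e-6
        )

    def test_components_orthonormal(self, rng):
        dense = (rng.random((40, 20)) < 0.3).astype(float)
        model = fit_pca(_dti_from_dense(dense), k=8)
        gram = model.components @ model.components.T
        np.testing.assert_allclose(gram, np.eye(8), atol=1e-6)

    def test_mean_row_projects_to_zero(self, rng):
        dense = (rng.random((30, 10)) < 0.5).astype(float)
        model = fit_pca(_dti_from_dense(dense), k=3)
        np.testing.assert_allclose(
            pca_project(model, model.mean), np.zeros(3), atol=1e-10
        )

    def test_projection_matches_dense_oracle(self, rng):
        dense = (rng.random((30, 10)) < 0.5).astype(float)
        model = fit_pca(_dti_from_dense(dense), k=4)
        row = dense[3]
        np.testing.assert_allclose(
            pca_project(model, row), model.components @ (row - model.mean),
            atol=1e-12,
        )

    def test_reconstruction_error_decreases_with_k(self, rng):
        dense = (rng.random((25, 12)) < 0.4).astype(float)
        dti = _dti_from_dense(dense)
        errors = []
        for k in (2, 5, 9):
            model = fit_pca(dti, k=k)
            proj = (dense - model.mean) @ model.components.T
            recon = model.mean + proj @ model.components
            errors.append(np.sum((dense - recon) ** 2))
        assert errors[0] >= errors[1] >= errors[2]

    def test_degenerate_inputs_rejected(self):
        zero = _dti_from_dense(np.zeros((4, 3)))
        with pytest.raises(DegenerateInputError):
            fit_pca(zero, k=2)
        ok = _dti_from_dense(np.eye(4, 3))
        with pytest.raises(ValueError):
            fit_pca(ok, k=5)


class TestAmfp:
    def test_zero_propagation_returns_raw_embeddings(self):
        ids, _, edges = _planted_two_block(n=40, seed=1)
        ddi = from_entries(ids, ids, [(ids[i], ids[j]) for i, j in edges], "DDI")
        model = fit_amfp(ddi, d=8, epochs=20, propagation_weight=0.0, seed=0)
        np.testing.assert_array_equal(model.embeddings, model.raw_embeddings)

    def test_score_symmetric_and_in_open_unit_interval(self):
        ids, _, edges = _planted_two_block(n=40, seed=1)
        ddi = from_entries(ids, ids, [(ids[i], ids[j]) for i, j in edges], "DDI")
        model = fit_amfp(ddi, d=8, epochs=20, seed=0)
        for a, b in [(ids[0], ids[1]), (ids[3], ids[30])]:
            s = amfp_score(model, a, b)
            assert s == amfp_score(model, b, a)
            assert 0.0 < s < 1.0

    def test_unknown_id_rejected(self):
        ids, _, edges = _planted_two_block(n=20, seed=1)
        ddi = from_entries(ids, ids, [(ids[i], ids[j]) for i, j in edges], "DDI")
        model = fit_amfp(ddi, d=4, epochs=5, seed=0)
        with pytest.raises(KeyError):
            amfp_score(model, ids[0], "ghost")

    def test_seeded_runs_reproducible(self):
        ids, _, edges = _planted_two_block(n=40, seed=1)
        ddi = from_entries(ids, ids, [(ids[i], ids[j]) for i, j in edges], "DDI")
        m1 = fit_amfp(ddi, d=8, epochs=10, seed=3)
        m2 = fit_amfp(ddi, d=8, epochs=10, seed=3)
        np.testing.assert_array_equal(m1.embeddings, m2.embeddings)

    def test_within_block_scores_exceed_between_block(self):
        ids, comm, edges = _planted_two_block(n=100, seed=2)
        ddi = from_entries(ids, ids, [(ids[i], ids[j]) for i, j in edges], "DDI")
        model = fit_amfp(ddi, d=16, epochs=150, seed=0)
        z, b, c = model.embeddings, model.bias, model.global_bias
        logits = z @ z.T + b[:, None] + b[None, :] + c
        iu = np.triu_indices(len(ids), 1)
        same = comm[iu[0]] == comm[iu[1]]
        assert logits[iu][same].mean() > logits[iu][~same].mean()

    def test_community_cosine_separation_over_seeds(self):
        """Within-community embedding cosine exceeds between, 3 seeds."""
        ids, comm, edges = _planted_two_block(n=100, seed=4)
        ddi = from_entries(ids, ids, [(ids[i], ids[j]) for i, j in edges], "DDI")
        gaps = []
        for seed in (0, 1, 2):
            model = fit_amfp(ddi, d=16, epochs=150, seed=seed)
            e = model.embeddings
            e = e / np.linalg.norm(e, axis=1, keepdims=True)
            cos = e @ e.T
            iu = np.triu_indices(len(ids), 1)
            same = comm[iu[0]] == comm[iu[1]]
            gaps.append(cos[iu][same].mean() - cos[iu][~same].mean())
        assert np.mean(gaps) > 0

    def test_single_edge_pair_scores_above_median_nonedge(self):
        ids = [f"N{i}" for i in range(8)]
        ddi = from_entries(ids, ids, [("N0", "N1")], "DDI")
        model = fit_amfp(ddi, d=2, epochs=200, seed=0)
        edge_score = amfp_score(model, "N0", "N1")
        non_edges = [
            amfp_score(model, ids[i], ids[j])
            for i in range(8) for j in range(i + 1, 8)
            if (i, j) != (0, 1)
        ]
        assert edge_score > np.median(non_edges)

    def test_empty_graph_rejected(self):
        ddi = from_entries(["a", "b"], ["a", "b"], [], "DDI")
        with pytest.raises(DegenerateInputError):
            fit_amfp(ddi, d=2)


class TestImputation:
    @pytest.fixture
    def store(self):
        return {
            "dti": {"known1": np.array([1.0, 2.0]), "known2": np.array([3.0, 4.0])},
            "ddi": {"known1": np.array([5.0, 6.0, 7.0])},
        }

    library = [Molecule("known1", "c1ccccc1"), Molecule("known2", "CCCCCC")]

    def test_direct_blocks_used_when_present(self, store):
        feats = impute_features(Molecule("known1", "c1ccccc1"), store, self.library)
        assert feats.dti_provenance.mode == "direct"
        assert feats.ddi_provenance.mode == "direct"

    def test_identical_neighbor_copied_verbatim(self, store):
        # benzene written differently: similarity 1.0 to known1
        feats = impute_features(Molecule("new", "C1=CC=CC=C1"), store, self.library)
        assert feats.dti_provenance.mode == "neighbor"
        assert feats.dti_provenance.neighbor_id == "known1"
        assert feats.dti_provenance.similarity == 1.0
        np.testing.assert_array_equal(feats.dti_block, store["dti"]["known1"])
        np.testing.assert_array_equal(feats.ddi_block, store["ddi"]["known1"])

    def test_isolated_molecule_receives_column_means(self, store):
        feats = impute_features(Molecule("odd", "C#N"), store, self.library)
        assert feats.dti_provenance.mode == "average"
        assert feats.ddi_provenance.mode == "average"
        np.testing.assert_allclose(feats.dti_block, [2.0, 3.0])
        np.testing.assert_allclose(feats.ddi_block, [5.0, 6.0, 7.0])

    def test_blocks_imputed_independently(self, store):
        """DTI present, DDI missing with a qualifying neighbour."""
        feats = impute_features(Molecule("known2", "CCCCCC"), store, self.library)
        assert feats.dti_provenance.mode == "direct"
        assert feats.ddi_provenance.mode == "average"  # hexane ~ benzene < 0.7

    def test_average_within_min_max_bounds(self, rng):
        store = {
            "dti": {f"m{i}": rng.random(4) for i in range(6)},
            "ddi": {f"m{i}": rng.random(3) for i in range(6)},
        }
        feats = impute_features(Molecule("q", "C#N"), store, [])
        for name in ("dti", "ddi"):
            stacked = np.stack(list(store[name].values()))
            block = feats.dti_block if name == "dti" else feats.ddi_block
            assert np.all(block >= stacked.min(axis=0) - 1e-12)
            assert np.all(block <= stacked.max(axis=0) + 1e-12)

    def test_empty_store_rejected(self):
        with pytest.raises(ValueError):
            impute_features(Molecule("q", "CC"), {"dti": {}, "ddi": {}}, [])


class TestFeatureTable:
    def test_masked_ids_predict_provenance_pattern(self, small_bundle):
        """Exactly the generator-masked drugs get non-direct provenance."""
        b = small_bundle
        pca = fit_pca(b.dti, k=8)
        amfp = fit_amfp(b.ddi, d=16, epochs=30, seed=0)
        table = build_feature_table(b.molecules, b.dti, b.ddi, pca, amfp)
        masked_dti = set(b.ground_truth.masked_dti_ids)
        masked_ddi = set(b.ground_truth.masked_ddi_ids)
        for drug_id, feats in table.items():
            assert (feats.dti_provenance.mode != "direct") == (drug_id in masked_dti)
            assert (feats.ddi_provenance.mode != "direct") == (drug_id in masked_ddi)

    def test_vector_length_is_block_sum(self, small_bundle):
        b = small_bundle
        pca = fit_pca(b.dti, k=8)
        amfp = fit_amfp(b.ddi, d=16, epochs=30, seed=0)
        table = build_feature_table(b.molecules, b.dti, b.ddi, pca, amfp)
        assert all(f.vector.shape == (24,) for f in table.values())
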