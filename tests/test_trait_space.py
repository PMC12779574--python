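import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from avistability.datamodel import DIET_NAMES, MORPHOMETRIC_NAMES
from avistability.trait_space import (
    embed_3d,
    mixed_trait_dissimilarity,
    two_step_pca,
)


def _toy_morph(n=6, seed=3):
    rng = np.random.default_rng(seed)
    size = rng.standard_normal(n)
    x = np.exp(2.0 + 0.3 * size[:, None] + 0.1 * rng.standard_normal((n, 7)))
    return pd.DataFrame(
        x, columns=list(MORPHOMETRIC_NAMES), index=[f"s{i}" for i in range(n)]
    )


def _toy_hwi(index, seed=4):
    rng = np.random.default_rng(seed)
    return pd.Series(np.exp(3 + 0.3 * rng.standard_normal(len(index))), index=index)


class TestTwoStepPca:
    def test_identical_species_get_identical_scores(self):
        m = _toy_morph(5)
        m.iloc[1] = m.iloc[0]
        hwi = _toy_hwi(m.index)
        hwi.iloc[1] = hwi.iloc[0]
        axes = two_step_pca(m, hwi)
        for arr in (axes.trophic, axes.locomotory, axes.size, axes.dispersal):
            assert arr[0] == pytest.approx(arr[1], abs=1e-10)

    def test_size_axis_tracks_first_components(self, species_pool):
        """The size axis strongly correlates with both group first components."""
        m = species_pool[list(MORPHOMETRIC_NAMES)]
        axes = two_step_pca(m, species_pool["hwi"])
        z = stats.zscore(np.log(m.to_numpy()), axis=0)
        for block in (z[:, :4], z[:, 4:]):
            cov = np.cov(block, rowvar=False)
            w, v = np.linalg.eigh(cov)
            pc1 = (block - block.mean(axis=0)) @ v[:, np.argmax(w)]
            r = abs(np.corrcoef(axes.size, pc1)[0, 1])
            assert r > 0.7

    def test_matches_eigendecomposition_oracle(self):
        """Axis scores equal an independent covariance-eigendecomposition, up to sign."""
        m = _toy_morph(6)
        axes = two_step_pca(m, _toy_hwi(m.index))
        z = stats.zscore(np.log(m.to_numpy()), axis=0)

        def pc(block, k):
            cov = np.cov(block, rowvar=False)
            w, v = np.linalg.eigh(cov)
            order = np.argsort(w)[::-1]
            return (block - block.mean(axis=0)) @ v[:, order[k]]

        for got, exp in [
            (axes.trophic, pc(z[:, :4], 1)),
            (axes.locomotory, pc(z[:, 4:], 1)),
            (axes.size, pc(np.column_stack([pc(z[:, :4], 0), pc(z[:, 4:], 0)]), 0)),
        ]:
            err = min(np.abs(got - exp).max(), np.abs(got + exp).max())
            assert err < 1e-10

    def test_row_order_invariance(self):
        m = _toy_morph(8)
        hwi = _toy_hwi(m.index)
        a = two_step_pca(m, hwi)
        perm = np.random.default_rng(0).permutation(len(m))
        b = two_step_pca(m.iloc[perm], hwi)
        bf = b.frame().loc[a.frame().index]
        pd.testing.assert_frame_equal(a.frame(), bf, atol=1e-10, rtol=0)

    def test_degenerate_table_raises(self):
        m = _toy_morph(5)
        m.iloc[:] = m.iloc[0].to_numpy()
        with pytest.raises(ValueError, match="degenerate"):
            two_step_pca(m, _toy_hwi(m.index))

    def test_axes_are_centred(self, species_pool):
        axes = two_step_pca(
            species_pool[list(MORPHOMETRIC_NAMES)], species_pool["hwi"]
        )
        for arr in (axes.trophic, axes.locomotory, axes.size, axes.dispersal):
            assert abs(arr.mean()) < 1e-9


def _diets(index, rows):
    return pd.DataFrame(rows, columns=list(DIET_NAMES), index=index)


def _axes_for(ids, mat):
    from avistability.trait_space import NicheAxes

    mat = np.asarray(mat, dtype=float)
    return NicheAxes(list(ids), mat[:, 0], mat[:, 1], mat[:, 2], mat[:, 3])


class TestMixedTraitDissimilarity:
    def test_identical_species_distance_zero(self):
        ids = ["a", "b", "c", "d"]
        mat = np.arange(16).reshape(4, 4) * 1.0
        mat[1] = mat[0]
        diets = _diets(ids, np.tile(np.eye(9)[0], (4, 1)))
        diets.iloc[2] = diets.iloc[3] = np.eye(9)[1]
        d = mixed_trait_dissimilarity(_axes_for(ids, mat), diets)
        assert d.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_pure_diet_difference_is_one_fifth(self):
        """Equal axes, disjoint pure diets: distance = 1/5 of the maximum."""
        ids = ["a", "b", "c", "d"]
        mat = np.array([[0, 0, 0, 0], [0, 0, 0, 0], [1, 1, 1, 1], [2, 2, 2, 2.0]])
        rows = np.zeros((4, 9))
        rows[0, DIET_NAMES.index("frugivore")] = 1.0
        rows[1, DIET_NAMES.index("granivore")] = 1.0
        rows[2, DIET_NAMES.index("frugivore")] = 1.0
        rows[3, DIET_NAMES.index("granivore")] = 1.0
        d = mixed_trait_dissimilarity(_axes_for(ids, mat), _diets(ids, rows))
        # a vs b differ only in diet (total-variation 1), so 1/5 under equal weights
        assert d.loc["a", "b"] == pytest.approx(0.2, abs=1e-12)

    def test_metric_axioms_random_input(self, rng):
        ids = [f"s{i}" for i in range(10)]
        mat = rng.standard_normal((10, 4))
        diets = _diets(ids, rng.dirichlet(np.ones(9), size=10))
        d = mixed_trait_dissimilarity(_axes_for(ids, mat), diets).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert d.min() >= 0 and d.max() <= 1 + 1e-12

    def test_diet_category_relabelling_invariance(self, rng):
        ids = [f"s{i}" for i in range(6)]
        mat = rng.standard_normal((6, 4))
        rows = rng.dirichlet(np.ones(9), size=6)
        perm = rng.permutation(9)
        d1 = mixed_trait_dissimilarity(_axes_for(ids, mat), _diets(ids, rows))
        d2 = mixed_trait_dissimilarity(_axes_for(ids, mat), _diets(ids, rows[:, perm]))
        np.testing.assert_allclose(d1.to_numpy(), d2.to_numpy(), atol=1e-12)

    def test_zero_range_axis_dropped_with_warning(self, rng):
        ids = [f"s{i}" for i in range(5)]
        mat = rng.standard_normal((5, 4))
        mat[:, 2] = 1.0  # constant size axis
        diets = _diets(ids, rng.dirichlet(np.ones(9), size=5))
        with pytest.warns(UserWarning, match="dropped"):
            d = mixed_trait_dissimilarity(_axes_for(ids, mat), diets, zscore_axes=False)
        assert np.isfinite(d.to_numpy()).all()

    def test_balanced_weights_equalise_correlations(self, rng):
        ids = [f"s{i}" for i in range(15)]
        mat = rng.standard_normal((15, 4)) * np.array([5.0, 1.0, 0.2, 1.0])
        diets = _diets(ids, rng.dirichlet(np.ones(9) * 0.5, size=15))
        d = mixed_trait_dissimilarity(
            _axes_for(ids, mat), diets, weighting="balanced"
        )
        assert np.allclose(d.to_numpy(), d.to_numpy().T)
        assert d.to_numpy().max() <= 1 + 1e-9


class TestEmbed3d:
    def test_tetrahedron_recovers_equal_distances(self):
        ids = list("abcd")
        d = pd.DataFrame(1.0 - np.eye(4), index=ids, columns=ids)
        emb = embed_3d(d)
        rec = pdist(emb.coords)
        assert rec.std() < 1e-9

    def test_euclidean_configuration_round_trips(self, rng):
        pts = rng.standard_normal((8, 3))
        ids = [f"p{i}" for i in range(8)]
        d = pd.DataFrame(squareform(pdist(pts)), index=ids, columns=ids)
        emb = embed_3d(d)
        np.testing.assert_allclose(squareform(pdist(emb.coords)), d.to_numpy(), atol=1e-8)
        assert emb.embedding_quality == pytest.approx(1.0, abs=1e-9)
        assert emb.cailliez_constant == 0.0

    def test_matches_skbio_pcoa(self, rng):
        """Coordinates agree with an independent PCoA implementation up to sign."""
        skbio = pytest.importorskip("skbio")
        pts = rng.standard_normal((10, 5))
        d = squareform(pdist(pts))
        ids = [f"p{i}" for i in range(10)]
        emb = embed_3d(pd.DataFrame(d, index=ids, columns=ids))
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d, ids))
        ref_coords = ref.samples.iloc[:, :3].to_numpy()
        for k in range(3):
            err = min(
                np.abs(emb.coords[:, k] - ref_coords[:, k]).max(),
                np.abs(emb.coords[:, k] + ref_coords[:, k]).max(),
            )
            assert err < 1e-6

    def test_rank_correlation_on_gower_input(self, rng):
        """Embedded distances preserve the ordering of non-Euclidean dissimilarities."""
        ids = [f"s{i}" for i in range(20)]
        mat = rng.standard_normal((20, 4))
        diets = _diets(ids, rng.dirichlet(np.ones(9) * 0.7, size=20))
        d = mixed_trait_dissimilarity(_axes_for(ids, mat), diets)
        emb = embed_3d(d)
        rec = pdist(emb.coords)
        rho = stats.spearmanr(rec, squareform(d.to_numpy())).statistic
        assert rho > 0.9

    def test_too_few_positive_eigenvalues(self):
        ids = ["a", "b"]
        d = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=ids, columns=ids)
        with pytest.raises(ValueError, match="positive eigenvalues"):
            embed_3d(d)
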