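import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from chd import (
    isomap_applicable,
    isomap_unroll,
    mds_embed,
    pca_project,
    stress,
)
from chd.embedding import DisconnectedGraphError, EmbeddingCoordinates


def embed_coords(X, stage="mds"):
    return EmbeddingCoordinates(np.asarray(X, dtype=float), stage=stage)


def profile_coords(variance_profile, n=40, seed=0):
    """Coordinates whose PCA variance-explained profile is exactly as given."""
    v = np.asarray(variance_profile, dtype=float)
    rng = np.random.default_rng(seed)
    U, _ = np.linalg.qr(rng.normal(size=(n, v.size)))
    U = U - U.mean(axis=0)
    U, _ = np.linalg.qr(U)  # re-orthonormalize centered columns
    return embed_coords(U * np.sqrt(v))


class TestStress:
    def test_zero_for_exactly_realizable_distances(self, rng):
        X = rng.normal(size=(8, 3))
        D = squareform(pdist(X))
        assert stress(embed_coords(X), D) == 0.0

    def test_matches_brute_force_double_loop(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0]])
        D = np.array([[0, 1.5, 2.5], [1.5, 0, 0.5], [2.5, 0.5, 0]], dtype=float)
        expected = 0.0
        for i in range(3):
            for j in range(i + 1, 3):
                expected += (D[i, j] - np.linalg.norm(X[i] - X[j])) ** 2
        assert stress(embed_coords(X), D) == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_rigid_motion_of_coords(self, rng):
        X = rng.normal(size=(10, 4))
        D = squareform(pdist(X)) * 1.3
        Q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        assert stress(embed_coords(X @ Q + 5.0), D) == pytest.approx(
            stress(embed_coords(X), D), rel=1e-9
        )

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            stress(embed_coords(rng.normal(size=(4, 2))), np.zeros((5, 5)))


class TestMDSEmbed:
    def test_recovers_exact_euclidean_geometry(self, rng):
        X = rng.uniform(-1, 1, size=(25, 2))
        D = squareform(pdist(X))
        emb = mds_embed(D, dims=2, rng_seed=0)
        assert stress(emb, D) < 1e-10
        assert np.allclose(pdist(emb.coords), pdist(X), atol=1e-6)

    def test_three_equidistant_points_form_equilateral_triangle(self):
        D = np.ones((3, 3)) - np.eye(3)
        emb = mds_embed(D, dims=2, rng_seed=0)
        d = pdist(emb.coords)
        assert np.allclose(d, 1.0, atol=1e-6)
        assert stress(emb, D) < 1e-10

    def test_stress_descends_monotonically(self, rng):
        D = squareform(pdist(rng.normal(size=(15, 5)))) + 0.05 * squareform(
            rng.uniform(size=(15 * 14 // 2,))
        )
        _, hist = mds_embed(D, dims=3, rng_seed=1, return_history=True)
        assert np.all(np.diff(hist) <= 1e-12)

    def test_matches_sklearn_smacof_quality(self, rng):
        """Independent solver cross-check: our final stress is as low as sklearn's."""
        from sklearn.manifold import smacof

        X = rng.normal(size=(20, 6))
        D = squareform(pdist(X)) * (1 + 0.02 * rng.uniform(size=(20, 20)))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        emb = mds_embed(D, dims=4, rng_seed=0)
        _, sk_stress = smacof(
            D, n_components=4, n_init=4, max_iter=2000, eps=1e-12, random_state=0,
            metric=True, normalized_stress=False,
        )
        assert stress(emb, D) <= sk_stress * 1.05

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            mds_embed(np.array([[0.0, 1.0], [2.0, 0.0]]), dims=2)


class TestIsomap:
    def test_arc_geodesics_match_shortest_path_oracle(self):
        theta = np.linspace(0, np.pi, 20)
        X = np.stack([np.cos(theta), np.sin(theta)], axis=1)
        emb = embed_coords(X)
        # independent oracle: Dijkstra on the union-symmetrized 2-NN graph
        import networkx as nx

        D = squareform(pdist(X))
        G = nx.Graph()
        for i in range(20):
            for j in np.argsort(D[i])[1:3]:
                G.add_edge(i, int(j), weight=D[i, j])
        expected_end_to_end = nx.dijkstra_path_length(G, 0, 19)
        # the geodesic tracks the arc: close to the chord sum along the chain
        chords = np.linalg.norm(np.diff(X, axis=0), axis=1).sum()
        assert expected_end_to_end == pytest.approx(chords, rel=0.01)
        unrolled, geo = isomap_unroll(emb, k=2, return_geodesics=True)
        assert geo[0, -1] == pytest.approx(expected_end_to_end, abs=1e-9)
        # the re-embedding reproduces the geodesic span up to residual stress
        assert np.linalg.norm(unrolled.coords[0] - unrolled.coords[-1]) == pytest.approx(
            expected_end_to_end, rel=1e-3
        )

    def test_flat_manifold_is_fixed_point_of_distances(self):
        t = np.linspace(0, 10, 25) ** 1.2  # uneven but gap-free spacing
        X = np.stack([t, 2 * t + 1], axis=1)  # straight line in 2D
        emb = embed_coords(X)
        unrolled = isomap_unroll(emb, k=3)
        assert np.allclose(pdist(unrolled.coords), pdist(X), atol=1e-6)

    def test_disconnected_graph_raises_with_component_count(self):
        X = np.vstack([np.zeros((5, 2)) + [0, 0], np.zeros((5, 2)) + [100, 0]])
        X = X + np.arange(10)[:, None] * [0.1, 0.0]
        with pytest.raises(DisconnectedGraphError) as exc:
            isomap_unroll(embed_coords(X), k=1)
        assert exc.value.n_components >= 2  # the two clusters can never connect

    def test_invalid_k_rejected(self, rng):
        emb = embed_coords(rng.normal(size=(10, 3)))
        with pytest.raises(ValueError):
            isomap_unroll(emb, k=10)


class TestIsomapApplicable:
    def test_dominant_first_axis_profile_is_applicable(self):
        # v = (50, 10, 5, then uniform)% over D=30: mean 3.33%, half 1.67%;
        # successive differences 40% and 5% both exceed it
        rest = np.full(27, 0.35 / 27)
        v = np.concatenate([[0.50, 0.10, 0.05], rest])
        assert isomap_applicable(profile_coords(v, n=60)) is True

    def test_isotropic_profile_is_not_applicable(self):
        v = np.full(10, 0.1)
        assert isomap_applicable(profile_coords(v, n=40)) is False

    def test_boundary_equality_is_rejected_by_strict_rule(self):
        # v2 - v3 equals half the mean exactly (powers of two keep floats exact)
        v = np.array([0.5, 0.25, 0.125, 0.125])
        assert isomap_applicable(profile_coords(v, n=30)) is False

    def test_requires_three_dimensions(self, rng):
        with pytest.raises(ValueError):
            isomap_applicable(embed_coords(rng.normal(size=(5, 2))))


class TestPCAProject:
    def test_collinear_points_put_all_variance_on_first_axis(self, rng):
        direction = rng.normal(size=30)
        direction /= np.linalg.norm(direction)
        t = rng.uniform(-5, 5, size=20)
        X = np.outer(t, direction)
        ls = pca_project(embed_coords(X), n_components=1)
        assert ls.variance_explained[0] == pytest.approx(1.0, abs=1e-9)
        # latent must reproduce the arc-length ordering
        order = np.argsort(t)
        lat_order = np.argsort(ls.coordinate)
        assert np.array_equal(lat_order, order) or np.array_equal(lat_order, order[::-1])

    def test_variance_profile_sums_to_one_and_decreases(self, rng):
        ls = pca_project(embed_coords(rng.normal(size=(30, 6))), n_components=2)
        assert ls.variance_explained.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(ls.variance_explained) <= 1e-12)

    def test_scores_match_eigendecomposition_oracle(self, rng):
        X = rng.normal(size=(10, 5))
        Xc = X - X.mean(axis=0)
        w, V = np.linalg.eigh(Xc.T @ Xc / 10)
        top = V[:, np.argmax(w)]
        oracle = Xc @ top
        ls = pca_project(embed_coords(X), n_components=1)
        ratio = ls.coordinate / oracle
        assert np.allclose(np.abs(ratio), np.abs(ratio[0]), rtol=1e-6)

    def test_sign_convention_is_deterministic(self, rng):
        X = rng.normal(size=(25, 4)) * [5, 1, 0.5, 0.1]
        a = pca_project(embed_coords(X), 2)
        b = pca_project(embed_coords(X.copy()), 2)
        assert np.array_equal(a.coordinate, b.coordinate)
        from scipy.stats import skew

        assert skew(a.coordinate) >= 0

    def test_degenerate_input_warns_and_returns_zeros(self):
        with pytest.warns(UserWarning, match="degenerate"):
            ls = pca_project(embed_coords(np.ones((8, 3))), 1)
        assert np.all(ls.coordinate == 0)
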