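"""Candidate grid, degree screen, objective, selection rule, smoothing."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

from lmdist import (
    LMDist,
    LMdistParams,
    average_degree,
    build_neighbor_graph,
    candidate_radii,
    connect_graph,
    gaussian_smooth,
    lmdist_auto,
    objective_correlation,
    select_radius,
)
from lmdist.selection import _selection_rule

from conftest import euclidean_cloud_distances, random_semimetric


class TestCandidateRadii:
    def test_single_candidate_is_max(self):
        M = random_semimetric(np.random.default_rng(0), 6)
        grid = candidate_radii(M, 1)
        assert grid.shape == (1,)
        assert grid[0] == pytest.approx(M.max())

    def test_even_spacing_with_max_endpoint(self):
        M = np.array([
            [0.0, 0.2, 0.6], [0.2, 0.0, 1.0], [0.6, 1.0, 0.0],
        ])
        grid = candidate_radii(M, 50)
        assert grid.shape == (50,)
        assert grid[-1] == pytest.approx(1.0)
        np.testing.assert_allclose(np.diff(grid), np.diff(grid)[0])
        assert grid[0] > 0.2

    @pytest.mark.parametrize("seed", range(4))
    def test_range_property(self, seed):
        rng = np.random.default_rng(seed)
        M = random_semimetric(rng, 9)
        off = M[np.triu_indices(9, k=1)]
        grid = candidate_radii(M, 17)
        assert (grid > off[off > 0].min()).all()
        assert (grid <= off.max() + 1e-12).all()
        assert (np.diff(grid) > 0).all()

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            candidate_radii(np.zeros((4, 4)), 5)


class TestAverageDegree:
    def test_complete_graph_on_four_nodes(self):
        M = np.ones((4, 4)) - np.eye(4)
        G = build_neighbor_graph(M, 2.0)
        assert average_degree(G) == 3.0

    def test_empty_edge_set(self):
        M = np.ones((5, 5)) - np.eye(5)
        assert average_degree(build_neighbor_graph(M, 0.5)) == 0.0

    def test_matches_per_node_recount(self):
        rng = np.random.default_rng(1)
        M = random_semimetric(rng, 11)
        G = build_neighbor_graph(M, 0.5)
        assert average_degree(G) == pytest.approx(G.degrees().mean())

    def test_borrowed_edges_not_counted(self):
        # two far components: repair adds an edge, degree screen ignores it
        M = np.array([
            [0.0, 0.1, 0.9, 0.9],
            [0.1, 0.0, 0.9, 0.9],
            [0.9, 0.9, 0.0, 0.1],
            [0.9, 0.9, 0.1, 0.0],
        ])
        G = connect_graph(build_neighbor_graph(M, 0.2), M)
        assert len(G.mst_borrowed) == 1
        assert average_degree(G) == pytest.approx(2 * 2 / 4)


class TestObjectiveCorrelation:
    def test_line_geometry_perfect(self):
        x = np.linspace(0, 1, 8)
        D = np.abs(np.subtract.outer(x, x))
        assert objective_correlation(D) == pytest.approx(1.0, abs=1e-9)

    def test_equilateral_triangle_perfect(self):
        D = np.ones((3, 3)) - np.eye(3)
        assert objective_correlation(D) == pytest.approx(1.0, abs=1e-9)

    def test_matches_independent_pipeline(self):
        """Rebuild embedding + correlation from scratch with raw linalg."""
        rng = np.random.default_rng(2)
        M = random_semimetric(rng, 10)
        # independent route: double-center, eigh, positive axes, >80% cum
        J = np.eye(10) - np.ones((10, 10)) / 10
        B = -0.5 * J @ (M**2) @ J
        w, V = np.linalg.eigh(B)
        order = np.argsort(w)[::-1]
        w, V = w[order], V[:, order]
        keep = w > 1e-12 * abs(w[0])
        w, V = w[keep], V[:, keep]
        frac = w / w.sum()
        ndim = min(10, int(np.searchsorted(np.cumsum(frac), 0.80, side="right")) + 1)
        emb = V[:, :ndim] * np.sqrt(w[:ndim])
        expect = pearsonr(squareform(M, checks=False), pdist(emb))[0]
        assert objective_correlation(M) == pytest.approx(expect, abs=1e-10)

    def test_degenerate_embedding_scores_zero(self):
        D = np.zeros((4, 4))
        with pytest.warns(UserWarning):
            assert objective_correlation(D) == 0.0


class TestSelectionRule:
    def test_empty_list(self):
        assert _selection_rule([], 0.05) is None

    @pytest.mark.parametrize(
        "corrs, epsilon, winner",
        [
            ([0.9, 0.8, 0.7], 0.05, 0),          # nothing beats the incumbent
            ([0.7, 0.76, 0.9], 0.05, 2),         # planted gain > epsilon wins
            ([0.7, 0.74, 0.7], 0.05, 0),         # gain below epsilon ignored
            ([0.5, 0.6, 0.75, 0.7], 0.1, 2),     # incumbent updates then holds
            ([0.5, 0.9, 0.95, 1.0], 0.04, 3),    # chained replacements
            ([0.2, 0.2, 0.2], 0.0, 0),           # ties keep the largest radius
            ([0.3, 0.9, 0.8], np.inf, 0),        # infinite margin freezes incumbent
        ],
    )
    def test_exhaustive_rule_cases(self, corrs, epsilon, winner):
        assert _selection_rule(corrs, epsilon) == winner

    def test_epsilon_zero_is_argmax_largest_radius_on_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            corrs = np.round(rng.uniform(0, 1, 8), 2)
            k = _selection_rule(list(corrs), 0.0)
            assert corrs[k] == corrs.max()
            assert k == int(np.argmax(corrs))  # first occurrence = largest radius


class TestSelectRadius:
    def test_tiny_dataset_no_valid_radius(self):
        M = random_semimetric(np.random.default_rng(4), 4)
        res = select_radius(M, LMdistParams(phi=0.9))
        assert res.chosen_radius is None
        np.testing.assert_array_equal(res.adjusted.to_numpy(), M)

    def test_metric_input_largest_radius_near_identity(self):
        rng = np.random.default_rng(5)
        D, _ = euclidean_cloud_distances(rng, 20, dim=2)
        res = select_radius(D)
        valid = [d for d in res.diagnostics if d.degree_valid]
        assert res.chosen_radius == pytest.approx(max(d.radius for d in valid))
        assert np.abs(res.adjusted.to_numpy() - D).max() < 0.05 * D.max()

    def test_chosen_radius_always_degree_valid(self):
        rng = np.random.default_rng(6)
        M = random_semimetric(rng, 12)
        res = select_radius(M, LMdistParams(n_radii=12))
        chosen = [d for d in res.diagnostics if d.radius == res.chosen_radius]
        assert len(chosen) == 1 and chosen[0].degree_valid
        assert chosen[0].average_degree >= 0.10 * 12

    def test_epsilon_infinite_picks_largest_valid(self):
        rng = np.random.default_rng(7)
        M = random_semimetric(rng, 10)
        res = select_radius(M, LMdistParams(epsilon=np.inf, n_radii=10))
        valid = [d.radius for d in res.diagnostics if d.degree_valid]
        assert res.chosen_radius == pytest.approx(max(valid))

    def test_epsilon_zero_picks_argmax_correlation(self):
        rng = np.random.default_rng(8)
        M = random_semimetric(rng, 10)
        res = select_radius(M, LMdistParams(epsilon=0.0, n_radii=10))
        valid = [d for d in res.diagnostics if d.degree_valid]
        best = max(d.objective_correlation for d in valid)
        chosen = next(d for d in valid if d.radius == res.chosen_radius)
        assert chosen.objective_correlation == pytest.approx(best)

    def test_selection_deterministic(self, gradient_bc):
        a = select_radius(gradient_bc, LMdistParams(n_radii=10))
        b = select_radius(gradient_bc, LMdistParams(n_radii=10))
        assert a.chosen_radius == b.chosen_radius
        np.testing.assert_array_equal(a.adjusted.to_numpy(), b.adjusted.to_numpy())


class TestGaussianSmooth:
    def test_single_matrix_unchanged(self):
        M = random_semimetric(np.random.default_rng(9), 5)
        out = gaussian_smooth([(0.5, M)], 0.5, 0.1)
        np.testing.assert_allclose(out, M)

    def test_sigma_to_zero_collapses_on_chosen(self):
        rng = np.random.default_rng(10)
        A, B = random_semimetric(rng, 5), random_semimetric(rng, 5)
        out = gaussian_smooth([(0.3, A), (0.7, B)], 0.7, 1e-12)
        np.testing.assert_allclose(out, B)

    def test_equal_matrices_invariant_to_sigma(self):
        M = random_semimetric(np.random.default_rng(11), 6)
        for sigma in (0.01, 0.5, 10.0):
            out = gaussian_smooth([(0.2, M), (0.8, M)], 0.5, sigma)
            np.testing.assert_allclose(out, M)

    def test_convex_combination_bounds(self):
        rng = np.random.default_rng(12)
        mats = [(r, random_semimetric(rng, 6)) for r in (0.2, 0.5, 0.8)]
        out = gaussian_smooth(mats, 0.5, 0.2)
        stack = np.stack([m for _, m in mats])
        assert (out >= stack.min(axis=0) - 1e-12).all()
        assert (out <= stack.max(axis=0) + 1e-12).all()

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            gaussian_smooth([], 0.5, 0.1)


class TestLMDistEstimator:
    def test_sklearn_params_round_trip(self):
        from sklearn.base import clone

        est = LMDist(radius=0.4, phi=0.2, epsilon=0.01, smooth=True)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        est.set_params(epsilon=0.2)
        assert est.epsilon == 0.2

    def test_metric_braycurtis_matches_manual_pipeline(self, gradient_community):
        from lmdist import bray_curtis

        direct = LMDist(radius=0.4, metric="braycurtis").fit_transform(
            gradient_community.table
        )
        manual = LMDist(radius=0.4).fit_transform(bray_curtis(gradient_community.table))
        np.testing.assert_allclose(direct.to_numpy(), manual.to_numpy())

    def test_three_point_metric_identity(self):
        D = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
        with pytest.warns(UserWarning, match="samples"):
            res = lmdist_auto(D)
        assert res.chosen_radius is None
        np.testing.assert_array_equal(res.adjusted.to_numpy(), D)

    def test_invalid_metric_rejected(self):
        with pytest.raises(ValueError, match="metric"):
            LMDist(metric="unifrac").fit(np.zeros((3, 3)))

    def test_smoothing_preserves_gradient_solution(self, gradient_community,
                                                   gradient_bc):
        """Gaussian smoothing perturbs the adjusted matrix only mildly on
        average and leaves the recovered gradient intact."""
        from lmdist import axis_gradient_correlation, pcoa

        plain = lmdist_auto(gradient_bc, LMdistParams(n_radii=10))
        smoothed = lmdist_auto(gradient_bc, LMdistParams(n_radii=10, smooth=True))
        assert smoothed.smoothed and not plain.smoothed
        assert smoothed.chosen_radius == plain.chosen_radius
        diff = np.abs(smoothed.adjusted.to_numpy() - plain.adjusted.to_numpy())
        assert diff.mean() < 0.1 * gradient_bc.to_numpy().max()
        corr = axis_gradient_correlation(
            pcoa(smoothed.adjusted), 1, gradient_community.positions
        )
        assert corr > 0.9
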