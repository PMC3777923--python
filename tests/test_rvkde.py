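import numpy as np
import pytest

from pplink import (
    PPLinkError,
    RELATED,
    UNRELATED,
    RVKDEModel,
    RVKDEParams,
    bandwidth,
    default_grid,
    f_measure,
    fit,
    grid_search_cv,
    knn_radius,
)
from pplink.rvkde import _ClassDensity


def two_gaussians(rng, n=200, sep=4.0, m=2):
    rel = rng.normal(0.0, 1.0, size=(n, m))
    unr = rng.normal(0.0, 1.0, size=(n, m))
    unr[:, 0] += sep
    return rel, unr


class TestKnnRadius:
    def test_collinear_middle_point(self):
        pts = np.array([[0.0], [1.0], [2.0]])
        assert knn_radius(pts, 1, ks=2) == 1.0

    def test_asymmetric_neighbours(self):
        pts = np.array([[0.0], [1.0], [5.0]])
        assert knn_radius(pts, 0, ks=1) == 1.0
        assert knn_radius(pts, 0, ks=2) == 5.0

    def test_duplicated_points_zero_radius(self):
        pts = np.array([[1.0], [1.0], [3.0]])
        assert knn_radius(pts, 0, ks=1) == 0.0

    def test_ks_must_be_below_set_size(self):
        with pytest.raises(PPLinkError):
            knn_radius(np.zeros((3, 1)), 0, ks=3)


class TestBandwidth:
    def test_closed_form_1d(self):
        # m=1: sigma = beta * 2R / (alpha*ks); Gamma(3/2) = sqrt(pi)/2
        p = RVKDEParams(alpha=1.0, beta=1.0, ks=1, kt=1)
        assert bandwidth(2.0, 1, p) == pytest.approx(4.0)

    def test_zero_radius_hits_floor(self):
        p = RVKDEParams()
        assert bandwidth(0.0, 3, p, sigma_floor=1e-6) == 1e-6

    def test_linear_in_beta(self):
        p1 = RVKDEParams(beta=1.0)
        p2 = RVKDEParams(beta=2.0)
        assert bandwidth(1.5, 4, p2) == pytest.approx(2 * bandwidth(1.5, 4, p1))

    def test_decreasing_in_alpha_increasing_in_radius(self):
        lo = bandwidth(1.0, 2, RVKDEParams(alpha=4.0))
        hi = bandwidth(1.0, 2, RVKDEParams(alpha=1.0))
        assert lo < hi
        assert bandwidth(2.0, 2, RVKDEParams()) > bandwidth(1.0, 2, RVKDEParams())


class TestFit:
    def test_sigmas_positive_finite(self, rng):
        rel, unr = two_gaussians(rng, n=30)
        model = fit(rel, unr, RVKDEParams(ks=3, kt=10))
        for cls in model.classes.values():
            assert (cls.sigmas > 0).all() and np.isfinite(cls.sigmas).all()
        assert model.n == 60

    def test_identical_points_fall_back_to_floor(self):
        rel = np.ones((5, 2))
        unr = np.zeros((5, 2))
        model = fit(rel, unr, RVKDEParams(ks=2, kt=5))
        # duplicate vectors give zero radii; the floor keeps kernels usable
        assert (model.classes[RELATED].sigmas > 0).all()

    def test_deterministic(self, rng):
        rel, unr = two_gaussians(rng, n=25)
        m1 = fit(rel, unr, RVKDEParams(ks=3, kt=10))
        m2 = fit(rel, unr, RVKDEParams(ks=3, kt=10))
        np.testing.assert_array_equal(
            m1.classes[RELATED].sigmas, m2.classes[RELATED].sigmas
        )

    def test_class_smaller_than_ks_rejected(self, rng):
        rel, unr = two_gaussians(rng, n=4)
        with pytest.raises(PPLinkError):
            fit(rel, unr, RVKDEParams(ks=5, kt=5))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(PPLinkError):
            fit(np.zeros((5, 2)), np.zeros((5, 3)), RVKDEParams(ks=2))


def _single_point_model(sigma=1.0):
    model = RVKDEModel(params=RVKDEParams(kt=5), m=1)
    model.classes[RELATED] = _ClassDensity(
        samples=np.array([[0.0]]), sigmas=np.array([sigma])
    )
    model.classes[UNRELATED] = _ClassDensity(
        samples=np.array([[10.0]]), sigmas=np.array([sigma])
    )
    return model


class TestClassDensity:
    def test_gaussian_peak_closed_form(self):
        model = _single_point_model(sigma=1.0)
        assert model.density(RELATED, np.array([0.0])) == pytest.approx(
            1 / np.sqrt(2 * np.pi)
        )

    def test_vanishes_far_away(self):
        model = _single_point_model()
        assert model.density(RELATED, np.array([1e6])) == 0.0

    def test_unknown_class_rejected(self):
        with pytest.raises(PPLinkError):
            _single_point_model().density("mystery", np.array([0.0]))

    def test_full_sum_matches_double_loop_oracle(self, rng):
        """kt >= n_j reduces to a plain variable-bandwidth KDE."""
        rel = rng.random((50, 2))
        unr = rng.random((50, 2)) + 2.0
        model = fit(rel, unr, RVKDEParams(ks=4, kt=50))
        cls = model.classes[RELATED]
        queries = rng.random((20, 2)) * 3
        for v in queries:
            expected = 0.0
            for s, sig in zip(cls.samples, cls.sigmas):
                d2 = float((v[0] - s[0]) ** 2 + (v[1] - s[1]) ** 2)
                expected += (2 * np.pi) ** -1 * sig**-2 * np.exp(-d2 / (2 * sig**2))
            expected /= cls.n
            assert model.density(RELATED, v) == pytest.approx(expected, abs=1e-12)

    def test_truncation_error_is_one_sided(self, rng):
        rel = rng.random((40, 2))
        unr = rng.random((40, 2)) + 2.0
        full = fit(rel, unr, RVKDEParams(ks=4, kt=40))
        trunc = fit(rel, unr, RVKDEParams(ks=4, kt=5))
        queries = rng.random((25, 2)) * 3
        d_full = full.density(RELATED, queries)
        d_trunc = trunc.density(RELATED, queries)
        assert (d_trunc <= d_full + 1e-15).all()

    def test_integrates_to_one_in_1d(self, rng):
        """With kt = n_j the estimator is a proper density."""
        x = rng.standard_normal((200, 1))
        model = fit(x, x + 50.0, RVKDEParams(ks=5, kt=200))
        cls = model.classes[RELATED]
        step = cls.sigmas.min() / 5
        grid = np.arange(
            x.min() - 6 * cls.sigmas.max(), x.max() + 6 * cls.sigmas.max(), step
        )[:, None]
        integral = np.trapezoid(model.density(RELATED, grid), grid[:, 0])
        assert integral == pytest.approx(1.0, abs=1e-3)

    def test_consistency_on_standard_normal(self):
        """With adequate smoothing (beta = 40, i.e. sigma = 4R) the estimate
        tracks the true standard-normal density over [-2, 2]."""
        rng = np.random.default_rng(7)
        x = rng.standard_normal((2000, 1))
        model = fit(x, x + 100.0, RVKDEParams(alpha=1.0, beta=40.0, ks=20, kt=2000))
        grid = np.linspace(-2, 2, 401)[:, None]
        fhat = model.density(RELATED, grid)
        truth = np.exp(-grid[:, 0] ** 2 / 2) / np.sqrt(2 * np.pi)
        assert np.mean(np.abs(fhat - truth)) < 0.05


class TestLikelihoodsAndClassify:
    def test_mode_of_related_class_wins(self, rng):
        rel, unr = two_gaussians(rng)
        model = fit(rel, unr, RVKDEParams(ks=5, kt=50))
        lr, lu = model.likelihoods(np.array([0.0, 0.0]))
        assert lr > lu
        assert model.classify(np.array([0.0, 0.0])) == RELATED
        assert model.classify(np.array([4.0, 0.0])) == UNRELATED

    def test_far_query_likelihoods_underflow_to_zero(self, rng):
        rel, unr = two_gaussians(rng, n=20)
        model = fit(rel, unr, RVKDEParams(ks=3, kt=20))
        lr, lu = model.likelihoods(np.array([1e8, 1e8]))
        assert (lr, lu) == (0.0, 0.0)

    def test_exact_tie_goes_to_unrelated(self):
        model = RVKDEModel(params=RVKDEParams(kt=5), m=1)
        same = _ClassDensity(samples=np.array([[0.0]]), sigmas=np.array([1.0]))
        model.classes[RELATED] = same
        model.classes[UNRELATED] = _ClassDensity(
            samples=np.array([[0.0]]), sigmas=np.array([1.0])
        )
        assert model.classify(np.array([0.3])) == UNRELATED

    def test_score_orders_queries_sensibly(self, rng):
        rel, unr = two_gaussians(rng)
        model = fit(rel, unr, RVKDEParams(ks=5, kt=50))
        s = model.score(np.array([[0.0, 0.0], [2.0, 0.0], [4.0, 0.0]]))
        assert s[0] > s[1] > s[2]
        assert ((s >= 0) & (s <= 1)).all()

    def test_quick_recovery_with_fixed_params(self, rng):
        rel, unr = two_gaussians(rng, n=200)
        te_rel, te_unr = two_gaussians(np.random.default_rng(1), n=200)
        model = fit(rel, unr, RVKDEParams(alpha=1.0, beta=1.0, ks=10, kt=50))
        acc = np.mean(
            np.concatenate(
                [model.classify(te_rel) == RELATED, model.classify(te_unr) == UNRELATED]
            )
        )
        assert acc >= 0.95


class TestModelSerialization:
    def test_round_trip(self, tmp_path, rng):
        rel, unr = two_gaussians(rng, n=30)
        model = fit(rel, unr, RVKDEParams(ks=3, kt=10))
        path = tmp_path / "model.npz"
        model.save(path)
        back = RVKDEModel.load(path)
        assert back.params == model.params and back.m == model.m
        v = np.array([0.5, 0.5])
        assert back.score(v) == model.score(v)


class TestFMeasure:
    @pytest.mark.parametrize(
        "tp,fp,fn,expected",
        [(10, 0, 0, 1.0), (0, 5, 5, 0.0), (5, 5, 5, 0.5), (0, 0, 0, 0.0)],
    )
    def test_values(self, tp, fp, fn, expected):
        assert f_measure(tp, fp, fn) == pytest.approx(expected)

    def test_negative_counts_rejected(self):
        with pytest.raises(PPLinkError):
            f_measure(-1, 0, 0)


class TestGridSearchCV:
    def test_single_point_grid_returned(self, rng):
        rel, unr = two_gaussians(rng, n=30)
        only = RVKDEParams(alpha=1.0, beta=1.0, ks=3, kt=10)
        assert grid_search_cv(rel, unr, grid=[only], seed=0) == only

    def test_same_seed_same_selection(self, rng):
        rel, unr = two_gaussians(rng, n=40)
        grid = [RVKDEParams(ks=k, kt=10) for k in (2, 3, 5)]
        a = grid_search_cv(rel, unr, grid=grid, seed=3)
        b = grid_search_cv(rel, unr, grid=grid, seed=3)
        assert a == b

    def test_separable_data_scores_high(self, rng):
        rel, unr = two_gaussians(rng, n=200, sep=4.0)
        grid = [RVKDEParams(beta=b, ks=k, kt=20) for b in (0.5, 1.0) for k in (5, 10)]
        best, table = grid_search_cv(rel, unr, grid=grid, seed=0, return_table=True)
        best_score = dict((p, s) for p, s in table)[best]
        assert best_score > 0.9

    def test_tie_break_prefers_small_params(self, rng):
        # far-separated clusters: every grid point is perfect, smallest wins
        rel = rng.normal(0.0, 0.01, size=(25, 2))
        unr = rng.normal(100.0, 0.01, size=(25, 2))
        grid = [
            RVKDEParams(alpha=a, beta=b, ks=k, kt=t)
            for a in (1.0, 2.0) for b in (1.0, 2.0) for k in (2, 4) for t in (5, 10)
        ]
        best = grid_search_cv(rel, unr, grid=grid, seed=0)
        assert (best.ks, best.kt, best.beta, best.alpha) == (2, 5, 1.0, 1.0)

    def test_empty_grid_rejected(self, rng):
        rel, unr = two_gaussians(rng, n=20)
        with pytest.raises(PPLinkError):
            grid_search_cv(rel, unr, grid=[])

    def test_default_grid_shape(self):
        grid = default_grid()
        assert len(grid) == 3 * 4 * 3 * 3
        assert len(set(grid)) == len(grid)
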