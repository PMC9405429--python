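"""Standard ellipse areas, posterior sampling, overlap geometry."""

import numpy as np
import pytest

from isoniche import (
    bayesian_overlap,
    ellipse_overlap,
    ellipse_polygon,
    fit_ellipse,
    posterior_sea,
    sea_b_probability,
    sea_c,
    sea_c_rounded,
)
from isoniche.ellipses import STANDARD_CONTAINMENT, FitError


class TestFitEllipse:
    def test_symmetric_cross_hand_computation(self):
        """(±1,0),(0,±1): sample covariance diag(2/3, 2/3), SEA = 2π/3."""
        fit = fit_ellipse([(1, 0), (-1, 0), (0, 1), (0, -1)])
        np.testing.assert_allclose(fit.cov, np.diag([2 / 3, 2 / 3]))
        assert fit.sea == pytest.approx(2 * np.pi / 3)
        assert fit.eigenvalues == pytest.approx([2 / 3, 2 / 3])

    def test_identity_covariance_sample_gives_area_pi(self, rng):
        pts = rng.multivariate_normal([0, 0], np.eye(2), size=10_000)
        assert fit_ellipse(pts).sea == pytest.approx(np.pi, rel=0.02)

    def test_collinear_points_raise(self):
        with pytest.raises(FitError):
            fit_ellipse([(0, 0), (1, 1), (2, 2)])

    def test_fewer_than_three_points_raise(self):
        with pytest.raises(FitError):
            fit_ellipse([(0, 0), (1, 0)])

    def test_rotation_invariance_and_quadratic_scaling(self, rng):
        pts = rng.multivariate_normal([0, 0], [[2.0, 0.6], [0.6, 0.9]], size=40)
        sea = fit_ellipse(pts).sea
        th = 0.83
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        assert fit_ellipse(pts @ rot.T).sea == pytest.approx(sea, rel=1e-9)
        assert fit_ellipse(pts * 2.5).sea == pytest.approx(sea * 2.5**2, rel=1e-9)


class TestSmallSampleCorrection:
    # printed (SEA, n) -> SEA_C worked examples from the community tables
    @pytest.mark.parametrize(
        "sea,n,expected",
        [(1.35, 11, 1.50), (0.58, 16, 0.62), (2.03, 22, 2.13), (2.01, 18, 2.14), (0.71, 10, 0.80)],
    )
    def test_published_worked_examples(self, sea, n, expected):
        assert sea_c_rounded(sea, n) == expected

    def test_correction_inflates_and_vanishes_asymptotically(self):
        assert sea_c(1.0, 3) == 2.0
        assert sea_c(1.0, 10) > 1.0
        assert sea_c(1.0, 10_000) == pytest.approx(1.0, rel=1e-3)

    def test_n_below_three_rejected(self):
        with pytest.raises(ValueError):
            sea_c(1.0, 2)


class TestPosteriorSEA:
    def test_recovers_known_determinant(self, rng):
        """n = 200 from det-1 covariance: posterior median within 10% of π,
        cross-checked against an independent inverse-Wishart construction
        (inverse of Wishart draws via scipy's wishart)."""
        from scipy import stats

        cov = np.array([[2.0, 0.3], [0.3, 0.545]])
        cov[1, 1] = (1 + 0.3**2) / 2.0  # det exactly 1
        pts = rng.multivariate_normal([0, 0], cov, size=200)
        post = posterior_sea(pts, n_draws=1000, seed=1)
        assert post.median == pytest.approx(np.pi, rel=0.10)

        centred = pts - pts.mean(axis=0)
        scatter = centred.T @ centred
        w = stats.wishart.rvs(df=199, scale=np.linalg.inv(scatter), size=4000,
                              random_state=np.random.default_rng(2))
        oracle_areas = np.pi * np.sqrt(np.linalg.det(np.linalg.inv(w)))
        assert post.median == pytest.approx(np.median(oracle_areas), rel=0.05)

    def test_exactly_n_draws_all_positive(self, rng):
        pts = rng.normal(size=(30, 2))
        post = posterior_sea(pts, n_draws=1000, seed=0)
        assert post.area_draws.shape == (1000,)
        assert np.all(post.area_draws > 0)

    def test_credible_intervals_nested(self, rng):
        post = posterior_sea(rng.normal(size=(25, 2)), n_draws=2000, seed=3)
        (l50, h50), (l75, h75), (l95, h95) = (
            post.credible_intervals[lvl] for lvl in (0.50, 0.75, 0.95)
        )
        assert l95 <= l75 <= l50 < h50 <= h75 <= h95

    def test_fixed_seed_is_reproducible(self, rng):
        pts = rng.normal(size=(15, 2))
        a = posterior_sea(pts, seed=5)
        b = posterior_sea(pts, seed=5)
        np.testing.assert_array_equal(a.area_draws, b.area_draws)

    def test_posterior_concentrates_on_ml_area(self, rng):
        pts = rng.multivariate_normal([0, 0], [[1.5, -0.4], [-0.4, 0.8]], size=500)
        post = posterior_sea(pts, n_draws=3000, seed=4)
        assert post.area_draws.mean() == pytest.approx(fit_ellipse(pts).sea, rel=0.05)

    def test_too_few_points_raise(self):
        with pytest.raises(FitError):
            posterior_sea([(0, 0), (1, 0), (0, 1)])


class TestEllipsePolygon:
    def test_unit_circle_area(self):
        poly = ellipse_polygon([0, 0], np.eye(2))  # r = 1 standard ellipse
        assert poly.area == pytest.approx(np.pi, rel=1e-4)

    def test_anisotropic_covariance(self):
        poly = ellipse_polygon([0, 0], np.diag([4.0, 1.0]))
        assert poly.area == pytest.approx(2 * np.pi, rel=1e-4)

    def test_95_percent_containment_closed_form(self):
        # r² = −2 ln 0.05 (χ²₂ quantile), area = π r² √det
        poly = ellipse_polygon([0, 0], np.eye(2), containment=0.95)
        assert poly.area == pytest.approx(np.pi * (-2 * np.log(0.05)), rel=1e-4)

    def test_non_positive_definite_rejected(self):
        with pytest.raises(ValueError):
            ellipse_polygon([0, 0], np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_standard_ellipse_holds_about_40_percent(self, rng):
        """The r = 1 ellipse of a fitted bivariate normal contains
        1 − e^(−1/2) ≈ 39.35% of the data (the conventional "40%" level)."""
        cov = np.array([[1.8, 0.7], [0.7, 1.1]])
        pts = rng.multivariate_normal([3, -2], cov, size=50_000)
        fit = fit_ellipse(pts)
        d = pts - fit.mean
        maha2 = np.einsum("ij,jk,ik->i", d, np.linalg.inv(fit.cov), d)
        assert (maha2 <= 1.0).mean() == pytest.approx(STANDARD_CONTAINMENT, abs=0.007)


class TestOverlap:
    def _fit(self, mean, cov, rng, n=2000):
        return fit_ellipse(rng.multivariate_normal(mean, cov, size=n))

    def test_identical_ellipses_fully_overlap(self, rng):
        fit = self._fit([0, 0], np.eye(2), rng)
        res = ellipse_overlap(fit, fit)
        assert res.prop_a == pytest.approx(1.0, abs=1e-9)
        assert res.prop_b == pytest.approx(1.0, abs=1e-9)

    def test_distant_ellipses_do_not_overlap(self, rng):
        a = self._fit([0, 0], np.eye(2), rng)
        b = self._fit([100, 0], np.eye(2), rng)
        assert ellipse_overlap(a, b).intersection_area == 0.0

    def test_unit_circle_lens_closed_form(self):
        """Two unit circles one unit apart: lens area 2·cos⁻¹(1/2) − √3/2."""
        import isoniche.ellipses as ell

        lens = 2 * np.arccos(0.5) - 0.5 * np.sqrt(3)
        fa = ell.EllipseFit("a", 10, np.array([0.0, 0.0]), np.eye(2), np.ones(2), np.pi, 0.0)
        fb = ell.EllipseFit("b", 10, np.array([1.0, 0.0]), np.eye(2), np.ones(2), np.pi, 0.0)
        res = ellipse_overlap(fa, fb)
        assert res.intersection_area == pytest.approx(lens, abs=1e-3)
        assert res.prop_a == pytest.approx(lens / np.pi, abs=1e-3)

    def test_agrees_with_point_in_both_oracle(self, rng):
        """Monte-Carlo oracle: sample the bounding box of both ellipses and
        count points inside both."""
        from shapely import contains_xy

        a = self._fit([0, 0], [[1.3, 0.4], [0.4, 0.7]], rng)
        b = self._fit([0.8, 0.5], [[0.9, -0.2], [-0.2, 1.4]], rng)
        res = ellipse_overlap(a, b)
        pa, pb = (
            ellipse_polygon(f.mean, f.cov) for f in (a, b)
        )
        lo = np.minimum(*(np.array(p.bounds[:2]) for p in (pa, pb)))
        hi = np.maximum(*(np.array(p.bounds[2:]) for p in (pa, pb)))
        n_mc = 400_000
        mc = rng.uniform(lo, hi, size=(n_mc, 2))
        inside = contains_xy(pa, mc[:, 0], mc[:, 1]) & contains_xy(pb, mc[:, 0], mc[:, 1])
        box = np.prod(hi - lo)
        est = inside.mean() * box
        se = box * np.sqrt(inside.mean() * (1 - inside.mean()) / n_mc)
        assert abs(res.intersection_area - est) < 3 * se

    def test_intersection_bounded_by_smaller_ellipse(self, rng):
        a = self._fit([0, 0], np.eye(2), rng)
        b = self._fit([0.5, 0], np.diag([4.0, 2.0]), rng)
        res = ellipse_overlap(a, b)
        area_a = ellipse_polygon(a.mean, a.cov).area
        area_b = ellipse_polygon(b.mean, b.cov).area
        assert res.intersection_area <= min(area_a, area_b) + 1e-9

    def test_bayesian_overlap_medians_near_ml_for_large_n(self, rng):
        pts_a = rng.multivariate_normal([0, 0], np.eye(2), size=400)
        pts_b = rng.multivariate_normal([1, 0], np.eye(2), size=400)
        ml = ellipse_overlap(fit_ellipse(pts_a), fit_ellipse(pts_b))
        bay = bayesian_overlap(
            posterior_sea(pts_a, n_draws=300, seed=1),
            posterior_sea(pts_b, n_draws=300, seed=2),
        )
        assert bay.prop_a == pytest.approx(ml.prop_a, abs=0.05)


class TestSEABProbability:
    def test_same_data_independent_seeds_near_50(self, rng):
        pts = rng.normal(size=(40, 2))
        pa = posterior_sea(pts, n_draws=4000, seed=10)
        pb = posterior_sea(pts, n_draws=4000, seed=11)
        assert sea_b_probability(pa, pb) == pytest.approx(50.0, abs=3.0)

    def test_wider_niche_dominates(self, rng):
        pa = posterior_sea(rng.multivariate_normal([0, 0], 4 * np.eye(2), 200), seed=0)
        pb = posterior_sea(rng.multivariate_normal([0, 0], np.eye(2), 200), seed=1)
        assert sea_b_probability(pa, pb) > 99.0

    def test_tied_draws_count_zero(self, rng):
        post = posterior_sea(rng.normal(size=(20, 2)), seed=3)
        assert sea_b_probability(post, post) == 0.0

    def test_mismatched_draw_counts_rejected(self, rng):
        pts = rng.normal(size=(20, 2))
        with pytest.raises(ValueError):
            sea_b_probability(
                posterior_sea(pts, n_draws=100, seed=0), posterior_sea(pts, n_draws=200, seed=0)
            )
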