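import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

from mdfps.geometry import GridSpec, make_admin_grid
from mdfps.geostat import (
    GeostatBinomial,
    MaternParams,
    PosteriorSurface,
    conditional_latent,
    matern_correlation,
    matern_covariance,
)
from mdfps.rasters import CovariateStack


class TestMaternCovariance:
    def test_zero_distance_equals_variance(self):
        params = MaternParams(variance=2.5, range_km=30.0)
        assert matern_covariance(np.array(0.0), params) == pytest.approx(2.5)

    def test_decay_at_hundred_ranges(self):
        params = MaternParams(variance=1.0, range_km=1.0)
        assert matern_covariance(np.array(100.0), params) < 1e-6

    def test_matrix_matches_scalar_formula_oracle(self):
        """Element-by-element evaluation of sigma^2 (1+sqrt(3)d/phi)exp(-sqrt(3)d/phi)."""
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 50, (5, 2))
        d = cdist(pts, pts)
        params = MaternParams(variance=1.7, range_km=12.0)
        got = matern_covariance(d, params)
        for i in range(5):
            for j in range(5):
                t = np.sqrt(3) * d[i, j] / 12.0
                assert got[i, j] == pytest.approx(1.7 * (1 + t) * np.exp(-t), abs=1e-12)

    def test_symmetric_and_psd_with_nugget(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 100, (30, 2))
        cov = matern_covariance(cdist(pts, pts), MaternParams(1.0, 20.0), nugget=1e-8)
        np.testing.assert_allclose(cov, cov.T)
        assert np.linalg.eigvalsh(cov).min() > -1e-9

    def test_covariance_nonincreasing_in_distance(self):
        d = np.linspace(0, 200, 400)
        c = matern_covariance(d, MaternParams(1.0, 25.0))
        assert np.all(np.diff(c) <= 1e-15)

    @pytest.mark.parametrize("nu", [0.5, 1.5, 2.5])
    def test_closed_forms_agree_with_bessel_branch(self, nu):
        d = np.array([0.5, 3.0, 17.0, 60.0])
        closed = matern_correlation(d, 20.0, nu)
        bessel = matern_correlation(d, 20.0, nu + 1e-9)  # forces the generic branch
        np.testing.assert_allclose(closed, bessel, rtol=1e-5)

    def test_nonfinite_distances_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            matern_covariance(np.array([np.nan]), MaternParams(1.0, 10.0))


class TestConditionalLatent:
    def test_matches_dense_joint_gaussian_oracle(self):
        """Brute-force oracle: condition the full joint covariance directly.

        Build the (sites + points) joint Matérn covariance with the nugget
        on the whole diagonal, compute mean/cov of points | sites with
        explicit matrix inversion, and compare at 1e-8.
        """
        rng = np.random.default_rng(6)
        sites = rng.uniform(0, 80, (10, 2))
        points = rng.uniform(0, 80, (3, 2))
        w = rng.standard_normal(10)
        phi, nug = 22.0, 1e-6

        mean, cov = conditional_latent(sites, w, points, phi, 1.5, nug)

        allpts = np.vstack([sites, points])
        joint = matern_correlation(cdist(allpts, allpts), phi, 1.5) + nug * np.eye(13)
        S_ss, S_pp = joint[:10, :10], joint[10:, 10:]
        S_ps = joint[10:, :10]
        inv = np.linalg.inv(S_ss)
        mean_o = S_ps @ inv @ w
        cov_o = S_pp - S_ps @ inv @ S_ps.T
        np.testing.assert_allclose(mean, mean_o, atol=1e-8)
        np.testing.assert_allclose(cov, cov_o, atol=1e-8)

    def test_interpolates_site_values_as_nugget_vanishes(self):
        rng = np.random.default_rng(7)
        sites = rng.uniform(0, 50, (8, 2))
        w = rng.standard_normal(8)
        mean, cov = conditional_latent(sites, w, sites[:3], 18.0, 1.5, nugget=1e-12)
        np.testing.assert_allclose(mean, w[:3], atol=1e-4)
        assert np.abs(np.diag(cov)).max() < 1e-3


def constant_surface_model(p0=0.5, n_draws=50):
    """Hand-assembled fitted model with beta draws at logit(p0) and S == 0."""
    m = GeostatBinomial(covariates=[])
    n = 25
    rng = np.random.default_rng(0)
    m.coords_ = rng.uniform(0, 90, (n, 2))
    m.feature_names_ = ["intercept"]
    m.beta_draws_ = np.full((n_draws, 1), np.log(p0 / (1 - p0)))
    m.sigma_draws_ = np.full(n_draws, 1e-8)
    m.sigma2_draws_ = m.sigma_draws_**2
    m.range_draws_ = np.full(n_draws, 20.0)
    m.z_draws_ = np.zeros((n_draws, n))
    m.s_draws_ = np.zeros((n_draws, n))
    return m


class TestPrediction:
    def test_null_model_predicts_half_everywhere(self):
        m = constant_surface_model(0.5)
        grid = GridSpec(0, 0, 5.0, 18, 18)
        stack = CovariateStack(grid=grid, layers={})
        surf = m.predict_surface(stack, n_draws=20, seed=1)
        np.testing.assert_allclose(surf.samples, 0.5, atol=1e-6)

    def test_surface_masked_by_admin_union(self):
        m = constant_surface_model(0.4)
        grid = GridSpec(0, 0, 5.0, 20, 20)
        stack = CovariateStack(grid=grid, layers={})
        admin = make_admin_grid(4, 50.0)  # lower-left quarter only
        surf = m.predict_surface(stack, admin=admin, n_draws=5, seed=1)
        assert surf.mask.sum() == 100
        assert surf.samples.shape == (5, 100)

    def test_pixel_ranking_invariant_under_logit_transform(self):
        rng = np.random.default_rng(3)
        grid = GridSpec(0, 0, 5.0, 6, 6)
        samples = rng.uniform(0.05, 0.95, (40, 36))
        surf = PosteriorSurface(grid=grid, mask=np.ones((6, 6), bool), samples=samples)
        mean_p = surf.samples.mean(axis=0)
        mean_logit = np.log(surf.samples / (1 - surf.samples)).mean(axis=0)
        # monotone-transform check applies to per-draw values, so compare
        # rank stability of the posterior median instead of the mean
        med_p = np.median(surf.samples, axis=0)
        med_l = np.median(np.log(surf.samples / (1 - surf.samples)), axis=0)
        np.testing.assert_array_equal(np.argsort(med_p), np.argsort(med_l))

    def test_surface_values_always_probabilities(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            PosteriorSurface(
                grid=GridSpec(0, 0, 5.0, 2, 2),
                mask=np.ones((2, 2), bool),
                samples=np.array([[0.1, 0.2, 1.4, 0.3]]),
            )


def simulate_counts(n_clusters=60, seed=0, extent=120.0, p_logit=0.2, trials=25):
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, extent, (n_clusters, 2))
    from scipy.special import expit

    succ = rng.binomial(trials, expit(p_logit), n_clusters)
    return pd.DataFrame(
        {
            "cluster_id": np.arange(n_clusters),
            "x_km": coords[:, 0],
            "y_km": coords[:, 1],
            "admin_id": 1,
            "n_demand": trials,
            "n_satisfied": succ,
        }
    )


class TestFitValidation:
    def test_too_few_clusters_rejected(self):
        with pytest.raises(ValueError, match="20 clusters"):
            GeostatBinomial().fit(simulate_counts(10))

    def test_single_class_outcome_rejected(self):
        counts = simulate_counts(30)
        counts["n_satisfied"] = counts["n_demand"]
        with pytest.raises(ValueError, match="successes and failures"):
            GeostatBinomial().fit(counts)

    def test_count_bounds_validated(self):
        counts = simulate_counts(30)
        counts.loc[3, "n_satisfied"] = counts.loc[3, "n_demand"] + 1
        with pytest.raises(ValueError, match="n_satisfied"):
            GeostatBinomial().fit(counts)

    def test_colocated_clusters_are_summed(self):
        counts = simulate_counts(30)
        dup = counts.iloc[[0]].copy()
        counts2 = pd.concat([counts, dup], ignore_index=True)
        m = GeostatBinomial(
            covariates=[], n_chains=1, n_warmup=60, n_draws=40, check_convergence=False
        ).fit(counts2)
        assert m.trials_.sum() == counts2["n_demand"].sum()
        assert len(m.coords_) == 30

    def test_missing_covariate_layer_rejected(self, small_stack):
        with pytest.raises(ValueError, match="missing covariate"):
            GeostatBinomial(covariates=["unobtanium"]).fit(simulate_counts(25, extent=80), small_stack)


class TestFitBehaviour:
    def test_duplicated_data_sharpens_coefficients(self):
        """Doubling every cluster (dedup off, nudged coords) must narrow the
        intercept's credible interval: more data, more information."""
        counts = simulate_counts(40, seed=9, extent=100.0)
        dup = counts.copy()
        dup["x_km"] += 0.19  # avoid exact co-location without changing structure
        dup["cluster_id"] += 1000
        doubled = pd.concat([counts, dup], ignore_index=True)
        kw = dict(covariates=[], n_chains=2, n_warmup=250, n_draws=250, seed=3,
                  deduplicate=False, nugget=1e-5, check_convergence=False)
        a = GeostatBinomial(**kw).fit(counts)
        b = GeostatBinomial(**kw).fit(doubled)
        wa = np.diff(np.quantile(a.beta_draws_[:, 0], [0.025, 0.975]))[0]
        wb = np.diff(np.quantile(b.beta_draws_[:, 0], [0.025, 0.975]))[0]
        assert wb < wa

    def test_null_gp_recovery(self):
        """No spatial signal: beta0 posterior covers truth, sigma^2 small."""
        counts = simulate_counts(80, seed=5, extent=150.0, p_logit=0.3)
        m = GeostatBinomial(
            covariates=[], n_chains=2, n_warmup=400, n_draws=300, seed=2,
            check_convergence=False,
        ).fit(counts)
        lo, hi = np.quantile(m.beta_draws_[:, 0], [0.025, 0.975])
        assert lo < 0.3 < hi
        assert np.median(m.sigma2_draws_) < 0.25
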