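"""Three-stage estimator: stage fits, GP conditioning, draws."""

import numpy as np
import pandas as pd
import pytest

from anc_stgpr.config import SimConfig, StgprConfig
from anc_stgpr.hierarchy import LocationHierarchy
from anc_stgpr.stgpr import (STGPR, GPRPosterior, ModelFrame, Stage2Prior,
                             estimate_amplitude, fit_gpr, fit_stage1,
                             matern32, sample_draws, smooth_residuals,
                             tricube)

from conftest import naive_gp_oracle


def synthetic_frame(n_countries=40, n_years=12, n_per_country=2, beta=None,
                    country_sd=0.3, noise_sd=0.1, seed=0,
                    indicator="bp_measured"):
    """Frame generated directly from the stage-1 model (transform scale)."""
    rng = np.random.default_rng(seed)
    beta = np.asarray(beta if beta is not None else [0.5, 0.8, 0.3, -0.2])
    per_region = max(2, n_countries // 5)
    countries, regions = [], {}
    for i in range(n_countries):
        r = f"R{i // per_region + 1}"
        c = f"C{i // per_region + 1:02d}{i % per_region + 1:02d}"
        countries.append(c)
        regions[c] = r
    years = np.arange(2000, 2000 + n_years)
    cov_rows, data_rows = [], []
    u = rng.normal(0.0, country_sd, n_countries)
    for ci, c in enumerate(countries):
        x_c = rng.normal(0.0, 1.0, (n_years, 3))
        for yi, y in enumerate(years):
            cov_rows.append({"location": c, "year": int(y),
                             "x1": x_c[yi, 0], "x2": x_c[yi, 1],
                             "x3": x_c[yi, 2]})
        for k in range(n_per_country):
            yi = rng.integers(0, n_years)
            v = noise_sd ** 2 * rng.uniform(0.5, 2.0)
            mu = beta[0] + x_c[yi] @ beta[1:] + u[ci]
            data_rows.append({
                "location": c, "year": int(years[yi]),
                "source_id": f"{c}_{k}",
                "y": mu + rng.normal(0.0, np.sqrt(v)), "v": v,
                "x1": x_c[yi, 0], "x2": x_c[yi, 1], "x3": x_c[yi, 2]})
    nodes = [{"location_id": "global", "parent_id": "", "level": "global"}]
    for r in sorted(set(regions.values())):
        nodes.append({"location_id": r, "parent_id": "global",
                      "level": "region"})
    for c in countries:
        nodes.append({"location_id": c, "parent_id": regions[c],
                      "level": "country"})
    livebirths = pd.DataFrame([
        {"location_id": c, "year": int(y), "livebirths": 1000.0}
        for c in countries for y in years])
    hierarchy = LocationHierarchy(pd.DataFrame(nodes), livebirths)
    return ModelFrame(indicator, pd.DataFrame(data_rows),
                      pd.DataFrame(cov_rows), hierarchy), beta, u


class TestStage1:
    def test_recovers_known_coefficients(self):
        """Pooled over replicate panels, estimates are unbiased (within 3
        pooled standard errors) and the per-fit |z| > 2 rate stays near its
        nominal 5%."""
        estimates, ses, zs = [], [], []
        n_seeds = 16
        for seed in range(n_seeds):
            frame, beta, _ = synthetic_frame(n_countries=40, n_per_country=6,
                                             seed=seed)
            fit = fit_stage1(frame)
            estimates.append(fit.fixed_effects)
            ses.append(fit.fixed_effects_se)
            zs.append((fit.fixed_effects - beta) / fit.fixed_effects_se)
        mean_est = np.mean(estimates, axis=0)
        pooled_se = np.mean(ses, axis=0) / np.sqrt(n_seeds)
        assert (np.abs(mean_est - beta) < 3 * pooled_se).all()
        # Wald SEs ignore variance-component uncertainty, so allow modest
        # anticonservatism but catch gross miscalibration
        zs = np.array(zs)
        assert (zs ** 2).mean() < 2.5
        assert (np.abs(zs) > 2).mean() <= 0.25

    def test_matches_statsmodels_mixedlm_with_equal_variances(self):
        """Independent oracle: with equal observation variances the weighted
        REML collapses to a plain random-intercept model."""
        import statsmodels.formula.api as smf

        frame, _, _ = synthetic_frame(n_countries=25, n_per_country=8, seed=2)
        frame.data["v"] = 0.02
        fit = fit_stage1(frame)
        df = frame.data
        m = smf.mixedlm("y ~ x1 + x2 + x3", df, groups=df["location"]).fit(
            reml=True)
        np.testing.assert_allclose(fit.fixed_effects, m.params[:4].to_numpy(),
                                   atol=2e-3)
        tau2_sm = float(m.cov_re.iloc[0, 0])
        assert fit.country_sd ** 2 == pytest.approx(tau2_sm, rel=0.05)

    def test_flat_truth_gives_flat_predictions(self):
        frame, _, _ = synthetic_frame(beta=[0.7, 0, 0, 0], country_sd=0.0,
                                      noise_sd=0.05, n_per_country=4, seed=3)
        fit = fit_stage1(frame)
        m1 = fit.predictions["m1"]
        assert m1.std() < 0.05
        assert m1.mean() == pytest.approx(0.7, abs=0.05)

    def test_unseen_country_prediction_is_fixed_effects_only(self):
        frame, _, _ = synthetic_frame(seed=4, n_per_country=3)
        seen = set(frame.data["location"])
        unseen = [c for c in frame.countries if c not in seen]
        if not unseen:
            frame.data = frame.data[frame.data["location"]
                                    != frame.countries[0]]
            unseen = [frame.countries[0]]
        fit = fit_stage1(frame)
        c = unseen[0]
        y = int(frame.years[0])
        x = frame.x_at(c, y)
        expected = fit.fixed_effects[0] + x @ fit.fixed_effects[1:]
        assert fit.m1(c, y) == pytest.approx(expected, abs=1e-10)
        assert c not in fit.blups


class TestStage2:
    def make_prior(self, frame, m1_value=0.0):
        rows = [(c, int(y), m1_value) for c in frame.countries
                for y in frame.years]
        from anc_stgpr.stgpr import Stage1Fit
        return Stage1Fit(np.zeros(4), np.zeros(4), 0.0, 1.0, {},
                         pd.DataFrame(rows, columns=["location", "year", "m1"]))

    def frame_with_data(self, rows):
        frame, _, _ = synthetic_frame(n_countries=4, n_years=10,
                                      n_per_country=1, seed=5)
        frame.data = pd.DataFrame(rows)
        return frame

    def test_single_residual_fully_recovered_at_its_own_cell(self):
        frame = self.frame_with_data([
            {"location": "C0101", "year": 2003, "source_id": "s",
             "y": 0.8, "v": 0.01, "x1": 0, "x2": 0, "x3": 0}])
        stage1 = self.make_prior(frame)
        prior = smooth_residuals(frame, stage1, 10.0, 0.3)
        assert prior.m2("C0101", 2003) == pytest.approx(0.8)

    def test_zero_space_weight_and_no_own_data_keeps_stage1(self):
        frame = self.frame_with_data([
            {"location": "C0101", "year": 2003, "source_id": "s",
             "y": 0.8, "v": 0.01, "x1": 0, "x2": 0, "x3": 0}])
        stage1 = self.make_prior(frame)
        prior = smooth_residuals(frame, stage1, 10.0, 0.0)
        assert prior.m2("C0201", 2003) == pytest.approx(0.0, abs=1e-15)

    def test_symmetric_residuals_cancel(self):
        frame = self.frame_with_data([
            {"location": "C0101", "year": 2002, "source_id": "a",
             "y": 0.5, "v": 0.01, "x1": 0, "x2": 0, "x3": 0},
            {"location": "C0101", "year": 2006, "source_id": "b",
             "y": -0.5, "v": 0.01, "x1": 0, "x2": 0, "x3": 0}])
        stage1 = self.make_prior(frame)
        prior = smooth_residuals(frame, stage1, 10.0, 0.3)
        assert prior.m2("C0101", 2004) == pytest.approx(0.0, abs=1e-12)

    def test_tricube_kernel_support(self):
        assert tricube(np.array([0.0])) == pytest.approx(1.0)
        assert tricube(np.array([1.0])) == pytest.approx(0.0)
        assert tricube(np.array([1.5])) == pytest.approx(0.0)

    def test_invalid_hyperparameters_rejected(self):
        frame, _, _ = synthetic_frame(n_countries=4, seed=6)
        stage1 = fit_stage1(frame)
        with pytest.raises(ValueError):
            smooth_residuals(frame, stage1, -1.0, 0.3)
        with pytest.raises(ValueError):
            smooth_residuals(frame, stage1, 10.0, 1.5)


class TestGPR:
    def _prior_and_frame(self, frame, m2=0.0):
        rows = [(c, int(y), m2) for c in frame.countries for y in frame.years]
        prior = Stage2Prior(pd.DataFrame(rows,
                                         columns=["location", "year", "m2"]),
                            10.0, 0.3)
        return prior

    def test_data_free_location_returns_prior(self):
        frame, _, _ = synthetic_frame(n_countries=4, seed=7)
        frame.data = frame.data.iloc[:2]
        prior = self._prior_and_frame(frame)
        post = fit_gpr(prior, frame, amplitude=0.4, timescale=8.0)
        empty = [c for c in frame.countries
                 if c not in set(frame.data["location"])][0]
        i = post.locations.index(empty)
        np.testing.assert_allclose(post.means[i], 0.0, atol=1e-14)
        np.testing.assert_allclose(np.diag(post.covariances[i]), 0.16,
                                   atol=1e-12)

    def test_tiny_noise_interpolates_datum(self):
        frame, _, _ = synthetic_frame(n_countries=4, seed=8)
        c = frame.countries[0]
        frame.data = pd.DataFrame([{
            "location": c, "year": 2004, "source_id": "s", "y": 0.9,
            "v": 1e-10, "x1": 0, "x2": 0, "x3": 0}])
        prior = self._prior_and_frame(frame)
        post = fit_gpr(prior, frame, amplitude=0.4, timescale=8.0)
        i = post.locations.index(c)
        j = int(np.where(post.years == 2004)[0][0])
        assert abs(post.means[i, j] - 0.9) < 1e-6

    def test_matches_naive_dense_oracle(self):
        """Random small instances against the textbook closed form."""
        rng = np.random.default_rng(9)
        frame, _, _ = synthetic_frame(n_countries=3, n_years=20, seed=9)
        years = frame.years.astype(float)
        for trial in range(20):
            c = frame.countries[0]
            n_obs = rng.integers(1, 10)
            t_obs = rng.choice(years, n_obs, replace=True)
            y_obs = rng.normal(0, 0.5, n_obs)
            v_obs = rng.uniform(0.01, 0.3, n_obs)
            amplitude = rng.uniform(0.1, 1.0)
            timescale = rng.uniform(2.0, 20.0)
            m2_vals = rng.normal(0, 0.3, len(years))
            rows = [(cc, int(y), m2_vals[k] if cc == c else 0.0)
                    for cc in frame.countries
                    for k, y in enumerate(frame.years)]
            prior = Stage2Prior(pd.DataFrame(
                rows, columns=["location", "year", "m2"]), 10.0, 0.3)
            frame.data = pd.DataFrame([
                {"location": c, "year": int(t), "source_id": f"s{k}",
                 "y": y_obs[k], "v": v_obs[k], "x1": 0, "x2": 0, "x3": 0}
                for k, t in enumerate(t_obs)])
            post = fit_gpr(prior, frame, amplitude, timescale)
            i = post.locations.index(c)
            m_obs = np.array([m2_vals[int(t - 2000)] for t in t_obs])
            mean, cov = naive_gp_oracle(years, t_obs.astype(float), y_obs,
                                        v_obs, m2_vals, m_obs, amplitude,
                                        timescale)
            np.testing.assert_allclose(post.means[i], mean, atol=1e-8)
            np.testing.assert_allclose(post.covariances[i], cov, atol=1e-8)

    def test_posterior_variance_never_exceeds_prior(self):
        frame, _, _ = synthetic_frame(n_countries=6, n_per_country=4, seed=10)
        prior = self._prior_and_frame(frame)
        post = fit_gpr(prior, frame, amplitude=0.4, timescale=8.0)
        prior_var = 0.4 ** 2
        assert (np.diagonal(post.covariances, axis1=1, axis2=2)
                <= prior_var + 1e-10).all()

    def test_removing_a_datum_widens_posterior_at_its_year(self):
        frame, _, _ = synthetic_frame(n_countries=3, seed=11)
        c = frame.countries[0]
        data = pd.DataFrame([
            {"location": c, "year": 2003, "source_id": "a", "y": 0.5,
             "v": 0.02, "x1": 0, "x2": 0, "x3": 0},
            {"location": c, "year": 2008, "source_id": "b", "y": 0.1,
             "v": 0.02, "x1": 0, "x2": 0, "x3": 0}])
        prior = self._prior_and_frame(frame)
        frame.data = data
        full = fit_gpr(prior, frame, 0.4, 8.0)
        frame.data = data.iloc[[1]]
        reduced = fit_gpr(prior, frame, 0.4, 8.0)
        i = full.locations.index(c)
        j = int(np.where(full.years == 2003)[0][0])
        assert (full.covariances[i, j, j] < reduced.covariances[i, j, j])


class TestAmplitude:
    def _frame_with_resid(self, resid, seed=0):
        frame, _, _ = synthetic_frame(n_countries=5, n_years=10, seed=seed)
        n = len(resid)
        locs = [frame.countries[i % len(frame.countries)] for i in range(n)]
        frame.data = pd.DataFrame([
            {"location": locs[k], "year": 2005, "source_id": f"s{k}",
             "y": resid[k], "v": 0.01, "x1": 0, "x2": 0, "x3": 0}
            for k in range(n)])
        prior = Stage2Prior(pd.DataFrame(
            [(c, int(y), 0.0) for c in frame.countries for y in frame.years],
            columns=["location", "year", "m2"]), 10.0, 0.3)
        return frame, prior

    def test_zero_residuals_hit_floor(self):
        frame, prior = self._frame_with_resid(np.zeros(20))
        assert estimate_amplitude(frame, prior) == pytest.approx(0.01)

    def test_mad_consistency_for_gaussian_residuals(self):
        rng = np.random.default_rng(12)
        sigma = 0.37
        frame, prior = self._frame_with_resid(rng.normal(0, sigma, 10 ** 4))
        assert estimate_amplitude(frame, prior) == pytest.approx(sigma,
                                                                 rel=0.03)

    def test_robust_to_heavy_tails(self):
        """10% contamination at 10x the core scale inflates the MAD-based
        amplitude only mildly; the exact inflation follows from the mixture
        CDF (independent closed-form oracle) and stays below 15%."""
        from scipy.optimize import brentq
        from scipy.stats import norm

        rng = np.random.default_rng(13)
        sigma = 0.3
        resid = rng.normal(0, sigma, 5000)
        resid[:500] = rng.normal(0, 10 * sigma, 500)
        frame, prior = self._frame_with_resid(resid)
        eta = estimate_amplitude(frame, prior)
        # median of |X| under the 0.9 N(0,s) + 0.1 N(0,10s) mixture
        u = brentq(lambda q: 0.9 * (2 * norm.cdf(q) - 1)
                   + 0.1 * (2 * norm.cdf(q / 10) - 1) - 0.5, 0.1, 3.0)
        expected = 1.4826 * u * sigma
        assert eta == pytest.approx(expected, rel=0.03)
        assert eta < 1.15 * sigma

    def test_too_few_residuals_use_default(self):
        frame, prior = self._frame_with_resid(np.array([0.5, 0.5]))
        cfg = StgprConfig(default_amplitude=0.25)
        assert estimate_amplitude(frame, prior, cfg) == pytest.approx(0.25)


class TestDraws:
    def _posterior(self, means, covs, years=None):
        n_loc, n_years = means.shape
        years = years if years is not None else np.arange(2000,
                                                          2000 + n_years)
        return GPRPosterior([f"L{i}" for i in range(n_loc)], years, means,
                            covs, 0.3, 10.0)

    def test_zero_covariance_degenerates_to_mean(self):
        means = np.array([[0.2, -0.1, 0.4]])
        covs = np.zeros((1, 3, 3))
        post = self._posterior(means, covs)
        cube = sample_draws(post, 50, seed=1, transform="logit")
        from scipy.special import expit
        np.testing.assert_allclose(
            cube.values, expit(means)[:, :, None] * np.ones(50), atol=1e-12)

    def test_draw_mean_matches_posterior_mean(self):
        rng = np.random.default_rng(14)
        means = rng.normal(0, 0.5, (3, 8))
        a = rng.normal(0, 0.3, (8, 8))
        cov = a @ a.T
        covs = np.stack([cov] * 3)
        post = self._posterior(means, covs)
        cube = sample_draws(post, 1000, seed=2, transform="logit")
        from scipy.special import logit
        draw_means = logit(cube.values).mean(axis=2)
        sd = np.sqrt(np.diag(cov))
        assert (np.abs(draw_means - means) < 4 * sd / np.sqrt(1000)).all()

    def test_same_seed_identical(self):
        rng = np.random.default_rng(15)
        means = rng.normal(0, 0.5, (2, 5))
        covs = np.stack([np.eye(5) * 0.04] * 2)
        post = self._posterior(means, covs)
        c1 = sample_draws(post, 100, seed=3)
        c2 = sample_draws(post, 100, seed=3)
        np.testing.assert_array_equal(c1.values, c2.values)

    def test_content_mean_draws_clamped_to_0_5(self):
        means = np.full((1, 4), np.log(4.9))
        covs = np.stack([np.eye(4) * 0.25])
        post = self._posterior(means, covs)
        cube = sample_draws(post, 500, seed=4, transform="log", upper=5.0)
        assert cube.values.max() <= 5.0
        assert cube.values.min() >= 0.0


class TestModelObject:
    def test_fit_returns_results_with_summary(self, small_estimates,
                                              small_covariates,
                                              small_hierarchy):
        frame = ModelFrame.from_estimates(small_estimates, "bp_measured",
                                          small_covariates, small_hierarchy)
        results = STGPR(frame).fit()
        text = results.summary()
        assert "bp_measured" in text and "Matern" in text
        cube = results.sample(n_draws=100, seed=5)
        assert cube.n_draws == 100
        assert cube.values.min() >= 0.0 and cube.values.max() <= 1.0
        preds = results.predictions()
        assert len(preds) == len(small_hierarchy.countries) * 10
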