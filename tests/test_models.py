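"""Sampler correctness: conjugate oracles, log-posterior cross-checks,
convergence diagnostics, and parameter recovery on generated data."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import farmbayes as fb
from farmbayes.models import (
    BERNOULLI_LOGIT,
    build_design,
    compute_rhat,
    log_posterior,
)
from farmbayes.preprocess import ColumnMeta, DesignMatrix


def make_design(X, y, sites=None, households=None):
    """Hand-built DesignMatrix on the already-standardized scale."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    cols = [f"x{i}" for i in range(p)]
    return DesignMatrix(
        X=X,
        columns=cols,
        column_meta=[ColumnMeta(c, 0.0, 1.0, False) for c in cols],
        y=np.asarray(y, dtype=float),
        response="y",
        y_mean=0.0,
        y_sd=1.0,
        site_index=np.asarray(sites if sites is not None else ["s"] * n),
        household_index=np.asarray(households if households is not None else ["h"] * n),
        row_ids=pd.DataFrame(index=range(n)),
    )


def shared_spec(p, likelihood="gaussian"):
    return fb.ModelSpec(
        "y",
        tuple(f"x{i}" for i in range(p)),
        likelihood,
        site_varying_intercept=False,
        site_varying_slopes=False,
    )


# --- conjugate / closed-form oracles -----------------------------------------


class TestConjugateOracle:
    def test_fixed_sigma_matches_closed_form(self):
        """With known noise the Gibbs draws are iid from the exact normal
        conjugate posterior; mean and SD must match it within MC error."""
        rng = np.random.default_rng(1)
        n, sigma = 300, 0.7
        X = rng.normal(size=(n, 3))
        beta_true = np.array([0.5, -0.3, 0.8])
        y = X @ beta_true + sigma * rng.normal(size=n)
        d = make_design(X, y)
        res = fb.fit_linear_model(
            d, shared_spec(3), fb.McmcSettings(2, 200, 4000, seed=3),
            fixed_sigma=sigma,
        )
        Z, names, _ = build_design(d, shared_spec(3))
        mu, V = fb.conjugate_linear_posterior(Z, y, sigma)
        N = 2 * 4000
        for i, name in enumerate(names):
            post_sd = np.sqrt(V[i, i])
            mc_se = post_sd / np.sqrt(N)
            assert abs(res.summary.loc[name, "mean"] - mu[i]) < 3 * mc_se
            sd_se = post_sd * np.sqrt(2.0 / N) * 3
            assert abs(res.summary.loc[name, "sd"] - post_sd) < sd_se + 1e-3

    def test_prior_recovered_with_no_data(self):
        """Empty design (no covariates, no rows): the coefficient posterior
        is its N(0,1) prior."""
        d = make_design(np.empty((0, 0)), np.empty(0))
        spec = fb.ModelSpec("y", (), site_varying_intercept=False,
                            site_varying_slopes=False)
        res = fb.fit_linear_model(d, spec, fb.McmcSettings(2, 100, 5000, seed=9))
        s = res.summary.loc["alpha"]
        N = 2 * 5000
        assert abs(s["mean"]) < 3 / np.sqrt(N)
        assert abs(s["sd"] - 1.0) < 3 * np.sqrt(2.0 / N) + 0.01
        assert (res.samples("sigma") > 0).all()


class TestLogPosterior:
    def test_gaussian_zero_residual_closed_form(self):
        n = 17
        d = make_design(np.zeros((n, 2)), np.zeros(n))
        spec = shared_spec(2)
        params = np.zeros(4)  # alpha, 2 betas, then sigma
        params[3] = 1.0
        got = log_posterior(params, d, spec)
        # independent closed form: N(0,1) likelihood at zero residuals +
        # standard-normal prior at 0 (3 coefs) + inverse-gamma(2,1) on
        # sigma^2 with the sigma-space Jacobian
        expected = (
            -0.5 * n * np.log(2 * np.pi)
            + 3 * stats.norm.logpdf(0.0)
            + stats.invgamma.logpdf(1.0, 2.0, scale=1.0)
            + np.log(2.0)
        )
        assert got == pytest.approx(expected, abs=1e-10)

    def test_logistic_all_half_probabilities(self):
        rng = np.random.default_rng(2)
        n = 40
        d = make_design(rng.normal(size=(n, 2)), rng.integers(0, 2, n))
        spec = shared_spec(2, BERNOULLI_LOGIT)
        params = np.zeros(3)
        got = log_posterior(params, d, spec)
        prior = 3 * stats.norm.logpdf(0.0)
        assert got - prior == pytest.approx(n * np.log(0.5), abs=1e-10)

    def test_sigma_nonpositive_is_minus_inf(self):
        d = make_design(np.zeros((3, 1)), np.zeros(3))
        assert log_posterior(np.array([0.0, 0.0, -1.0]), d, shared_spec(1)) == -np.inf

    @pytest.mark.parametrize("likelihood", ["gaussian", "bernoulli_logit"])
    def test_dual_implementation_oracle(self, likelihood):
        """100 random points vs an independently coded scipy-based density."""
        rng = np.random.default_rng(7)
        n, p = 25, 2
        X = rng.normal(size=(n, p))
        sites = np.repeat(["north", "south"], [12, 13])
        if likelihood == "gaussian":
            y = rng.normal(size=n)
        else:
            y = rng.integers(0, 2, n).astype(float)
        d = make_design(X, y, sites=sites)
        spec = fb.ModelSpec("y", ("x0", "x1"), likelihood)  # site-varying
        Z, names, _ = build_design(d, spec)
        k = Z.shape[1]

        def oracle(params):
            coefs = params[:k]
            lp = stats.norm.logpdf(coefs).sum()
            eta = Z @ coefs
            if likelihood == "gaussian":
                sigma = params[k]
                lp += stats.invgamma.logpdf(sigma**2, 2.0, scale=1.0)
                lp += np.log(2 * sigma)
                lp += stats.norm.logpdf(y, loc=eta, scale=sigma).sum()
            else:
                lp += stats.bernoulli.logpmf(y.astype(int), stats.logistic.cdf(eta)).sum()
            return lp

        for _ in range(100):
            params = rng.normal(size=k + (1 if likelihood == "gaussian" else 0))
            if likelihood == "gaussian":
                params[-1] = abs(params[-1]) + 0.1
            got = log_posterior(params, d, spec)
            assert got == pytest.approx(oracle(params), abs=1e-8)


# --- convergence diagnostics ---------------------------------------------------


class TestRhat:
    def test_stationary_chain(self):
        rng = np.random.default_rng(0)
        draws = rng.normal(size=20000).reshape(2, 10000)
        assert 1.0 <= compute_rhat(draws) <= 1.01

    def test_disjoint_chains(self):
        rng = np.random.default_rng(0)
        draws = np.vstack(
            [rng.normal(-10, 1, 500), rng.normal(10, 1, 500)]
        )
        assert compute_rhat(draws) > 1.1

    def test_constant_chains_convention(self):
        with pytest.warns(RuntimeWarning, match="zero within-chain variance"):
            assert compute_rhat(np.ones((2, 100))) == 1.0

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="chains"):
            compute_rhat(np.zeros((1, 100)))

    def test_matches_arviz_split_rhat(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(3)
        draws = np.cumsum(rng.normal(size=(2, 400)), axis=1) * 0.01 + rng.normal(
            size=(2, 400)
        )
        ours = compute_rhat(draws)
        theirs = float(az.rhat(az.convert_to_dataset(draws), method="split")["x"])
        assert ours == pytest.approx(theirs, abs=1e-8)


# --- recovery ------------------------------------------------------------------


class TestRecovery:
    def test_gaussian_recovery_n2000(self, fast_settings):
        """Posterior means of all yield-model betas within 3 posterior SDs of
        generator truth at n = 2,000, sigma = 0.5.

        The response is put on the generator's own standardized scale (config
        pooled moments) — the scale the true betas are defined on; sample
        re-standardization would rescale every coefficient by the realized
        response SD and no longer target the truth."""
        cfg = fb.default_config_from_table1(households_per_site=125, seed=42)
        truth = dataclasses.replace(fb.default_truth(cfg), sigma=0.5)
        df, _ = fb.simulate_dataset(cfg, truth=truth)
        assert len(df) == 2000
        ym, ys = cfg.pooled_moments("yield_kg_ha")
        df = df.assign(yield_z=(df["yield_kg_ha"] - ym) / ys)
        d = fb.standardize(df, list(fb.YIELD_COVARIATES), "yield_z",
                           standardize_response=False)
        spec = fb.ModelSpec("yield_z", fb.YIELD_COVARIATES)
        res = fb.fit_linear_model(d, spec, dataclasses.replace(fast_settings, draws=2000))
        summ = res.summary
        for name, info in res.param_info.items():
            if info.kind != "beta":
                continue
            true_val = truth.beta[info.site][info.covariate]
            z = abs(summ.loc[name, "mean"] - true_val) / summ.loc[name, "sd"]
            assert z < 3, (name, true_val, summ.loc[name, "mean"])

    def test_logistic_slope_recovery(self, fast_settings):
        rng = np.random.default_rng(10)
        n = 2000
        x = rng.normal(size=n)
        eta = 1.0 * x  # known log-odds slope on a standardized covariate
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        d = make_design(x[:, None], y)
        res = fb.fit_logistic_model(
            d, shared_spec(1, BERNOULLI_LOGIT),
            dataclasses.replace(fast_settings, draws=2000),
        )
        s = res.summary.loc["beta[x0]"]
        assert abs(s["mean"] - 1.0) < 3 * s["sd"]
        s0 = res.summary.loc["alpha"]
        assert abs(s0["mean"]) < 3 * s0["sd"]

    def test_logistic_symmetric_null(self, fast_settings):
        rng = np.random.default_rng(11)
        n = 2000
        X = rng.normal(size=(n, 2))
        y = rng.integers(0, 2, n).astype(float)
        d = make_design(X, y)
        res = fb.fit_logistic_model(d, shared_spec(2, BERNOULLI_LOGIT), fast_settings)
        for name in res.parameters:
            s = res.summary.loc[name]
            assert abs(s["mean"]) < 3 * s["sd"] + 0.05

    def test_hurdle_sign_recovery(self, fast_settings):
        """Incidence slope +0.8 on low fertilizer and level slope -0.5 on
        compost both recovered with decisive posterior sign at n = 2,000."""
        cfg = fb.default_config_from_table1(households_per_site=125, seed=77)
        truth = fb.default_truth(cfg)
        for site in cfg.sites:
            truth.striga_incidence_logit[site].update(
                {"fertilizer": -0.8, "intercept": 0.0}
            )
            truth.striga_level_coefs[site].update({"compost": -0.9})
        df, _ = fb.simulate_dataset(cfg, truth=truth)
        d = fb.standardize(df, list(fb.BASE_COVARIATES), "striga_count",
                           standardize_response=False)
        inc_spec = fb.ModelSpec(
            "striga_present", fb.BASE_COVARIATES, BERNOULLI_LOGIT,
            site_varying_intercept=False, site_varying_slopes=False,
        )
        lvl_spec = fb.ModelSpec(
            "striga_level", fb.BASE_COVARIATES,
            site_varying_intercept=False, site_varying_slopes=False,
        )
        hur = fb.fit_hurdle_striga(d, inc_spec, lvl_spec, fast_settings)
        assert hur.n_level == int((df["striga_count"] >= 1).sum())
        p_fert = hur.incidence.summary.loc["beta[fertilizer]", "prob_positive"]
        assert p_fert < 0.05  # more fertilizer, less striga incidence
        p_comp = hur.level.summary.loc["beta[compost]", "prob_positive"]
        assert p_comp < 0.05

    def test_hurdle_all_zero_counts_rejected(self, small_dataset):
        df, _ = small_dataset
        df = df.copy()
        df["striga_count"] = 0
        d = fb.standardize(df, list(fb.BASE_COVARIATES), "striga_count",
                           standardize_response=False)
        spec = fb.ModelSpec("striga_present", fb.BASE_COVARIATES, BERNOULLI_LOGIT)
        lvl = fb.ModelSpec("striga_level", fb.BASE_COVARIATES)
        with pytest.raises(ValueError, match="positive"):
            fb.fit_hurdle_striga(d, spec, lvl, fb.McmcSettings(seed=0, draws=10))

    def test_site_varying_fit_on_shared_beta(self, fast_settings):
        """Data generated with one shared slope: per-site posteriors must not
        differ by more than 3 SDs of the pairwise difference."""
        rng = np.random.default_rng(21)
        n = 1600
        sites = np.repeat(list("abcd"), n // 4)
        x = rng.normal(size=n)
        y = 0.5 * x + 0.7 * rng.normal(size=n)
        d = make_design(x[:, None], y, sites=sites)
        spec = fb.ModelSpec("y", ("x0",))
        res = fb.fit_linear_model(d, spec, fast_settings)
        names = [f"beta[{s}][x0]" for s in "abcd"]
        for i in range(4):
            for j in range(i + 1, 4):
                diff = res.samples(names[i]) - res.samples(names[j])
                assert abs(diff.mean()) < 3 * diff.std(ddof=1)


class TestContracts:
    def test_seeded_reproducibility(self, small_dataset, fast_settings):
        df, _ = small_dataset
        d = fb.standardize(df, list(fb.BASE_COVARIATES), "spad")
        spec = fb.ModelSpec("spad", fb.BASE_COVARIATES)
        r1 = fb.fit_linear_model(d, spec, fast_settings)
        r2 = fb.fit_linear_model(d, spec, fast_settings)
        pd.testing.assert_frame_equal(r1.summary, r2.summary)

    def test_logistic_requires_binary_response(self, small_dataset, fast_settings):
        df, _ = small_dataset
        d = fb.standardize(df, list(fb.BASE_COVARIATES), "spad")
        spec = fb.ModelSpec("spad", fb.BASE_COVARIATES, BERNOULLI_LOGIT)
        with pytest.raises(ValueError, match="0/1"):
            fb.fit_logistic_model(d, spec, fast_settings)

    def test_zero_column_design_rejected(self, fast_settings):
        X = np.zeros((20, 1))
        X[:, 0] = 0.0
        rng = np.random.default_rng(0)
        d = make_design(X, rng.normal(size=20))
        with pytest.raises(ValueError, match="singular"):
            fb.fit_linear_model(d, shared_spec(1), fast_settings)

    def test_posterior_result_round_trip(self, small_dataset, fast_settings, tmp_path):
        df, _ = small_dataset
        d = fb.standardize(df, list(fb.BASE_COVARIATES), "spad")
        spec = fb.ModelSpec("spad", fb.BASE_COVARIATES)
        res = fb.fit_linear_model(d, spec, fast_settings)
        path = tmp_path / "draws.npz"
        res.save(path)
        back = fb.PosteriorResult.load(path)
        assert back.parameters == res.parameters
        np.testing.assert_array_equal(back.draws["sigma"], res.draws["sigma"])
        pd.testing.assert_frame_equal(back.summary, res.summary)

    def test_quantile_ordering_and_sigma_positive(self, small_dataset, fast_settings):
        df, _ = small_dataset
        d = fb.standardize(df, list(fb.BASE_COVARIATES), "spad")
        res = fb.fit_linear_model(
            d, fb.ModelSpec("spad", fb.BASE_COVARIATES), fast_settings
        )
        s = res.summary
        assert (s["q2.5"] <= s["q50"]).all() and (s["q50"] <= s["q97.5"]).all()
        assert s["prob_positive"].between(0, 1).all()
        assert (res.samples("sigma") > 0).all()
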