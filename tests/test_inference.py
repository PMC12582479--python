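import numpy as np
import pytest
from scipy import stats

import thermoload as tl
from thermoload.inference import _MarginalModel
from thermoload.ssm_core import PriorConfig, second_difference, env_residuals, init_prior_centres


# -- convergence diagnostics ------------------------------------------------


def test_rhat_iid_chains_near_one():
    rng = np.random.default_rng(0)
    draws = rng.standard_normal((4, 2000))
    assert tl.rhat(draws) == pytest.approx(1.0, abs=0.01)


def test_rhat_detects_divergent_chains():
    rng = np.random.default_rng(1)
    draws = np.stack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
    assert tl.rhat(draws) > 1.1


def test_rhat_constant_chains_flagged():
    assert np.isnan(tl.rhat(np.ones((4, 100))))
    with pytest.raises(ValueError):
        tl.rhat(np.ones(100))


def test_ess_iid_draws_near_total():
    rng = np.random.default_rng(2)
    draws = rng.standard_normal((4, 2000))
    assert tl.ess(draws) == pytest.approx(8000, rel=0.15)


def test_ess_autocorrelated_chain_much_smaller():
    """AR(1) with rho = 0.9 has ESS about n(1-rho)/(1+rho), far below n."""
    rng = np.random.default_rng(3)
    rho = 0.9
    draws = np.empty((4, 2000))
    for c in range(4):
        x = 0.0
        for t in range(2000):
            x = rho * x + rng.normal(0, np.sqrt(1 - rho**2))
            draws[c, t] = x
    e = tl.ess(draws)
    assert e < 0.2 * 8000
    assert e == pytest.approx(8000 * (1 - rho) / (1 + rho), rel=0.5)


def test_ess_constant_flagged():
    assert np.isnan(tl.ess(np.zeros((4, 100))))


# -- credible bands and the overlap rule ------------------------------------


def test_credible_band_degenerate_draws():
    post_draws = np.full((200, 5), 3.25)
    band = tl.CredibleBand(
        level=0.95,
        lower=np.quantile(post_draws, 0.025, axis=0),
        upper=np.quantile(post_draws, 0.975, axis=0),
    )
    np.testing.assert_array_equal(band.lower, band.upper)


def test_credible_band_normal_quantiles(toy_posterior):
    rng = np.random.default_rng(4)
    draws = rng.standard_normal((200_000, 1))
    lower = np.quantile(draws, 0.025, axis=0)
    upper = np.quantile(draws, 0.975, axis=0)
    assert lower[0] == pytest.approx(-1.96, abs=0.05)
    assert upper[0] == pytest.approx(1.96, abs=0.05)


def test_credible_band_nesting(toy_posterior):
    b50 = tl.credible_band(toy_posterior, "load", "T_26-31", level=0.5)
    b95 = tl.credible_band(toy_posterior, "load", "T_26-31", level=0.95)
    assert np.all(b95.lower <= b50.lower)
    assert np.all(b50.upper <= b95.upper)
    with pytest.raises(ValueError):
        tl.credible_band(toy_posterior, "load", "T_26-31", level=1.2)


@pytest.mark.parametrize(
    "i1,i2,verdict",
    [
        (([0.0], [1.0]), ([2.0], [3.0]), "separated"),
        (([0.0], [2.0]), ([1.0], [3.0]), "overlapping"),
        (([0.0], [1.0]), ([1.0], [2.0]), "overlapping"),  # touching endpoints
    ],
)
def test_compare_conditions_verdicts(i1, i2, verdict):
    b1 = tl.CredibleBand(level=0.95, lower=i1[0], upper=i1[1])
    b2 = tl.CredibleBand(level=0.95, lower=i2[0], upper=i2[1])
    assert tl.compare_conditions(b1, b2, at=1) == verdict
    assert tl.compare_conditions(b2, b1, at=1) == verdict  # symmetry


def test_compare_conditions_grid_mismatch():
    b1 = tl.CredibleBand(level=0.95, lower=[0.0, 0.0], upper=[1.0, 1.0])
    b2 = tl.CredibleBand(level=0.95, lower=[0.0], upper=[1.0])
    with pytest.raises(ValueError):
        tl.compare_conditions(b1, b2, at=1)


# -- marginal-likelihood machinery vs the joint density ---------------------


def test_marginal_model_consistent_with_log_joint():
    """For the Normal-Load variant, p(y|theta) * N(z | mu, Q^-1) must equal
    the state priors times the likelihood at any z, i.e. the assembled
    marginal agrees with the independently coded log_joint."""
    params = tl.HyperParams(
        sigma_obs={c: 0.3 + 0.05 * i for i, c in enumerate(tl.CONDITIONS)},
        sigma_base=0.2,
        sigma_load=0.15,
        sigma_env=0.25,
        h=0.7,
        period=4,
        load_noise_family="normal",
    )
    truth = tl.model_dataset(params, T=9, seed=6)
    y = truth.y
    priors = PriorConfig(init_scale=3.0)
    model = _MarginalModel(y, priors)
    sig_obs = np.array([params.sigma_obs[c] for c in tl.CONDITIONS])
    lam = np.full((3, y.T - 2), params.sigma_load**2)
    ml, cb, mu = model.marginal(sig_obs, params.sigma_base, lam, params.sigma_env, params.h)

    rng = np.random.default_rng(7)
    for _ in range(3):
        states = model.draw_states(cb, mu, rng)
        z = np.empty(model.n)
        z[model.base_idx] = states.base
        for j in range(3):
            z[model.load_idx[j]] = states.load[j]
            z[model.env_idx[j]] = states.env[j]
        # log N(z | mu, Q^-1) via the quadratic form computed from residuals
        quad = 0.0
        for i, cond in enumerate(tl.CONDITIONS):
            res = (tl.predicted_mean(states, cond) - y.y[i])[y.observed[i]]
            quad += float(res @ res) / params.sigma_obs[cond] ** 2
        # recompute against mu-states
        mu_states = tl.StateComponents(
            base=mu[model.base_idx],
            load=np.stack([mu[model.load_idx[j]] for j in range(3)]),
            env=np.stack([mu[model.env_idx[j]] for j in range(3)]),
        )
        lj_z = tl.log_joint(y, states, params, priors)
        lj_mu = tl.log_joint(y, mu_states, params, priors)
        # remove hyperparameter priors (identical in both, cancel in diff)
        # p(y,z)/p(y,mu) must equal N(z|mu,Q^-1)/N(mu|mu,Q^-1)
        d = z - mu
        quad_d = _quadratic_form(model, params, y, priors, d)
        assert lj_z - lj_mu == pytest.approx(-0.5 * quad_d, abs=1e-7)
        # and the marginal + conditional identity at z = mu:
        logdet = 2.0 * float(np.sum(np.log(cb[-1])))
        log_cond_mu = 0.5 * logdet - 0.5 * model.n * np.log(2 * np.pi)
        hyper_prior = 0.0
        for c in tl.CONDITIONS:
            hyper_prior += stats.halfnorm.logpdf(params.sigma_obs[c], scale=priors.sigma_obs_scale)
        hyper_prior += stats.halfnorm.logpdf(params.sigma_base, scale=priors.sigma_base_scale)
        hyper_prior += stats.halfnorm.logpdf(params.sigma_load, scale=priors.sigma_load_scale)
        hyper_prior += stats.halfnorm.logpdf(params.sigma_env, scale=priors.sigma_env_scale)
        assert ml + log_cond_mu == pytest.approx(lj_mu - hyper_prior, abs=1e-7)


def _quadratic_form(model, params, y, priors, d):
    """(d' Q d) computed term by term from the model residual operators."""
    states_d = tl.StateComponents(
        base=d[model.base_idx],
        load=np.stack([d[model.load_idx[j]] for j in range(3)]),
        env=np.stack([d[model.env_idx[j]] for j in range(3)]),
    )
    quad = 0.0
    for i, cond in enumerate(tl.CONDITIONS):
        res = tl.predicted_mean(states_d, cond)[y.observed[i]]
        quad += float(res @ res) / params.sigma_obs[cond] ** 2
    quad += float(np.sum(second_difference(states_d.base) ** 2)) / params.sigma_base**2
    quad += float(np.sum(second_difference(states_d.load) ** 2)) / params.sigma_load**2
    for j in range(3):
        r = env_residuals(states_d.env[j], params.h, params.period)
        quad += float(r @ r) / params.sigma_env**2
    w0 = 1.0 / priors.init_scale**2
    quad += w0 * float(np.sum(states_d.base[:2] ** 2))
    quad += w0 * float(np.sum(states_d.load[:, :2] ** 2))
    quad += w0 * float(np.sum(states_d.env[:, : params.period - 1] ** 2))
    return quad


# -- fitting ---------------------------------------------------------------


def test_fit_shapes_and_meta(toy_posterior, toy_truth):
    post = toy_posterior
    assert post.base.shape == (2, 150, 12)
    assert post.load.shape == (2, 150, 3, 12)
    assert post.sigma_obs.shape == (2, 150, 4)
    assert post.meta["seed"] == 5
    assert post.n_chains == 2 and post.n_draws == 150


def test_fit_is_deterministic_under_seed(toy_truth):
    cfg = tl.MCMCConfig(chains=2, warmup=20, sampling=30, seed=9)
    p1 = tl.fit(toy_truth.y, mcmc=cfg)
    p2 = tl.fit(toy_truth.y, mcmc=cfg)
    np.testing.assert_array_equal(p1.base, p2.base)
    np.testing.assert_array_equal(p1.sigma_load, p2.sigma_load)


def test_fit_with_masked_observation_returns_missing_value_posterior(toy_truth):
    y2 = toy_truth.y.mask("T_26-31", 1)
    post = tl.fit(y2, mcmc=tl.MCMCConfig(chains=2, warmup=50, sampling=100, seed=3))
    draws = post.component_draws("predicted", "T_26-31")[:, 0]
    assert np.all(np.isfinite(draws))
    # the imputation stays on the scale of the surrounding data
    assert abs(np.mean(draws) - toy_truth.y.y[1, 1]) < 3.0


def test_fit_base_tracks_control_when_noise_tiny():
    T, N = 10, 4
    base = 5.0 + 0.1 * np.arange(T)
    rng = np.random.default_rng(11)
    y = np.tile(base, (4, 1)) + rng.normal(0, 0.02, (4, T))
    series = tl.MeasurementSeries(modality="hf", y=y, period=N)
    post = tl.fit(series, mcmc=tl.MCMCConfig(chains=2, warmup=100, sampling=150, seed=2))
    mean = post.component_draws("base", None).mean(axis=0)
    sd = post.component_draws("base", None).std(axis=0)
    assert np.all(np.abs(mean - y[0]) < 2 * sd + 0.05)


def test_fit_input_validation(toy_truth):
    with pytest.raises(ValueError):
        tl.fit(toy_truth.y, variant="bogus")
    empty = tl.MeasurementSeries(
        modality="hf", y=np.full((4, 8), np.nan), period=4
    )
    with pytest.raises(ValueError):
        tl.fit(empty)


# -- forecasting ------------------------------------------------------------


def test_forecast_returns_bands_and_coverage(toy_truth):
    result = tl.forecast(
        toy_truth.y, split=8, mcmc=tl.MCMCConfig(chains=2, warmup=80, sampling=120, seed=4),
        level=0.5,
    )
    assert set(result.bands) == set(tl.CONDITIONS)
    assert result.times.tolist() == [9, 10, 11, 12]
    assert 0.0 <= result.coverage <= 1.0
    # the prediction variant fixes the Env recursion's damping at 1
    assert result.posterior.meta["fix_h"] == 1.0
    assert result.posterior.meta["variant"] == "prediction"
    np.testing.assert_array_equal(result.posterior.h, 1.0)


def test_forecast_bands_widen_with_horizon():
    """A pure-trend series forecast accumulates state variance, so the
    predictive band grows with the horizon."""
    T = 16
    rng = np.random.default_rng(13)
    base = 5.0 + 0.2 * np.arange(T) + np.cumsum(np.cumsum(rng.normal(0, 0.05, T)))
    y = np.tile(base, (4, 1)) + rng.normal(0, 0.1, (4, T))
    series = tl.MeasurementSeries(modality="hf", y=y, period=4)
    result = tl.forecast(
        series, split=10, mcmc=tl.MCMCConfig(chains=2, warmup=100, sampling=200, seed=5),
        level=0.9,
    )
    width = result.bands["T_26-26"].upper - result.bands["T_26-26"].lower
    assert width[-1] > width[0]
    assert np.mean(width[3:]) > np.mean(width[:3])


def test_forecast_split_validation(toy_truth):
    with pytest.raises(ValueError):
        tl.forecast(toy_truth.y, split=12)
    with pytest.raises(ValueError):
        tl.forecast(toy_truth.y, split=2)


# -- summaries --------------------------------------------------------------


def test_summarize_columns_and_means(toy_posterior):
    df = tl.summarize(toy_posterior)
    assert list(df.columns) == ["component", "condition", "t", "mean", "q2.5", "q25", "q75", "q97.5"]
    sub = df[(df.component == "base") & (df.t == 1)]
    assert sub["mean"].iloc[0] == pytest.approx(
        float(toy_posterior.base[:, :, 0].mean())
    )
    assert (df["q2.5"] <= df["q25"]).all() and (df["q75"] <= df["q97.5"]).all()


def test_hyperparameter_diagnostics_table(toy_posterior):
    table = tl.hyperparameter_diagnostics(toy_posterior)
    assert len(table) == 8
    assert set(["parameter", "rhat", "ess", "mean", "sd"]) <= set(table.columns)
    assert table["ess"].gt(0).all()
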