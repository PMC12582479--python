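"""Posterior inference for the Base/Load/Env decomposition.

The model is conditionally linear-Gaussian: given the noise scales, the
damping factor and (for the analysis variant) per-innovation auxiliary
variances representing the Cauchy Load noise as a normal scale mixture,
the full latent state vector is jointly Gaussian and can be integrated
out in closed form.  Each sampler iteration therefore

1. slice-samples every noise scale and the damping factor h against the
   state-marginal likelihood p(y | scales, h, mixture variances) -- one
   Cholesky factorization of the joint state precision per evaluation --
   so hyperparameter draws are nearly uncorrelated;
2. draws all latent states exactly from their joint Gaussian full
   conditional (same factorization);
3. refreshes the Cauchy mixture variances by their conjugate
   inverse-gamma conditionals, parameterized as sigma_load^2 times a
   scale-free shape so the Load scale itself stays marginal.

With states integrated out of every hyperparameter move, the usual MCMC
budget (4 chains, 2000 warm-up + 2000 sampling) gives well-converged
chains.  Convergence is judged with rank-normalized split R-hat and bulk
effective sample size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import arviz as az
import numpy as np
import pandas as pd
from scipy.linalg import cho_solve_banded, cholesky_banded, solve_banded

from .protocol import CONDITIONS
from .ssm_core import (
    LOADED,
    MeasurementSeries,
    PriorConfig,
    StateComponents,
    init_prior_centres,
)

HYPER_NAMES = (
    "sigma_obs[T_26-26]",
    "sigma_obs[T_26-31]",
    "sigma_obs[T_26-36]",
    "sigma_obs[T_21-36]",
    "sigma_base",
    "sigma_load",
    "sigma_env",
    "h",
)

#: convergence thresholds used to declare a fit reliable
RHAT_THRESHOLD = 1.05
ESS_THRESHOLD = 1000.0


@dataclass(frozen=True)
class MCMCConfig:
    chains: int = 4
    warmup: int = 2000
    sampling: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chains < 1 or self.warmup < 0 or self.sampling < 1:
            raise ValueError("invalid MCMC configuration")


@dataclass(frozen=True)
class DecompositionPosterior:
    """MCMC draws of the latent components and hyperparameters.

    Arrays are indexed (chain, draw, ...); ``load``/``env`` additionally
    carry a leading condition axis ordered b, c, d.
    """

    base: np.ndarray  # (chains, draws, T)
    load: np.ndarray  # (chains, draws, 3, T)
    env: np.ndarray  # (chains, draws, 3, T)
    sigma_obs: np.ndarray  # (chains, draws, 4)
    sigma_base: np.ndarray  # (chains, draws)
    sigma_load: np.ndarray
    sigma_env: np.ndarray
    h: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return int(self.base.shape[0])

    @property
    def n_draws(self) -> int:
        return int(self.base.shape[1])

    @property
    def T(self) -> int:
        return int(self.base.shape[2])

    def hyper_draws(self, name: str) -> np.ndarray:
        """(chains, draws) array of one hyperparameter."""
        if name.startswith("sigma_obs["):
            cond = name[len("sigma_obs[") : -1]
            return self.sigma_obs[:, :, CONDITIONS.index(cond)]
        return getattr(self, name)

    def component_draws(self, component: str, condition: str | None = None) -> np.ndarray:
        """Flattened (chains*draws, T) draws of one trajectory.

        ``component`` is 'base', 'load', 'env' or 'predicted' (the
        noise-free observation mean of ``condition``).
        """
        if component == "base":
            arr = self.base
        elif component in ("load", "env"):
            if condition is None or condition == CONDITIONS[0]:
                raise ValueError("load/env require a non-control condition")
            j = LOADED.index(condition)
            arr = getattr(self, component)[:, :, j]
        elif component == "predicted":
            if condition is None:
                raise ValueError("predicted requires a condition")
            if condition == CONDITIONS[0]:
                arr = self.base
            else:
                j = LOADED.index(condition)
                arr = self.base + self.load[:, :, j] + self.env[:, :, j]
        else:
            raise ValueError(f"unknown component {component!r}")
        return arr.reshape(-1, arr.shape[-1])

    def to_inference_data(self) -> az.InferenceData:
        coords = {"condition": list(LOADED), "time": np.arange(1, self.T + 1)}
        data = {
            "base": (["chain", "draw", "time"], self.base),
            "load": (["chain", "draw", "condition", "time"], self.load),
            "env": (["chain", "draw", "condition", "time"], self.env),
            "sigma_base": (["chain", "draw"], self.sigma_base),
            "sigma_load": (["chain", "draw"], self.sigma_load),
            "sigma_env": (["chain", "draw"], self.sigma_env),
            "h": (["chain", "draw"], self.h),
        }
        for i, cond in enumerate(CONDITIONS):
            data[f"sigma_obs[{cond}]"] = (["chain", "draw"], self.sigma_obs[:, :, i])
        return az.from_dict(
            posterior={k: v for k, (_, v) in data.items()},
            coords=coords,
            dims={
                "base": ["time"],
                "load": ["condition", "time"],
                "env": ["condition", "time"],
            },
        )


@dataclass(frozen=True)
class CredibleBand:
    """Central posterior interval of one trajectory, per time point."""

    level: float
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        if not (0.0 < self.level < 1.0):
            raise ValueError("level must lie in (0, 1)")
        lower = np.atleast_1d(np.asarray(self.lower, float))
        upper = np.atleast_1d(np.asarray(self.upper, float))
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if lower.shape != upper.shape:
            raise ValueError("lower/upper shape mismatch")
        if np.any(lower > upper + 1e-12):
            raise ValueError("lower bound exceeds upper bound")


@dataclass(frozen=True)
class ForecastResult:
    """Posterior-predictive forecast of the held-out final set."""

    split: int  # last 1-based time index used for fitting
    level: float
    times: np.ndarray  # 1-based forecast indices
    bands: dict[str, CredibleBand]  # per condition, over `times`
    held_out: np.ndarray | None  # (4, horizon) with NaN where unobserved
    coverage: float | None
    posterior: DecompositionPosterior


# --------------------------------------------------------------------------
# slice sampler


def _slice_sample(logp, x0: float, rng: np.random.Generator, width: float = 1.0,
                  max_steps: int = 50, logp0: float | None = None):
    """One update of Neal's stepping-out/shrinkage slice sampler.

    Returns (x1, logp(x1)); passing the known ``logp0`` at ``x0`` saves one
    evaluation.
    """
    lp0 = logp(x0) if logp0 is None else logp0
    y = lp0 + math.log(rng.random())
    u = rng.random()
    lo, hi = x0 - width * u, x0 + width * (1.0 - u)
    for _ in range(max_steps):
        if logp(lo) <= y:
            break
        lo -= width
    for _ in range(max_steps):
        if logp(hi) <= y:
            break
        hi += width
    for _ in range(200):
        x1 = lo + (hi - lo) * rng.random()
        lp1 = logp(x1)
        if lp1 > y:
            return x1, lp1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0, lp0


# --------------------------------------------------------------------------
# model structure for the Gaussian state draw


class _MarginalModel:
    """Banded precision assembly and state-marginal likelihood.

    Every Gaussian factor of the model is a scalar term
    N(a_r' z | m_r, v_r); collecting them gives the state full-conditional
    precision Q = sum a a' / v and linear term b = sum a m / v, and the
    state-marginal log p(y | scales, h, mixture shapes) follows from one
    Cholesky factorization of Q (log-determinant plus completed square).

    States are interleaved by time (base, Load b/c/d, Env b/c/d per time
    point), which makes Q banded with bandwidth max(14, 7(N-1)); assembly
    uses precomputed flat indices into LAPACK upper-banded storage so each
    likelihood evaluation is one ``bincount`` plus one banded Cholesky.
    The Env coefficients carry powers of h, so every precision entry is
    coef * h**p / v_r with constant coef and p in {0, 1, 2}.
    """

    def __init__(self, y: MeasurementSeries, priors: PriorConfig):
        T, N = y.T, y.period
        self.y = y
        self.priors = priors
        self.T, self.N = T, N
        self.n = 7 * T
        self.bw = max(14, 7 * (N - 1))
        t_all = 7 * np.arange(T)
        self.base_idx = t_all
        self.load_idx = [t_all + 1 + j for j in range(3)]
        self.env_idx = [t_all + 4 + j for j in range(3)]
        centres = init_prior_centres(y)

        terms_cols: list[np.ndarray] = []  # state indices of each term
        terms_coef: list[np.ndarray] = []  # coefficients (h excluded)
        terms_hpow: list[np.ndarray] = []  # power of h carried per column
        terms_m: list[float] = []  # term means
        nz = np.zeros

        def add(cols, coef, hpow, m):
            terms_cols.append(np.asarray(cols))
            terms_coef.append(np.asarray(coef, float))
            terms_hpow.append(np.asarray(hpow))
            terms_m.append(float(m))

        # observations, in condition order (control touches base only)
        self.obs_term_idx: list[np.ndarray] = []
        for i in range(4):
            ids = []
            for t in np.flatnonzero(y.observed[i]):
                ids.append(len(terms_cols))
                if i == 0:
                    add([t_all[t]], [1.0], [0], y.y[i, t])
                else:
                    j = i - 1
                    add(
                        [t_all[t], self.load_idx[j][t], self.env_idx[j][t]],
                        [1.0, 1.0, 1.0],
                        [0, 0, 0],
                        y.y[i, t],
                    )
            self.obs_term_idx.append(np.asarray(ids, dtype=int))

        # Base trend second differences
        ids = []
        for t in range(T - 2):
            ids.append(len(terms_cols))
            add(t_all[[t, t + 1, t + 2]], [1.0, -2.0, 1.0], nz(3, int), 0.0)
        self.base_term_idx = np.asarray(ids, dtype=int)

        # Load trend second differences (per-innovation variances lam)
        ids = []
        for j in range(3):
            for t in range(T - 2):
                ids.append(len(terms_cols))
                add(self.load_idx[j][[t, t + 1, t + 2]], [1.0, -2.0, 1.0], nz(3, int), 0.0)
        self.load_term_idx = np.asarray(ids, dtype=int)  # ordered like lam.ravel()

        # Env recursion: Env_t + h * sum of previous N-1 values
        ids = []
        for j in range(3):
            for t in range(N - 1, T):
                ids.append(len(terms_cols))
                cols = self.env_idx[j][t - N + 1 : t + 1]
                coef = np.ones(N)
                hpow = np.ones(N, dtype=int)
                hpow[-1] = 0  # the Env_t column carries no h
                add(cols, coef, hpow, 0.0)
        self.env_term_idx = np.asarray(ids, dtype=int)

        # initial-state priors (centred per init_prior_centres)
        ids = []
        init_cols = [t_all[0], t_all[1]]
        init_means = [centres.base[0], centres.base[1]]
        for j in range(3):
            init_cols += [self.load_idx[j][0], self.load_idx[j][1]]
            init_means += [centres.load[j, 0], centres.load[j, 1]]
            init_cols += list(self.env_idx[j][: N - 1])
            init_means += [0.0] * (N - 1)
        for col, m in zip(init_cols, init_means):
            ids.append(len(terms_cols))
            add([col], [1.0], [0], m)
        self.init_term_idx = np.asarray(ids, dtype=int)

        # flatten all upper-triangle pair contributions
        self.n_terms = len(terms_cols)
        slot, pair_coef, pair_hpow, pair_term = [], [], [], []
        b_col, b_coef, b_term = [], [], []
        for r, (cols, coef, hpow) in enumerate(zip(terms_cols, terms_coef, terms_hpow)):
            for a in range(cols.size):
                for bb in range(a, cols.size):
                    i, j = cols[a], cols[bb]
                    ca, cb = coef[a], coef[bb]
                    if i > j:
                        i, j = j, i
                    slot.append((self.bw + i - j) * self.n + j)
                    pair_coef.append(ca * cb)
                    pair_hpow.append(hpow[a] + hpow[bb])
                    pair_term.append(r)
            m = terms_m[r]
            if m != 0.0:
                for a in range(cols.size):
                    b_col.append(cols[a])
                    b_coef.append(coef[a] * m)
                    b_term.append(r)
        self._slot = np.asarray(slot, dtype=np.intp)
        self._pair_coef = np.asarray(pair_coef)
        self._pair_hpow = np.asarray(pair_hpow, dtype=int)
        self._pair_term = np.asarray(pair_term, dtype=int)
        self._b_col = np.asarray(b_col, dtype=np.intp)
        self._b_coef = np.asarray(b_coef)
        self._b_term = np.asarray(b_term, dtype=int)
        self._msq = np.asarray(terms_m) ** 2
        self._v = np.empty(self.n_terms)
        self._ab_size = (self.bw + 1) * self.n

    def _variances(self, sigma_obs, sigma_base, lam, sigma_env):
        v = self._v
        for i in range(4):
            v[self.obs_term_idx[i]] = sigma_obs[i] ** 2
        v[self.base_term_idx] = sigma_base**2
        v[self.load_term_idx] = lam.ravel()
        v[self.env_term_idx] = sigma_env**2
        v[self.init_term_idx] = self.priors.init_scale**2
        return v

    def marginal(self, sigma_obs, sigma_base, lam, sigma_env, h):
        """Marginal log-likelihood plus the factorization for a state draw."""
        v = self._variances(sigma_obs, sigma_base, lam, sigma_env)
        w = 1.0 / v
        hp = np.array([1.0, h, h * h])
        contrib = self._pair_coef * hp[self._pair_hpow] * w[self._pair_term]
        ab = np.bincount(self._slot, weights=contrib, minlength=self._ab_size)
        ab = ab.reshape(self.bw + 1, self.n)
        b = np.bincount(
            self._b_col, weights=self._b_coef * w[self._b_term], minlength=self.n
        )
        cb = cholesky_banded(ab, lower=False, check_finite=False)
        mu = cho_solve_banded((cb, False), b, check_finite=False)
        c = float(self._msq @ w)
        lognorm = -0.5 * float(np.sum(np.log(2.0 * np.pi * v)))
        logdet = 2.0 * float(np.sum(np.log(cb[-1])))
        lp = (
            lognorm
            - 0.5 * c
            + 0.5 * self.n * math.log(2.0 * math.pi)
            - 0.5 * logdet
            + 0.5 * float(b @ mu)
        )
        self._last = (cb, mu)
        return lp, cb, mu

    def draw_states(self, cb, mu, rng) -> StateComponents:
        """z = mu + U^{-1} xi: exact draw from N(mu, Q^{-1})."""
        z = mu + solve_banded(
            (0, self.bw), cb, rng.standard_normal(self.n), check_finite=False
        )
        return StateComponents(
            base=z[self.base_idx],
            load=np.stack([z[self.load_idx[j]] for j in range(3)]),
            env=np.stack([z[self.env_idx[j]] for j in range(3)]),
        )


def _half_normal_logpdf(x: float, scale: float) -> float:
    return -0.5 * x * x / (scale * scale)


def _run_chain(
    y: MeasurementSeries,
    model: _MarginalModel,
    priors: PriorConfig,
    mcmc: MCMCConfig,
    variant: str,
    fix_h: float | None,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    T = model.T
    data_sd = float(np.std(y.y[y.observed])) or 1.0

    # initial values, jittered per chain
    sigma_obs = data_sd * 0.3 * np.exp(rng.normal(0.0, 0.3, size=4))
    sigma_base = data_sd * 0.1 * math.exp(rng.normal(0.0, 0.3))
    sigma_load = data_sd * 0.1 * math.exp(rng.normal(0.0, 0.3))
    sigma_env = data_sd * 0.1 * math.exp(rng.normal(0.0, 0.3))
    h = float(fix_h) if fix_h is not None else float(rng.uniform(0.2, 0.9))
    # Cauchy mixture variances lam = sigma_load^2 * xi; xi is scale-free so
    # sigma_load moves marginally of the states
    xi = np.ones((3, T - 2))

    n_keep = mcmc.sampling
    out = {
        "base": np.empty((n_keep, T)),
        "load": np.empty((n_keep, 3, T)),
        "env": np.empty((n_keep, 3, T)),
        "sigma_obs": np.empty((n_keep, 4)),
        "sigma_base": np.empty(n_keep),
        "sigma_load": np.empty(n_keep),
        "sigma_env": np.empty(n_keep),
        "h": np.empty(n_keep),
    }

    # hyperparameters on the log scale: (4 obs scales, base, load, env[, h])
    prior_scales = np.array(
        [priors.sigma_obs_scale] * 4
        + [priors.sigma_base_scale, priors.sigma_load_scale, priors.sigma_env_scale]
    )
    sample_h = fix_h is None
    n_par = 8 if sample_h else 7

    def theta():
        phi = np.empty(n_par)
        phi[:4] = np.log(sigma_obs)
        phi[4:7] = np.log([sigma_base, sigma_load, sigma_env])
        if sample_h:
            phi[7] = math.log(h)
        return phi

    def lp_full(phi):
        """Joint log-posterior of the log-scale hyperparameters, states
        integrated out (half-Normal scale priors, Uniform(0,1] on h,
        log-scale Jacobians)."""
        if np.any(np.abs(phi[:7]) > 12.0):
            return -np.inf
        sig = np.exp(phi[:7])
        hh = h
        if sample_h:
            if phi[7] > 0.0 or phi[7] < -12.0:
                return -np.inf
            hh = math.exp(phi[7])
        ml, _, _ = model.marginal(sig[:4], sig[4], sig[5] ** 2 * xi, sig[6], hh)
        lp = ml - 0.5 * float(np.sum((sig / prior_scales) ** 2)) + float(np.sum(phi[:7]))
        if sample_h:
            lp += phi[7]
        return lp

    total = mcmc.warmup + mcmc.sampling
    width = 0.4
    n_extra_directions = 2
    # per-update slice widths, adapted toward ~3x the typical accepted move
    # during warm-up only (kept fixed afterwards, so sampling is valid)
    widths = np.full(n_par + n_extra_directions, width)
    for it in range(total):
        # -- slice updates of the hyperparameters, states integrated out:
        # one sweep over coordinates, then random directions to track
        # posterior correlations among the scales
        phi = theta()
        lp_cur = lp_full(phi)
        for k in range(n_par + n_extra_directions):
            if k < n_par:
                d = np.zeros(n_par)
                d[k] = 1.0
            else:
                d = rng.standard_normal(n_par)
                d /= np.linalg.norm(d)
            alpha, lp_cur = _slice_sample(
                lambda a, d=d: lp_full(phi + a * d), 0.0, rng, widths[k], logp0=lp_cur
            )
            phi = phi + alpha * d
            if it < mcmc.warmup:
                widths[k] = 0.9 * widths[k] + 0.1 * (3.0 * abs(alpha) + 0.05)
        # one evaluation at the accepted point refreshes the cached
        # factorization for the state draw
        lp_cur = lp_full(phi)
        sigma_obs = np.exp(phi[:4])
        sigma_base, sigma_load, sigma_env = np.exp(phi[4:7])
        if sample_h:
            h = math.exp(phi[7])

        # -- exact joint state draw from the cached factorization
        cb, mu = model._last
        states = model.draw_states(cb, mu, rng)

        # -- Load-scale and mixture refresh (analysis variant only): given
        # the states, (sigma_load, xi) are conditionally independent of y,
        # so sigma_load is drawn from its Cauchy-likelihood conditional with
        # xi integrated out, then xi from its conjugate inverse-gamma
        if variant == "analysis":
            load_innov = states.load[:, 2:] - 2.0 * states.load[:, 1:-1] + states.load[:, :-2]

            def lp_sigma_load(x):
                if abs(x) > 12.0:
                    return -np.inf
                sig = math.exp(x)
                z2 = (load_innov / sig) ** 2
                lp = -float(np.sum(np.log1p(z2))) - load_innov.size * x
                return lp + _half_normal_logpdf(sig, priors.sigma_load_scale) + x

            xlo, _ = _slice_sample(lp_sigma_load, math.log(sigma_load), rng, width)
            sigma_load = math.exp(xlo)
            shape_b = 0.5 * (1.0 + (load_innov / sigma_load) ** 2)
            xi = shape_b / rng.exponential(1.0, size=shape_b.shape)

        if it >= mcmc.warmup:
            k = it - mcmc.warmup
            out["base"][k] = states.base
            out["load"][k] = states.load
            out["env"][k] = states.env
            out["sigma_obs"][k] = sigma_obs
            out["sigma_base"][k] = sigma_base
            out["sigma_load"][k] = sigma_load
            out["sigma_env"][k] = sigma_env
            out["h"][k] = h
    return out


def fit(
    y: MeasurementSeries,
    priors: PriorConfig | None = None,
    mcmc: MCMCConfig = MCMCConfig(),
    variant: str = "analysis",
    fix_h: float | None = None,
) -> DecompositionPosterior:
    """Fit the decomposition by Gibbs sampling.

    Parameters
    ----------
    y
        Observations for the four conditions on a shared grid; missing
        entries (mask False) are treated as latent and simply contribute
        no observation term.
    priors
        Defaults to data-scaled weakly-informative priors.
    variant
        'analysis' (Cauchy Load innovations) or 'prediction' (Normal).
    fix_h
        Fix the Env damping factor instead of sampling it (the
        forecasting variant drops damping, i.e. h = 1).
    """
    if variant not in ("analysis", "prediction"):
        raise ValueError("variant must be 'analysis' or 'prediction'")
    if not np.any(y.observed):
        raise ValueError("no observed data")
    if y.T < y.period:
        raise ValueError("series shorter than the seasonal period")
    if priors is None:
        priors = PriorConfig.from_data(y)
    model = _MarginalModel(y, priors)
    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.chains)
    chains = [
        _run_chain(y, model, priors, mcmc, variant, fix_h, np.random.default_rng(s))
        for s in seeds
    ]
    stacked = {k: np.stack([c[k] for c in chains]) for k in chains[0]}
    meta = {
        "chains": mcmc.chains,
        "warmup": mcmc.warmup,
        "sampling": mcmc.sampling,
        "seed": mcmc.seed,
        "variant": variant,
        "fix_h": fix_h,
        "modality": y.modality,
        "period": y.period,
    }
    return DecompositionPosterior(meta=meta, **stacked)


# --------------------------------------------------------------------------
# diagnostics


def rhat(draws: np.ndarray) -> float:
    """Rank-normalized split R-hat of one scalar quantity.

    ``draws`` has shape (chains, iterations).  Returns NaN for constant
    chains, where the diagnostic is undefined.
    """
    draws = np.asarray(draws, float)
    if draws.ndim != 2 or draws.shape[0] < 2 or draws.shape[1] < 4:
        raise ValueError("need >= 2 chains of >= 4 draws")
    if np.ptp(draws) == 0.0:
        return float("nan")
    return float(az.rhat(draws))


def ess(draws: np.ndarray) -> float:
    """Bulk effective sample size of one scalar quantity."""
    draws = np.asarray(draws, float)
    if draws.ndim != 2 or draws.shape[0] < 2 or draws.shape[1] < 4:
        raise ValueError("need >= 2 chains of >= 4 draws")
    if np.ptp(draws) == 0.0:
        return float("nan")
    return float(az.ess(draws))


def hyperparameter_diagnostics(posterior: DecompositionPosterior) -> pd.DataFrame:
    """R-hat / ESS / summary table over all sampled hyperparameters.

    A fixed damping factor (forecast mode) is excluded: it is not sampled.
    """
    names = list(HYPER_NAMES)
    if posterior.meta.get("fix_h") is not None:
        names.remove("h")
    rows = []
    for name in names:
        d = posterior.hyper_draws(name)
        rows.append(
            {
                "parameter": name,
                "mean": float(d.mean()),
                "sd": float(d.std()),
                "rhat": rhat(d),
                "ess": ess(d),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# credible intervals and comparisons


def credible_band(
    posterior: DecompositionPosterior,
    component: str,
    condition: str | None = None,
    level: float = 0.95,
) -> CredibleBand:
    """Central ``level`` posterior interval of one trajectory."""
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    draws = posterior.component_draws(component, condition)
    alpha = (1.0 - level) / 2.0
    lower = np.quantile(draws, alpha, axis=0)
    upper = np.quantile(draws, 1.0 - alpha, axis=0)
    return CredibleBand(level=level, lower=lower, upper=upper)


def compare_conditions(band1: CredibleBand, band2: CredibleBand, at: int) -> str:
    """'separated' iff the closed intervals at 1-based index ``at`` are
    disjoint; touching endpoints count as overlapping."""
    if band1.level != band2.level:
        raise ValueError("bands must share the credible level")
    if band1.lower.shape != band2.lower.shape:
        raise ValueError("bands are on different grids")
    i = at - 1
    if not (0 <= i < band1.lower.size):
        raise ValueError("time index outside the grid")
    l1, u1 = band1.lower[i], band1.upper[i]
    l2, u2 = band2.lower[i], band2.upper[i]
    return "separated" if (u1 < l2 or u2 < l1) else "overlapping"


# --------------------------------------------------------------------------
# forecasting


def forecast(
    y: MeasurementSeries,
    split: int,
    mcmc: MCMCConfig = MCMCConfig(),
    priors: PriorConfig | None = None,
    level: float = 0.95,
    retain_h: bool = False,
) -> ForecastResult:
    """Truncate-and-forecast: fit on time points 1..split, predict the rest.

    Fits the prediction variant (Normal Load innovations; undamped Env
    recursion, h = 1, unless ``retain_h``) with the later observations
    masked, then forms posterior-predictive bands for the held-out points
    including observation noise, and their empirical coverage.
    """
    horizon = y.T - split
    if horizon < 1 or split < y.period:
        raise ValueError("split leaves too short a fit or forecast window")
    observed = y.observed.copy()
    observed[:, split:] = False
    y_fit = replace(y, observed=observed)
    post = fit(
        y_fit,
        priors=priors,
        mcmc=mcmc,
        variant="prediction",
        fix_h=None if retain_h else 1.0,
    )
    rng = np.random.default_rng(np.random.SeedSequence([mcmc.seed, 2**20 + 7]))
    times = np.arange(split + 1, y.T + 1)
    alpha = (1.0 - level) / 2.0
    bands: dict[str, CredibleBand] = {}
    covered = hits = 0
    held = np.where(y.observed, y.y, np.nan)[:, split:]
    for i, cond in enumerate(CONDITIONS):
        mean_draws = post.component_draws("predicted", cond)[:, split:]
        sig = post.sigma_obs[:, :, i].reshape(-1, 1)
        y_rep = mean_draws + sig * rng.standard_normal(mean_draws.shape)
        lower = np.quantile(y_rep, alpha, axis=0)
        upper = np.quantile(y_rep, 1.0 - alpha, axis=0)
        bands[cond] = CredibleBand(level=level, lower=lower, upper=upper)
        obs = y.observed[i, split:]
        vals = y.y[i, split:]
        inside = (vals >= lower) & (vals <= upper) & obs
        covered += int(inside.sum())
        hits += int(obs.sum())
    coverage = covered / hits if hits else None
    return ForecastResult(
        split=split,
        level=level,
        times=times,
        bands=bands,
        held_out=held,
        coverage=coverage,
        posterior=post,
    )


# --------------------------------------------------------------------------
# summaries


def summarize(posterior: DecompositionPosterior) -> pd.DataFrame:
    """Long-format posterior summary of every component trajectory."""
    rows = []
    specs = [("base", None)]
    specs += [("load", c) for c in LOADED]
    specs += [("env", c) for c in LOADED]
    specs += [("predicted", c) for c in CONDITIONS]
    for component, cond in specs:
        draws = posterior.component_draws(component, cond)
        q = np.quantile(draws, [0.025, 0.25, 0.75, 0.975], axis=0)
        for t in range(draws.shape[1]):
            rows.append(
                {
                    "component": component,
                    "condition": cond if cond is not None else "all",
                    "t": t + 1,
                    "mean": float(draws[:, t].mean()),
                    "q2.5": float(q[0, t]),
                    "q25": float(q[1, t]),
                    "q75": float(q[2, t]),
                    "q97.5": float(q[3, t]),
                }
            )
    return pd.DataFrame(rows)
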