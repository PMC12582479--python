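"""Generative state-space model: Base + Load + Env decomposition.

Observation equations (per time point t):

    y_a(t) = Base_t + eps_a                       (control)
    y_n(t) = Base_t + Load_{t,n} + Env_{t,n} + eps_n,   n in {b, c, d}

with eps_n ~ Normal(0, sigma_n).  State equations:

    Base_t = 2 Base_{t-1} - Base_{t-2} + eps_Base,t
    Load_{t,n} = 2 Load_{t-1,n} - Load_{t-2,n} + eps_Load,t
    Env_{t,n} = -h * sum_{k=t-N+1}^{t-1} Env_{k,n} + eps_Env,t

Base and Load are second-order random walks (locally linear trends); their
second differences are the innovations.  Load innovations are Cauchy in the
analysis variant -- occasional large shifts in the accumulated burden --
and Normal in the prediction (forecasting) variant, whose Env recursion
also drops the damping factor (h = 1).  Env is a damped zero-sum seasonal
term synchronized with the room alternation; N is the number of grid
points per B+A room cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .protocol import CONDITIONS, MODALITIES

#: conditions that carry Load and Env components (all but the control)
LOADED = CONDITIONS[1:]


@dataclass(frozen=True)
class HyperParams:
    """Scales and structural constants of the decomposition model.

    sigma_obs maps each condition label to its observation noise scale;
    sigma_load and sigma_env are shared across the non-control conditions.
    """

    sigma_obs: dict[str, float]
    sigma_base: float
    sigma_load: float
    sigma_env: float
    h: float
    period: int
    load_noise_family: str = "cauchy"  # "cauchy" (analysis) or "normal" (prediction)

    def __post_init__(self) -> None:
        if set(self.sigma_obs) != set(CONDITIONS):
            raise ValueError("sigma_obs must cover exactly the four conditions")
        scales = [*self.sigma_obs.values(), self.sigma_base, self.sigma_load, self.sigma_env]
        if any(s < 0 for s in scales):
            raise ValueError("scales must be non-negative")
        if not (0.0 < self.h <= 1.0):
            raise ValueError("h must lie in (0, 1]")
        if self.period < 2:
            raise ValueError("period must be >= 2")
        if self.load_noise_family not in ("cauchy", "normal"):
            raise ValueError("load_noise_family must be 'cauchy' or 'normal'")


@dataclass(frozen=True)
class StateComponents:
    """Latent trajectories: shared Base, per-condition Load and Env.

    ``load`` and ``env`` have shape (3, T), rows ordered as the
    non-control conditions b, c, d.
    """

    base: np.ndarray
    load: np.ndarray
    env: np.ndarray

    def __post_init__(self) -> None:
        base = np.asarray(self.base, dtype=float)
        load = np.asarray(self.load, dtype=float)
        env = np.asarray(self.env, dtype=float)
        object.__setattr__(self, "base", base)
        object.__setattr__(self, "load", load)
        object.__setattr__(self, "env", env)
        T = base.size
        if load.shape != (3, T) or env.shape != (3, T):
            raise ValueError("load/env must have shape (3, T) matching base")

    @property
    def T(self) -> int:
        return int(self.base.size)


@dataclass(frozen=True)
class MeasurementSeries:
    """One modality's observations for the four conditions on a shared grid.

    ``y`` has shape (4, T) with rows in the canonical condition order
    (control first); ``observed`` is True where a value is present.
    """

    modality: str
    y: np.ndarray
    observed: np.ndarray = None  # type: ignore[assignment]
    period: int = 8

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        y = np.asarray(self.y, dtype=float)
        if y.ndim != 2 or y.shape[0] != 4:
            raise ValueError("y must have shape (4, T)")
        observed = self.observed
        if observed is None:
            observed = ~np.isnan(y)
        observed = np.asarray(observed, dtype=bool)
        if observed.shape != y.shape:
            raise ValueError("observed mask must match y")
        if not np.all(np.isfinite(y[observed])):
            raise ValueError("observed values must be finite")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "observed", observed)

    @property
    def T(self) -> int:
        return int(self.y.shape[1])

    def mask(self, condition: str, t: int) -> "MeasurementSeries":
        """Copy with the observation at 1-based index ``t`` marked missing."""
        obs = self.observed.copy()
        obs[CONDITIONS.index(condition), t - 1] = False
        return replace(self, observed=obs)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, cond in enumerate(CONDITIONS):
            for t in range(self.T):
                rows.append(
                    {
                        "condition": cond,
                        "modality": self.modality,
                        "t": t + 1,
                        "value": self.y[i, t] if self.observed[i, t] else np.nan,
                    }
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class InitialConditions:
    """Starting values for the state recursions.

    ``base``: Base at t = 1, 2; ``load``: shape (3, 2), the first two Load
    values per non-control condition; ``env``: shape (3, N-1), the initial
    Env window per non-control condition.
    """

    base: np.ndarray
    load: np.ndarray
    env: np.ndarray

    @classmethod
    def zeros(cls, period: int, base_level: float = 0.0) -> "InitialConditions":
        return cls(
            base=np.full(2, float(base_level)),
            load=np.zeros((3, 2)),
            env=np.zeros((3, period - 1)),
        )


@dataclass(frozen=True)
class PriorConfig:
    """Weakly-informative priors for the sampler and the joint density.

    Scales: half-Normal(0, s) on every sigma; Uniform(0, 1] on h.  Initial
    states get Normal priors centred on the first observations (Base on the
    first control value, Load on the first condition-minus-control gap, Env
    on zero) with common scale ``init_scale``.
    """

    sigma_obs_scale: float = 5.0
    sigma_base_scale: float = 5.0
    sigma_load_scale: float = 5.0
    sigma_env_scale: float = 5.0
    init_scale: float = 10.0

    @classmethod
    def from_data(cls, y: MeasurementSeries, factor: float = 2.5) -> "PriorConfig":
        s = float(np.std(y.y[y.observed])) or 1.0
        return cls(
            sigma_obs_scale=factor * s,
            sigma_base_scale=factor * s,
            sigma_load_scale=factor * s,
            sigma_env_scale=factor * s,
            init_scale=4.0 * factor * s,
        )


def _normal_lpdf(x, mu, sigma):
    z = (np.asarray(x, float) - mu) / sigma
    return -0.5 * z * z - np.log(sigma) - 0.5 * np.log(2.0 * np.pi)


def _cauchy_lpdf(x, mu, sigma):
    z = (np.asarray(x, float) - mu) / sigma
    return -np.log(np.pi * sigma * (1.0 + z * z))


def _half_normal_lpdf(x, sigma):
    return np.log(2.0) + _normal_lpdf(x, 0.0, sigma)


def second_difference(x: np.ndarray) -> np.ndarray:
    """x_t - 2 x_{t-1} + x_{t-2}: the trend innovations."""
    return np.diff(np.asarray(x, float), n=2, axis=-1)


def env_residuals(env_row: np.ndarray, h: float, period: int) -> np.ndarray:
    """Env_t + h * sum of the previous N-1 values, for t = N .. T."""
    env_row = np.asarray(env_row, float)
    N = period
    T = env_row.size
    if T < N:
        return np.zeros(0)
    windows = np.lib.stride_tricks.sliding_window_view(env_row, N - 1)[: T - N + 1]
    return env_row[N - 1 :] + h * windows.sum(axis=1)


def init_prior_centres(y: MeasurementSeries) -> InitialConditions:
    """Prior centres for the initial states, read off the first observations."""
    first = np.empty(4)
    for i in range(4):
        idx = np.flatnonzero(y.observed[i])
        first[i] = y.y[i, idx[0]] if idx.size else 0.0
    return InitialConditions(
        base=np.full(2, first[0]),
        load=np.tile((first[1:] - first[0])[:, None], (1, 2)),
        env=np.zeros((3, y.period - 1)),
    )


def log_joint(
    y: MeasurementSeries,
    states: StateComponents,
    params: HyperParams,
    priors: PriorConfig | None = None,
) -> float:
    """Log of the unnormalized joint density p(y, states, params).

    Sums the Normal observation terms (missing entries contribute
    nothing), the trend second-difference terms for Base and Load, the
    damped seasonal term for Env, the initial-state priors and the
    hyperparameter priors.
    """
    if states.T != y.T:
        raise ValueError("state and observation lengths differ")
    if np.any(~np.isfinite(states.base)) or np.any(~np.isfinite(states.load)):
        raise ValueError("non-finite states")
    for cond in CONDITIONS:
        if params.sigma_obs[cond] <= 0:
            raise ValueError("observation scales must be positive")
    if min(params.sigma_base, params.sigma_load, params.sigma_env) <= 0:
        raise ValueError("state scales must be positive")

    lp = 0.0
    # observation terms
    for i, cond in enumerate(CONDITIONS):
        mu = predicted_mean(states, cond)
        obs = y.observed[i]
        lp += float(np.sum(_normal_lpdf(y.y[i, obs], mu[obs], params.sigma_obs[cond])))
    # state terms
    lp += float(np.sum(_normal_lpdf(second_difference(states.base), 0.0, params.sigma_base)))
    load_innov = second_difference(states.load)
    if params.load_noise_family == "cauchy":
        lp += float(np.sum(_cauchy_lpdf(load_innov, 0.0, params.sigma_load)))
    else:
        lp += float(np.sum(_normal_lpdf(load_innov, 0.0, params.sigma_load)))
    for j in range(3):
        res = env_residuals(states.env[j], params.h, params.period)
        lp += float(np.sum(_normal_lpdf(res, 0.0, params.sigma_env)))
    # initial-state and hyperparameter priors
    if priors is not None:
        centres = init_prior_centres(y)
        s0 = priors.init_scale
        lp += float(np.sum(_normal_lpdf(states.base[:2], centres.base, s0)))
        lp += float(np.sum(_normal_lpdf(states.load[:, :2], centres.load, s0)))
        lp += float(np.sum(_normal_lpdf(states.env[:, : params.period - 1], 0.0, s0)))
        for cond in CONDITIONS:
            lp += float(_half_normal_lpdf(params.sigma_obs[cond], priors.sigma_obs_scale))
        lp += float(_half_normal_lpdf(params.sigma_base, priors.sigma_base_scale))
        lp += float(_half_normal_lpdf(params.sigma_load, priors.sigma_load_scale))
        lp += float(_half_normal_lpdf(params.sigma_env, priors.sigma_env_scale))
        # h ~ Uniform(0, 1]: constant, no contribution
    return lp


def predicted_mean(states: StateComponents, condition: str) -> np.ndarray:
    """Noise-free observation mean: Base, or Base + Load + Env."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if condition == CONDITIONS[0]:
        return states.base.copy()
    j = LOADED.index(condition)
    return states.base + states.load[j] + states.env[j]


def simulate(
    params: HyperParams,
    init: InitialConditions,
    T: int,
    seed: int | np.random.Generator,
    modality: str = "hf",
    cauchy_truncation: float | None = None,
) -> tuple[StateComponents, MeasurementSeries]:
    """Forward-simulate latent states and observations.

    ``cauchy_truncation`` (in units of sigma_load) clips Cauchy Load
    innovations to keep synthetic trajectories physiological; the fitted
    model never truncates.
    """
    if T < 2:
        raise ValueError("T must be >= 2")
    if T < params.period:
        raise ValueError("T must be >= period")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    N = params.period

    base = np.empty(T)
    base[:2] = init.base
    for t in range(2, T):
        eps = rng.normal(0.0, params.sigma_base) if params.sigma_base > 0 else 0.0
        base[t] = 2.0 * base[t - 1] - base[t - 2] + eps

    load = np.empty((3, T))
    load[:, :2] = init.load
    for j in range(3):
        for t in range(2, T):
            if params.sigma_load > 0:
                if params.load_noise_family == "cauchy":
                    eps = params.sigma_load * rng.standard_cauchy()
                    if cauchy_truncation is not None:
                        lim = cauchy_truncation * params.sigma_load
                        eps = float(np.clip(eps, -lim, lim))
                else:
                    eps = rng.normal(0.0, params.sigma_load)
            else:
                eps = 0.0
            load[j, t] = 2.0 * load[j, t - 1] - load[j, t - 2] + eps

    env = np.empty((3, T))
    env[:, : N - 1] = init.env
    for j in range(3):
        for t in range(N - 1, T):
            eps = rng.normal(0.0, params.sigma_env) if params.sigma_env > 0 else 0.0
            env[j, t] = -params.h * np.sum(env[j, t - N + 1 : t]) + eps

    states = StateComponents(base=base, load=load, env=env)
    y = np.empty((4, T))
    for i, cond in enumerate(CONDITIONS):
        sigma = params.sigma_obs[cond]
        noise = rng.normal(0.0, sigma, size=T) if sigma > 0 else 0.0
        y[i] = predicted_mean(states, cond) + noise
    series = MeasurementSeries(modality=modality, y=y, period=N)
    return states, series
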