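"""Ground-truth-known synthetic datasets emulating the study's structure.

Three scenarios:

* ``null`` -- all four conditions share the Base trend only (Load and Env
  identically zero): what the decomposition should report when repeated
  temperature steps have no effect.
* ``step_load`` -- condition-specific Load trends that grow with the
  nominal step size (b < c <= d), occasional heavy-tailed Load shifts, and
  a room-cycle-locked Env oscillation.
* ``cooling`` -- like ``step_load`` but with the largest-step condition's
  Load attenuated below the 10-degree condition, mimicking a cooler room A
  partially discharging the accumulated burden.

Values are on a log-spectral-power-like scale (unit magnitudes), the scale
on which the HRV indices are modelled.  Cauchy Load innovations are
truncated at 6 scale units in the generator only, to keep synthetic
trajectories physiological; fitted models never truncate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocess import RRISeries
from .protocol import CONDITIONS, MeasurementGrid
from .ssm_core import (
    HyperParams,
    InitialConditions,
    MeasurementSeries,
    StateComponents,
    predicted_mean,
    simulate,
)

SCENARIOS = ("null", "step_load", "cooling")

#: final-time Load magnitudes per scenario (conditions b, c, d)
LOAD_AMPLITUDES = {
    "null": (0.0, 0.0, 0.0),
    "step_load": (1.0, 2.5, 3.0),
    "cooling": (1.0, 2.5, 1.2),
}
#: Env oscillation half-amplitudes per condition (b, c, d)
ENV_AMPLITUDES = {
    "null": (0.0, 0.0, 0.0),
    "step_load": (0.5, 1.0, 1.5),
    "cooling": (0.5, 1.0, 1.5),
}
CAUCHY_TRUNCATION = 6.0
#: bound on the integrated Load wiggle in scenario datasets; half the
#: smallest between-condition amplitude gap, so orderings are guaranteed
WIGGLE_CAP = 0.2


def default_params(period: int, load_noise_family: str = "cauchy") -> HyperParams:
    """Moderate noise scales on the unit-magnitude synthetic scale."""
    return HyperParams(
        sigma_obs={c: 0.5 for c in CONDITIONS},
        sigma_base=0.10,
        sigma_load=0.08,
        sigma_env=0.10,
        h=0.5,
        period=period,
        load_noise_family=load_noise_family,
    )


@dataclass(frozen=True)
class SyntheticTruth:
    """A generated dataset together with its generating states/parameters."""

    scenario: str
    seed: int
    params: HyperParams
    states: StateComponents
    y: MeasurementSeries

    def to_files(self, directory: str | Path) -> tuple[Path, Path]:
        """Write the tidy data CSV and the YAML truth file."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        data_path = directory / f"{self.scenario}_data.csv"
        truth_path = directory / f"{self.scenario}_truth.yaml"
        self.y.to_frame().to_csv(data_path, index=False)
        truth = {
            "scenario": self.scenario,
            "seed": self.seed,
            "cauchy_truncation": CAUCHY_TRUNCATION,
            "params": {
                "sigma_obs": {k: float(v) for k, v in self.params.sigma_obs.items()},
                "sigma_base": float(self.params.sigma_base),
                "sigma_load": float(self.params.sigma_load),
                "sigma_env": float(self.params.sigma_env),
                "h": float(self.params.h),
                "period": int(self.params.period),
                "load_noise_family": self.params.load_noise_family,
            },
            "states": {
                "base": self.states.base.tolist(),
                "load": self.states.load.tolist(),
                "env": self.states.env.tolist(),
            },
        }
        truth_path.write_text(yaml.safe_dump(truth, sort_keys=False))
        return data_path, truth_path


def _room_pattern(grid: MeasurementGrid) -> np.ndarray:
    """+-0.5 square wave locked to the room sequence, zero-sum per B+A cycle."""
    return np.array([0.5 if p.room == "B" else -0.5 for p in grid.points])


def generate_dataset(
    scenario: str,
    grid: MeasurementGrid,
    params: HyperParams | None = None,
    seed: int = 0,
) -> SyntheticTruth:
    """Generate one dataset with known latent components.

    Base is a smooth drift plus trend noise; Load follows the scenario's
    final-time amplitudes along a smooth ramp plus (truncated-Cauchy or
    Normal) trend innovations; Env is the scenario amplitude times the
    room-locked square wave.  Observations add Normal noise per condition.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    if params is None:
        params = default_params(grid.period)
    rng = np.random.default_rng(seed)
    T = len(grid)
    x = np.arange(T) / max(T - 1, 1)

    # Base: gentle drift with curvature plus integrated trend noise
    base = 5.0 + 1.5 * x + 0.5 * x * x
    if params.sigma_base > 0 and T > 2:
        innov = rng.normal(0.0, params.sigma_base, T - 2)
        base = base + np.concatenate([[0.0, 0.0], np.cumsum(np.cumsum(innov))])

    # Load: scenario ramp plus an integrated heavy-tailed wiggle.  The
    # wiggle is capped at WIGGLE_CAP so the scenario's between-condition
    # ordering holds by construction (the amplitude gaps exceed twice the
    # cap); innovations themselves stay occasional-large (Cauchy body).
    load = np.zeros((3, T))
    ramp = x**1.5
    for j, amp in enumerate(LOAD_AMPLITUDES[scenario]):
        load[j] = amp * ramp
        if scenario != "null" and params.sigma_load > 0:
            if params.load_noise_family == "cauchy":
                innov = params.sigma_load * rng.standard_cauchy(T - 2)
                lim = CAUCHY_TRUNCATION * params.sigma_load
                innov = np.clip(innov, -lim, lim)
            else:
                innov = rng.normal(0.0, params.sigma_load, T - 2)
            wiggle = np.concatenate([[0.0, 0.0], np.cumsum(np.cumsum(innov))])
            peak = float(np.max(np.abs(wiggle)))
            if peak > WIGGLE_CAP:
                wiggle *= WIGGLE_CAP / peak
            load[j] += wiggle

    pattern = _room_pattern(grid)
    env = np.stack([amp * pattern for amp in ENV_AMPLITUDES[scenario]])

    states = StateComponents(base=base, load=load, env=env)
    y = np.empty((4, T))
    for i, cond in enumerate(CONDITIONS):
        y[i] = predicted_mean(states, cond) + rng.normal(
            0.0, params.sigma_obs[cond], size=T
        )
    series = MeasurementSeries(modality=grid.modality, y=y, period=grid.period)
    return SyntheticTruth(
        scenario=scenario, seed=seed, params=params, states=states, y=series
    )


def model_dataset(
    params: HyperParams,
    T: int,
    seed: int,
    modality: str = "hf",
    base_start: float = 5.0,
    base_slope: float = 0.05,
) -> SyntheticTruth:
    """Simulate directly from the state-space recursions (well-specified).

    Initial conditions: Base starts on a shallow line, Load at zero, and
    the Env window on a small +-alternating pattern so the seasonal
    recursion is excited from the first cycle.  Cauchy Load innovations
    are truncated at 6 scale units (generator only).
    """
    N = params.period
    env0 = 0.3 * np.array([1.0 if k % 2 == 0 else -1.0 for k in range(N - 1)])
    init = InitialConditions(
        base=np.array([base_start, base_start + base_slope]),
        load=np.zeros((3, 2)),
        env=np.tile(env0, (3, 1)),
    )
    states, y = simulate(
        params,
        init,
        T,
        seed,
        modality=modality,
        cauchy_truncation=CAUCHY_TRUNCATION,
    )
    return SyntheticTruth(
        scenario="model", seed=seed, params=params, states=states, y=y
    )


# --------------------------------------------------------------------------
# raw-stream fixtures


def skin_streams(
    truth: SyntheticTruth, grid: MeasurementGrid
) -> dict[str, pd.DataFrame]:
    """1 Hz four-site temperature streams reproducing ``truth.y`` exactly.

    Within each grid averaging window all four sites equal the target
    value, so the weighted mean averaged over the window returns it;
    between windows the stream holds the previous target.
    """
    if truth.y.modality != "skin":
        raise ValueError("skin streams need a skin-modality truth")
    total_s = int(np.ceil(grid.points[-1].end_min * 60.0)) + 1
    seconds = np.arange(total_s, dtype=float)
    out = {}
    for i, cond in enumerate(CONDITIONS):
        values = np.empty(total_s)
        values[:] = truth.y.y[i, 0]
        for k, p in enumerate(grid.points):
            lo = int(np.floor(p.start_min * 60.0))
            values[lo:] = truth.y.y[i, k]
        out[cond] = pd.DataFrame(
            {
                "seconds": seconds,
                "chest": values,
                "upperarm": values,
                "thigh": values,
                "leg": values,
            }
        )
    return out


def rri_for_window(
    start_s: float,
    duration_s: float,
    hr: float,
    log_hf: float,
    log_lf_hf: float,
    seed: int = 0,
) -> RRISeries:
    """An RRI series whose MEM features approximate the given targets.

    The tachogram is a sum of an LF (0.10 Hz) and an HF (0.30 Hz) sinusoid
    around the mean interval; a sinusoid of amplitude A carries band power
    A^2/2, so amplitudes are chosen from the target log powers.
    """
    mean_ms = 60000.0 / hr
    p_hf = np.exp(log_hf)
    p_lf = np.exp(log_hf + log_lf_hf)
    a_hf = np.sqrt(2.0 * p_hf)
    a_lf = np.sqrt(2.0 * p_lf)
    rng = np.random.default_rng(seed)
    phi_lf, phi_hf = rng.uniform(0.0, 2.0 * np.pi, size=2)

    onsets = [start_s]
    intervals = [mean_ms]
    t = start_s
    while t < start_s + duration_s:
        rr = (
            mean_ms
            + a_lf * np.sin(2.0 * np.pi * 0.10 * (t - start_s) + phi_lf)
            + a_hf * np.sin(2.0 * np.pi * 0.30 * (t - start_s) + phi_hf)
        )
        t += rr / 1000.0
        onsets.append(t)
        intervals.append(rr)
    return RRISeries(onsets=np.array(onsets), intervals=np.array(intervals))


def generate_raw_fixtures(
    truth: SyntheticTruth,
    grid: MeasurementGrid,
    seed: int = 0,
    hr: float = 70.0,
    log_hf_default: float = 5.5,
    log_lf_hf_default: float = 0.0,
) -> dict:
    """Raw streams whose preprocessing reproduces ``truth.y``.

    For a skin truth: per-condition 1 Hz four-site streams (exact).  For an
    HRV truth (hr/hf/lfhf): per-condition, per-rest-window RRI series whose
    targeted feature equals the truth value and whose other features sit at
    the given defaults; spectral-estimation bias keeps log-scale agreement
    approximate (about +-0.3).
    """
    if truth.y.modality == "skin":
        return {"skin": skin_streams(truth, grid)}
    if truth.y.modality not in ("hr", "hf", "lfhf"):
        raise ValueError("raw fixtures exist for skin and HRV modalities only")
    out: dict[str, list[RRISeries]] = {}
    ss = np.random.SeedSequence([seed])
    for i, cond in enumerate(CONDITIONS):
        series_list = []
        for k, p in enumerate(grid.points):
            target = truth.y.y[i, k]
            kw = {"hr": hr, "log_hf": log_hf_default, "log_lf_hf": log_lf_hf_default}
            kw[{"hr": "hr", "hf": "log_hf", "lfhf": "log_lf_hf"}[truth.y.modality]] = target
            series_list.append(
                rri_for_window(
                    start_s=p.start_min * 60.0,
                    duration_s=(p.end_min - p.start_min) * 60.0,
                    seed=int(np.random.default_rng(ss.spawn(1)[0]).integers(2**31)),
                    **kw,
                )
            )
        out[cond] = series_list
    return {truth.y.modality: out}
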