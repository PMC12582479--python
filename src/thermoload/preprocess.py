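"""Raw-stream preprocessing: weighted skin temperature, HRV spectral indices.

Heart-rate variability is computed from the R-R interval (RRI) tachogram of
each rest window: the first 30 s of the window are discarded, the remaining
beats are cubic-interpolated onto an even 4 Hz grid, and band powers are
taken from the maximum-entropy (Burg autoregressive) spectrum -- LF is the
0.04-0.15 Hz band, HF the 0.15-0.4 Hz band.  HF is reported on the log
scale and LF/HF as log(LF) - log(HF).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

from .protocol import MeasurementGrid

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)
DEFAULT_EXCLUSION_S = 30.0
DEFAULT_RESAMPLE_HZ = 4.0
DEFAULT_AR_ORDER = 16


@dataclass(frozen=True)
class SkinWeights:
    """Site weights for the four-site mean skin temperature."""

    w_chest: float = 0.3
    w_upperarm: float = 0.3
    w_thigh: float = 0.2
    w_leg: float = 0.2

    def __post_init__(self) -> None:
        w = (self.w_chest, self.w_upperarm, self.w_thigh, self.w_leg)
        if not all(0.0 < x < 1.0 for x in w):
            raise ValueError("weights must lie in (0, 1)")
        if abs(sum(w) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")


@dataclass(frozen=True)
class RRISeries:
    """Beat onsets (s, strictly increasing) and R-R intervals (ms).

    ``intervals[i]`` is the interval ending at ``onsets[i]``; the first
    entry has no preceding beat inside the series and is taken as given.
    """

    onsets: np.ndarray
    intervals: np.ndarray

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float)
        intervals = np.asarray(self.intervals, dtype=float)
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "intervals", intervals)
        if onsets.shape != intervals.shape:
            raise ValueError("onsets and intervals must have equal length")
        if onsets.size and np.any(np.diff(onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if np.any(intervals <= 0):
            raise ValueError("intervals must be positive")
        if onsets.size > 1:
            implied = np.diff(onsets) * 1000.0
            if not np.allclose(implied, intervals[1:], rtol=1e-3, atol=0.5):
                raise ValueError("intervals inconsistent with onsets")

    @classmethod
    def from_intervals(cls, intervals_ms, start_s: float = 0.0) -> "RRISeries":
        intervals_ms = np.asarray(intervals_ms, dtype=float)
        onsets = start_s + np.cumsum(intervals_ms) / 1000.0
        return cls(onsets=onsets, intervals=intervals_ms)

    def __len__(self) -> int:
        return int(self.onsets.size)


@dataclass(frozen=True)
class HRVFeatures:
    """Heart rate and log-scale spectral indices of one rest window."""

    hr: float  # beats / min
    log_hf: float
    log_lf_hf: float


def mean_skin_temperature(
    chest, upperarm, thigh, leg, weights: SkinWeights = SkinWeights()
):
    """Weighted four-site mean skin temperature (deg C), vectorized."""
    arrays = [np.asarray(a, dtype=float) for a in (chest, upperarm, thigh, leg)]
    if any(not np.all(np.isfinite(a)) for a in arrays):
        raise ValueError("non-finite skin temperature input")
    c, u, t, l = arrays
    return (
        weights.w_chest * c
        + weights.w_upperarm * u
        + weights.w_thigh * t
        + weights.w_leg * l
    )


def rest_window(
    rri: RRISeries,
    rest_start: float,
    rest_end: float,
    exclusion: float = DEFAULT_EXCLUSION_S,
) -> RRISeries:
    """Beats inside ``[rest_start + exclusion, rest_end]`` (seconds)."""
    if rest_end - rest_start <= exclusion:
        raise ValueError("rest window shorter than the exclusion period")
    lo = rest_start + exclusion
    keep = (rri.onsets >= lo) & (rri.onsets <= rest_end)
    if not np.any(keep):
        raise ValueError("no beats inside the rest window")
    return RRISeries(onsets=rri.onsets[keep], intervals=rri.intervals[keep])


def heart_rate(rri: RRISeries) -> float:
    """Mean heart rate in beats/min: 60000 / mean interval (ms)."""
    if len(rri) < 2:
        raise ValueError("need at least two beats")
    return 60000.0 / float(np.mean(rri.intervals))


def burg_ar(x: np.ndarray, order: int) -> tuple[np.ndarray, float]:
    """Fit an AR(p) model by Burg's method.

    Returns coefficients ``a`` of ``x_t + sum_k a_k x_{t-k} = e_t`` and the
    driving-noise variance.  This is the maximum-entropy spectral model for
    the given order.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if order < 1 or order >= n:
        raise ValueError("order must satisfy 1 <= order < len(x)")
    f = x[1:].copy()
    b = x[:-1].copy()
    a = np.zeros(0)
    e = float(np.dot(x, x)) / n
    if e == 0.0:
        raise ValueError("degenerate (all-zero) series")
    for _ in range(order):
        denom = float(np.dot(f, f) + np.dot(b, b))
        if denom == 0.0:
            raise ValueError("degenerate series during Burg recursion")
        k = -2.0 * float(np.dot(f, b)) / denom
        a = np.concatenate([a, [0.0]]) + k * np.concatenate([a[::-1], [1.0]])
        e *= 1.0 - k * k
        f, b = f[1:] + k * b[1:], b[:-1] + k * f[:-1]
    return a, e


def ar_psd(a: np.ndarray, noise_var: float, fs: float, freqs: np.ndarray) -> np.ndarray:
    """One-sided PSD of the fitted AR model at ``freqs`` (Hz)."""
    z = np.exp(-2j * np.pi * np.outer(freqs, np.arange(1, a.size + 1)) / fs)
    denom = np.abs(1.0 + z @ a) ** 2
    return 2.0 * noise_var / fs / denom


def resample_tachogram(
    rri: RRISeries, fs: float = DEFAULT_RESAMPLE_HZ
) -> tuple[np.ndarray, np.ndarray]:
    """Cubic-interpolate the tachogram onto an even grid, linearly detrended."""
    if len(rri) < 4:
        raise ValueError("too few beats to resample")
    t0, t1 = rri.onsets[0], rri.onsets[-1]
    grid = np.arange(t0, t1, 1.0 / fs)
    values = CubicSpline(rri.onsets, rri.intervals)(grid)
    return grid, signal.detrend(values, type="linear")


def mem_band_powers(
    rri: RRISeries,
    lf_band: tuple[float, float] = LF_BAND,
    hf_band: tuple[float, float] = HF_BAND,
    order: int = DEFAULT_AR_ORDER,
    fs: float = DEFAULT_RESAMPLE_HZ,
) -> tuple[float, float]:
    """Band-integrated LF and HF power (ms^2) of the MEM spectrum."""
    _, x = resample_tachogram(rri, fs=fs)
    if x.size <= order + 1:
        raise ValueError("window too short for the requested AR order")
    if np.ptp(x) <= 1e-8 * float(np.mean(rri.intervals)):
        raise ValueError("constant tachogram has no spectral content")
    a, noise_var = burg_ar(x, order)
    powers = []
    for lo, hi in (lf_band, hf_band):
        freqs = np.linspace(lo, hi, 512)
        powers.append(float(np.trapezoid(ar_psd(a, noise_var, fs, freqs), freqs)))
    return powers[0], powers[1]


def hrv_features(
    rri: RRISeries,
    order: int = DEFAULT_AR_ORDER,
    fs: float = DEFAULT_RESAMPLE_HZ,
    log_base: float | None = None,
) -> HRVFeatures:
    """HR, log HF and log LF/HF for one (already windowed) RRI series.

    ``log_base=None`` uses the natural log.
    """
    lf, hf = mem_band_powers(rri, order=order, fs=fs)
    if lf <= 0 or hf <= 0:
        raise ValueError("zero band power")
    scale = 1.0 if log_base is None else 1.0 / np.log(log_base)
    return HRVFeatures(
        hr=heart_rate(rri),
        log_hf=float(np.log(hf) * scale),
        log_lf_hf=float((np.log(lf) - np.log(hf)) * scale),
    )


def average_onto_grid(
    times_s: np.ndarray, values: np.ndarray, grid: MeasurementGrid
) -> np.ndarray:
    """Mean of a time-stamped stream over each grid averaging window.

    Windows are half-open ``[start, end)``; the final window is closed so
    the sub-ranges partition each section without double counting.  Times
    are in seconds, grid windows in minutes.
    """
    times_s = np.asarray(times_s, dtype=float)
    values = np.asarray(values, dtype=float)
    out = np.empty(len(grid))
    last = len(grid) - 1
    for i, p in enumerate(grid.points):
        lo, hi = p.start_min * 60.0, p.end_min * 60.0
        mask = (times_s >= lo) & ((times_s <= hi) if i == last else (times_s < hi))
        if not np.any(mask):
            raise ValueError(f"no samples in grid window t={p.t}")
        out[i] = float(np.mean(values[mask]))
    return out


def read_rri_csv(path) -> RRISeries:
    """Read a beat table (columns ``onset_s``, ``interval_ms``)."""
    import pandas as pd

    df = pd.read_csv(path)
    return RRISeries(onsets=df["onset_s"].to_numpy(), intervals=df["interval_ms"].to_numpy())


def write_rri_csv(rri: RRISeries, path) -> None:
    import pandas as pd

    pd.DataFrame({"onset_s": rri.onsets, "interval_ms": rri.intervals}).to_csv(
        path, index=False
    )
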