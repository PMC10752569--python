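"""Filtering, windowing, smoothing and alignment primitives shared by all decoders.

Every windowed operator (RMS envelope, firing rate, windowed mean) places its
output on a common 10 Hz feature grid whose points are *window centers*:

    c_k = t0 + window/2 + k * step        (window half-open: [c - w/2, c + w/2))

so any two :class:`FeatureSeries` derived from the same trial span are
index-aligned by construction, regardless of the sampling rate of the raw
signal they came from.  Windows are defined in *time* (sample membership via
binary search), not in sample counts, because the EMG rate (2222 Hz) does not
divide the 0.1 s step evenly.

Filters are applied zero-phase (forward-backward ``sosfiltfilt``) so that the
filtering stage introduces no group delay of its own; the electromechanical
delay between muscle activity and torque is absorbed explicitly by the
cross-correlation alignment step instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _dsp

logger = logging.getLogger("mutorque")

#: lattice used to match grid times exactly across series (half of the 0.1 s step)
_KEY_QUANTUM = 0.05


@dataclass
class SignalConfig:
    """Tunable constants of the feature pipeline.

    The Kalman noise variances default to equal fractions (1e-1) of the
    input series' variance, giving a steady-state one-pole response with a
    cutoff near 1.5 Hz on the 10 Hz grid - matched to the 2 Hz bandwidth of
    the conditioned torque reference so the smoother does not distort the
    feature relative to the reference it is regressed against (heavier
    smoothing biases the fitted twitch parameters).  Variance scaling makes
    the smoother scale-equivariant; pass explicit values to override.
    """

    rms_window_s: float = 0.5
    step_s: float = 0.1
    torque_lowpass_hz: float = 2.0
    emg_band_hz: tuple[float, float] = (20.0, 450.0)
    kalman_process_var: float | None = None
    kalman_measurement_var: float | None = None
    max_lag_s: float = 1.0


@dataclass
class FeatureSeries:
    """A uniformly sampled 10 Hz feature trace (values in %MVC, Hz, arb. force or Nm)."""

    times: np.ndarray
    values: np.ndarray
    step: float = 0.1

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have identical shape")

    def copy(self) -> "FeatureSeries":
        return FeatureSeries(self.times.copy(), self.values.copy(), self.step)

    def shifted(self, lag: float) -> "FeatureSeries":
        """Advance the series by ``lag`` seconds (t -> t - lag on the time axis)."""
        return FeatureSeries(self.times - lag, self.values.copy(), self.step)

    def __len__(self) -> int:
        return self.times.size


def _grid_keys(times: np.ndarray) -> np.ndarray:
    return np.round(np.asarray(times, float) / _KEY_QUANTUM).astype(np.int64)


def index_align(a: FeatureSeries, b: FeatureSeries) -> tuple[FeatureSeries, FeatureSeries]:
    """Restrict two series to their common grid points (exact lattice match)."""
    ka, kb = _grid_keys(a.times), _grid_keys(b.times)
    common, ia, ib = np.intersect1d(ka, kb, return_indices=True)
    return (
        FeatureSeries(a.times[ia], a.values[ia], a.step),
        FeatureSeries(b.times[ib], b.values[ib], b.step),
    )


def window_centers(t0: float, t1: float, window: float, step: float) -> np.ndarray:
    """Centers of fully supported windows inside [t0, t1]."""
    n = int(np.floor((t1 - t0 - window) / step + 1e-9)) + 1
    if n <= 0:
        raise ValueError(
            f"span of {t1 - t0:.3f} s is shorter than one {window:.3f} s window"
        )
    return t0 + window / 2.0 + step * np.arange(n)


def _windowed_reduce(
    trace: np.ndarray,
    fs: float,
    window: float,
    step: float,
    t0: float,
    kind: str,
) -> FeatureSeries:
    x = np.asarray(trace, dtype=float)
    t = t0 + np.arange(x.size) / fs
    centers = window_centers(t0, t0 + (x.size - 1) / fs, window, step)
    lo = np.searchsorted(t, centers - window / 2.0 - 1e-12, side="left")
    hi = np.searchsorted(t, centers + window / 2.0 - 1e-12, side="left")
    counts = (hi - lo).astype(float)
    if kind == "rms":
        c2 = np.concatenate([[0.0], np.cumsum(x * x)])
        vals = np.sqrt((c2[hi] - c2[lo]) / counts)
    elif kind == "mean":
        c1 = np.concatenate([[0.0], np.cumsum(x)])
        vals = (c1[hi] - c1[lo]) / counts
    else:  # pragma: no cover - internal
        raise ValueError(kind)
    return FeatureSeries(centers, vals, step)


def moving_rms(
    trace: np.ndarray,
    fs: float,
    window: float = 0.5,
    step: float = 0.1,
    t0: float = 0.0,
) -> FeatureSeries:
    """RMS envelope of ``trace`` on the centered 0.5 s / 0.1 s feature grid."""
    return _windowed_reduce(trace, fs, window, step, t0, "rms")


def windowed_mean(
    trace: np.ndarray,
    fs: float,
    window: float = 0.5,
    step: float = 0.1,
    t0: float = 0.0,
) -> FeatureSeries:
    """Moving-window mean (used to downsample torque to the feature grid)."""
    return _windowed_reduce(trace, fs, window, step, t0, "mean")


def preprocess_torque(
    raw_torque: np.ndarray,
    fs: float = 100.0,
    config: SignalConfig | None = None,
    t0: float = 0.0,
) -> FeatureSeries:
    """Reference-torque conditioning: DC removal, 2 Hz low-pass, windowed mean.

    The DC offset is the mean of the first second of data (the quiescent
    baseline of the trial); the low-pass is a 4th-order Butterworth applied
    zero-phase; the windowed mean produces the 10 Hz reference grid.
    """
    cfg = config or SignalConfig()
    x = np.asarray(raw_torque, dtype=float)
    if x.size < int(round(cfg.rms_window_s * fs)):
        raise ValueError("torque trace shorter than one feature window")
    n_dc = max(1, min(x.size, int(round(1.0 * fs))))
    x = x - x[:n_dc].mean()
    sos = _dsp.butter(4, cfg.torque_lowpass_hz, btype="low", fs=fs, output="sos")
    x = _dsp.sosfiltfilt(sos, x)
    return windowed_mean(x, fs, cfg.rms_window_s, cfg.step_s, t0)


def bandpass_emg(
    raw_emg: np.ndarray,
    fs: float = 2222.0,
    band: tuple[float, float] = (20.0, 450.0),
) -> np.ndarray:
    """20-450 Hz band-pass (4th-order Butterworth, zero-phase); removes DC."""
    sos = _dsp.butter(2, band, btype="bandpass", fs=fs, output="sos")
    return _dsp.sosfiltfilt(sos, np.asarray(raw_emg, dtype=float))


def firing_rate_series(
    firings: np.ndarray,
    span: tuple[float, float],
    window: float = 0.5,
    step: float = 0.1,
) -> FeatureSeries:
    """Windowed firing rate in Hz: (spike count in centered window) / window."""
    f = np.asarray(firings, dtype=float)
    centers = window_centers(span[0], span[1], window, step)
    hi = np.searchsorted(f, centers + window / 2.0, side="left")
    lo = np.searchsorted(f, centers - window / 2.0, side="left")
    return FeatureSeries(centers, (hi - lo) / window, step)


def kalman_smooth(
    series: FeatureSeries,
    process_var: float | None = None,
    measurement_var: float | None = None,
) -> FeatureSeries:
    """Scalar random-walk Kalman smoother run forward over the series.

    State = smoothed feature value, identity transition and observation.
    With the variance-scaled defaults the smoother commutes with scaling
    of the input, so features in arbitrary units are treated alike.
    """
    v = float(np.var(series.values)) if len(series) else 0.0
    q = 1e-1 * v if process_var is None else float(process_var)
    r = 1e-1 * v if measurement_var is None else float(measurement_var)
    if process_var is not None and process_var <= 0:
        raise ValueError("process_var must be > 0")
    if measurement_var is not None and measurement_var <= 0:
        raise ValueError("measurement_var must be > 0")
    if q <= 0 or r <= 0:  # constant input with default scaling
        return series.copy()
    obs = series.values
    out = np.empty_like(obs)
    x = obs[0]
    p = r
    out[0] = x
    for k in range(1, obs.size):
        p = p + q
        gain = p / (p + r)
        x = x + gain * (obs[k] - x)
        p = (1.0 - gain) * p
        out[k] = x
    return FeatureSeries(series.times.copy(), out, series.step)


def align_by_xcorr(
    feature: FeatureSeries,
    reference: FeatureSeries,
    max_lag: float = 1.0,
) -> tuple[float, FeatureSeries]:
    """Find the lag (on the 0.1 s grid) maximizing the correlation with ``reference``.

    Returns ``(lag, shifted)`` where positive ``lag`` means the feature was
    *delayed* relative to the reference and has been advanced by ``lag`` to
    compensate.  Ties are broken toward the smallest ``|lag|``; an all-zero
    (or constant) feature yields lag 0.
    """
    step = feature.step
    if max_lag < 0:
        raise ValueError("max_lag must be >= 0")
    if len(feature) == 0 or np.ptp(feature.values) == 0.0:
        logger.info("align_by_xcorr: degenerate (constant) feature, lag set to 0")
        return 0.0, feature.copy()
    m_max = int(round(max_lag / step))
    best_score = -np.inf
    best_m = 0
    order = [0]
    for m in range(1, m_max + 1):
        order.extend([m, -m])
    for m in order:
        lag = m * step
        cand = feature.shifted(lag)
        a, b = index_align(cand, reference)
        if len(a) < 5:
            continue
        sa, sb = a.values.std(), b.values.std()
        if sa == 0.0 or sb == 0.0:
            continue
        score = float(
            np.mean((a.values - a.values.mean()) * (b.values - b.values.mean()))
            / (sa * sb)
        )
        if score > best_score + 1e-12:
            best_score = score
            best_m = m
    lag = best_m * step
    return lag, feature.shifted(lag)


def normalize_to_mvc(series: FeatureSeries, mvc_rms: float) -> FeatureSeries:
    """Express an EMG-amplitude series as %MVC of the reference RMS."""
    if mvc_rms <= 0:
        raise ValueError("mvc_rms must be positive")
    return FeatureSeries(series.times.copy(), series.values * (100.0 / mvc_rms), series.step)


def compute_mvc(emg: np.ndarray, fs: float, window: float = 0.5) -> float:
    """Largest sliding 0.5 s window of the RMS of the (filtered) EMG trace."""
    x = np.asarray(emg, dtype=float)
    n_w = int(round(window * fs))
    if x.size < n_w:
        raise ValueError("EMG trace shorter than the MVC window")
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])
    rms = np.sqrt((c2[n_w:] - c2[:-n_w]) / n_w)
    return float(rms.max())
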