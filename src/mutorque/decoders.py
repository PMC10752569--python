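"""The three torque decoders: aEMG, neural drive (ND), and MUDrive.

* **aEMG** regresses the MVC-normalized, Kalman-smoothed RMS envelope of the
  EMG onto recorded torque (simple linear regression).
* **ND** regresses the smoothed firing rates of the 10 motor units that
  individually correlate best with torque onto torque (multiple linear
  regression): tau(t) = sum_i a_i FR_i(t) + b.
* **MUDrive** convolves each retained unit's spike train with a modeled force
  twitch and sums across the pool.  Each unit's twitch parameters
  (peak force P, rise time Tr, half-relaxation time Thr) are a linear
  rescaling - by recruitment threshold, per the size principle - of pool-level
  bounds (P_max, Tr_min, Tr_max, Thr_min, Thr_max) that are optimized by a
  genetic algorithm; P_min is fixed at 1.  The summed signal is windowed,
  Kalman-smoothed, aligned, and linearly regressed onto torque.

Twitch model
------------
The twitch is a critically-damped-style rise peaking at exactly P at t = Tr,

    f(t) = P * (t/Tr) * exp(1 - t/Tr)            for t <= Tr,

spliced to an exponential decay calibrated so the half-relaxation time is
exactly Thr:

    f(t) = P * 2**(-(t - Tr)/Thr)                for t > Tr.

Downstream code relies only on the contract f(0)=0, max f = P at Tr, and
f(Tr+Thr) = P/2, so any waveform meeting that contract is interchangeable.

Rate-dependent gain
-------------------
Twitch summation is nonlinear at high rates.  Each spike's twitch is scaled by
a sigmoidal gain driven by x = Tr / (preceding ISI): gain = 1 for x <= 0.4,
otherwise [S(x)/x] / [S(0.4)/0.4] with S(x) = 1 - exp(-2 x^3).  The first
spike of a train uses gain 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import fftconvolve

from .mu_validation import MotorUnit
from .signal_processing import (
    FeatureSeries,
    SignalConfig,
    align_by_xcorr,
    index_align,
    kalman_smooth,
    windowed_mean,
)

logger = logging.getLogger("mutorque")

#: physiologically realizable box for the five optimized pool parameters
CONSTRAINT_BOX: dict[str, tuple[float, float]] = {
    "p_max": (1.1, 150.0),
    "tr_min": (0.030, 0.110),
    "tr_max": (0.150, 0.240),
    "thr_min": (0.015, 0.060),
    "thr_max": (0.110, 0.140),
}

PARAM_NAMES: tuple[str, ...] = ("p_max", "tr_min", "tr_max", "thr_min", "thr_max")

#: deterministic tie-break order for sensitivity ranking
CANONICAL_PARAM_ORDER: tuple[str, ...] = ("tr_min", "thr_min", "p_max", "tr_max", "thr_max")


@dataclass
class PoolParameterBounds:
    """Pool-level twitch parameter ranges; P_min is predefined at 1."""

    p_max: float
    tr_min: float
    tr_max: float
    thr_min: float
    thr_max: float
    p_min: float = 1.0

    def feasible(self) -> bool:
        return (
            self.p_min < self.p_max
            and self.tr_min < self.tr_max
            and self.thr_min < self.thr_max
        )

    def validate(self) -> None:
        if not self.feasible():
            raise ValueError(f"infeasible pool bounds: {self}")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAM_NAMES}

    def with_value(self, name: str, value: float) -> "PoolParameterBounds":
        if name not in PARAM_NAMES:
            raise ValueError(f"unknown pool parameter {name!r}")
        return replace(self, **{name: float(value)})

    @classmethod
    def midpoint(cls) -> "PoolParameterBounds":
        """Midpoint of the physiologic constraint box (the no-optimization default)."""
        mids = {name: 0.5 * (lo + hi) for name, (lo, hi) in CONSTRAINT_BOX.items()}
        return cls(**mids)


@dataclass
class DecoderModel:
    """A fitted decoder: method tag, retained units, linear map and lag."""

    method: str
    retained_unit_ids: list
    coefficients: np.ndarray
    intercept: float
    lag: float
    bounds: PoolParameterBounds | None = None
    unit_twitches: dict | None = None  # unit id -> (P, Tr, Thr)


# ---------------------------------------------------------------------------
# simple / multiple OLS helpers (closed form; hot-loop friendly)
# ---------------------------------------------------------------------------

def _ols_simple(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    xc = x - x.mean()
    varx = float(xc @ xc)
    if varx == 0.0:
        raise ValueError("degenerate regressor (zero variance)")
    slope = float(xc @ (y - y.mean())) / varx
    intercept = float(y.mean() - slope * x.mean())
    return slope, intercept


def _r_squared(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
    return r * r


# ---------------------------------------------------------------------------
# aEMG
# ---------------------------------------------------------------------------

def fit_aemg(emg_feature: FeatureSeries, torque: FeatureSeries, lag: float = 0.0) -> DecoderModel:
    """OLS of torque on the single smoothed %MVC envelope (series pre-aligned)."""
    a, b = index_align(emg_feature, torque)
    slope, intercept = _ols_simple(a.values, b.values)
    return DecoderModel("aEMG", [], np.array([slope]), intercept, lag)


# ---------------------------------------------------------------------------
# ND
# ---------------------------------------------------------------------------

def refine_units(
    rate_series: dict, torque: FeatureSeries, max_units: int = 10
) -> list:
    """Rank units by R^2 of their smoothed rate against torque; keep the top 10.

    All units are kept when fewer than ``max_units`` are available; ties are
    broken by unit id for determinism.
    """
    if not rate_series:
        raise ValueError("no units to refine")
    scored = []
    for uid, series in rate_series.items():
        a, b = index_align(series, torque)
        scored.append((-_r_squared(a.values, b.values), str(uid), uid))
    scored.sort(key=lambda t: (t[0], t[1]))
    return [uid for _, _, uid in scored[:max_units]]


def fit_nd(
    rate_series: dict,
    torque: FeatureSeries,
    lag: float = 0.0,
    ridge: float = 1e-8,
) -> DecoderModel:
    """Multiple OLS of torque on the retained smoothed firing rates.

    Exactly collinear rates (e.g. duplicated units) trigger a ridge fallback
    with a tiny penalty on the centered design so the fit stays defined.
    """
    if not rate_series:
        raise ValueError("refined unit list is empty")
    ids = list(rate_series.keys())
    ref = torque
    cols = []
    for uid in ids:
        a, ref = index_align(rate_series[uid], ref)
    # second pass now that the common grid is fixed
    y = ref.values
    for uid in ids:
        a, _ = index_align(rate_series[uid], ref)
        cols.append(a.values)
    X = np.column_stack(cols)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    gram = Xc.T @ Xc
    cond = np.linalg.cond(gram) if gram.size else np.inf
    if not np.isfinite(cond) or cond > 1e10:
        logger.info("fit_nd: collinear rates (cond=%.3g), ridge fallback", cond)
        gram = gram + ridge * np.eye(gram.shape[0])
    coef = np.linalg.solve(gram, Xc.T @ yc)
    intercept = float(y.mean() - X.mean(axis=0) @ coef)
    return DecoderModel("ND", ids, coef, intercept, lag)


# ---------------------------------------------------------------------------
# MUDrive primitives
# ---------------------------------------------------------------------------

def compute_rt(
    emg: np.ndarray,
    fs: float,
    rate: FeatureSeries,
    mvc_rms: float,
    t0: float = 0.0,
    rate_gate: float = 5.0,
    window: float = 0.2,
) -> float | None:
    """Recruitment threshold in %MVC: EMG RMS in a 200 ms window at recruitment.

    Recruitment time is the first grid time at which the unit's firing rate
    exceeds 5 Hz.  Returns None when the rate never crosses the gate (the unit
    is then excluded from MUDrive).
    """
    above = rate.values > rate_gate
    if not above.any():
        return None
    t_star = float(rate.times[int(np.argmax(above))])
    i0 = max(0, int(round((t_star - window / 2.0 - t0) * fs)))
    i1 = min(len(emg), int(round((t_star + window / 2.0 - t0) * fs)))
    if i1 <= i0:
        return None
    seg = np.asarray(emg[i0:i1], dtype=float)
    return float(100.0 * np.sqrt(np.mean(seg * seg)) / mvc_rms)


def rescale_twitch_params(rts: np.ndarray, bounds: PoolParameterBounds) -> np.ndarray:
    """Linear rescaling of (P, Tr, Thr) to each unit by recruitment threshold.

    r_i = (RT_i - min RT)/(max RT - min RT); every parameter interpolates its
    pool bound pair, so higher-RT units get larger peak force and longer rise
    and half-relaxation times (size principle).  A single unit, or an
    all-equal-RT pool, maps to r = 0 (the minimum parameters).
    """
    rts = np.asarray(rts, dtype=float)
    if rts.size == 0:
        raise ValueError("no units with a defined recruitment threshold")
    span = float(rts.max() - rts.min())
    r = np.zeros_like(rts) if span == 0.0 else (rts - rts.min()) / span
    p = bounds.p_min + r * (bounds.p_max - bounds.p_min)
    tr = bounds.tr_min + r * (bounds.tr_max - bounds.tr_min)
    thr = bounds.thr_min + r * (bounds.thr_max - bounds.thr_min)
    return np.column_stack([p, tr, thr])


def twitch_waveform(p: float, tr: float, thr: float, fs: float) -> np.ndarray:
    """Sampled single-twitch force profile (see module docstring for the form).

    The waveform is truncated once the decaying tail falls below 1e-4 * P.
    """
    if p <= 0 or tr <= 0 or thr <= 0:
        raise ValueError("twitch parameters must be positive")
    duration = tr + thr * np.log2(1e4)
    n = int(np.ceil(duration * fs)) + 1
    t = np.arange(n) / fs
    rising = p * (t / tr) * np.exp(1.0 - t / tr)
    decay = p * np.exp2(-(t - tr) / thr)
    f = np.where(t <= tr, rising, decay)
    keep = np.nonzero(f >= 1e-4 * p)[0]
    return f[: keep[-1] + 1] if keep.size else f[:1]


_GAIN_KNEE = 0.4
_GAIN_REF = -np.expm1(-2.0 * _GAIN_KNEE**3) / _GAIN_KNEE


def spike_gain(tr: float, isi) -> np.ndarray | float:
    """Rate-dependent twitch gain from x = Tr / ISI (sigmoidal fusion model)."""
    x = tr / np.asarray(isi, dtype=float)
    s_over_x = -np.expm1(-2.0 * x**3) / x
    g = np.where(x <= _GAIN_KNEE, 1.0, s_over_x / _GAIN_REF)
    return g if g.shape else float(g)


def _gain_train(firings: np.ndarray, tr: float) -> np.ndarray:
    gains = np.ones(firings.size)
    if firings.size > 1:
        gains[1:] = spike_gain(tr, np.diff(firings))
    return gains


def mudrive_signal(
    firings_list: list,
    twitch_params: np.ndarray,
    duration: float,
    fs: float,
    t0: float = 0.0,
    spike_scales: list | None = None,
) -> np.ndarray:
    """Summed, gain-scaled twitch trains of a pool on a uniform grid.

    Each spike contributes ``gain(Tr, preceding ISI) * twitch`` shifted to the
    spike time (nearest-sample placement); unit contributions add linearly.
    ``spike_scales`` optionally multiplies each spike's gain by a per-spike
    factor (used by the synthetic generator for twitch-gain drift).
    """
    n = int(round(duration * fs)) + 1
    out = np.zeros(n)
    if spike_scales is None:
        spike_scales = [None] * len(firings_list)
    for firings, (p, tr, thr), scales in zip(
        firings_list, np.asarray(twitch_params, float), spike_scales
    ):
        f = np.asarray(firings, dtype=float)
        if f.size == 0:
            continue
        gains = _gain_train(f, tr)
        if scales is not None:
            gains = gains * np.asarray(scales, dtype=float)
        idx = np.round((f - t0) * fs).astype(np.int64)
        ok = (idx >= 0) & (idx < n)
        if not ok.any():
            continue
        train = np.zeros(n)
        np.add.at(train, idx[ok], gains[ok])
        out += fftconvolve(train, twitch_waveform(p, tr, thr, fs))[:n]
    return out


class MudriveFitter:
    """Caches fold-local spike data so repeated fits with different pool
    bounds (GA candidates, sensitivity draws) stay cheap.

    ``units`` must carry recruitment thresholds; units without one are
    rejected upstream.  ``torque`` is the preprocessed 10 Hz reference of the
    same fold.
    """

    def __init__(
        self,
        units: list[MotorUnit],
        torque: FeatureSeries,
        span: tuple[float, float],
        fs: float = 100.0,
        config: SignalConfig | None = None,
    ):
        if not units:
            raise ValueError("no units with a defined recruitment threshold")
        for u in units:
            if u.recruitment_threshold is None:
                raise ValueError(f"unit {u.id} has no recruitment threshold")
        self.units = units
        self.ids = [u.id for u in units]
        self.rts = np.array([u.recruitment_threshold for u in units], dtype=float)
        self.t0, self.t1 = span
        self.fs = fs
        self.torque = torque
        self.config = config or SignalConfig()
        self.firings = [
            u.firings[(u.firings >= self.t0) & (u.firings < self.t1)] for u in units
        ]

    def feature(self, bounds: PoolParameterBounds) -> FeatureSeries:
        # windowed *mean* (not RMS): the force-like signal gets the same
        # windowing as the torque reference, so the twitch ripple does not
        # bias the feature upward where its within-window variance is high
        params = rescale_twitch_params(self.rts, bounds)
        raw = mudrive_signal(self.firings, params, self.t1 - self.t0, self.fs, self.t0)
        feat = windowed_mean(raw, self.fs, self.config.rms_window_s, self.config.step_s, self.t0)
        return kalman_smooth(feat, self.config.kalman_process_var, self.config.kalman_measurement_var)

    def fit(self, bounds: PoolParameterBounds) -> tuple[DecoderModel, float]:
        """Fit the linear map for one candidate bounds vector.

        Returns (model, training RMSE); the regression is refit for every
        candidate so the optimization cost is well-defined.
        """
        bounds.validate()
        feat = self.feature(bounds)
        lag, shifted = align_by_xcorr(feat, self.torque, self.config.max_lag_s)
        a, b = index_align(shifted, self.torque)
        slope, intercept = _ols_simple(a.values, b.values)
        resid = slope * a.values + intercept - b.values
        rmse = float(np.sqrt(np.mean(resid * resid)))
        params = rescale_twitch_params(self.rts, bounds)
        twitches = {uid: tuple(row) for uid, row in zip(self.ids, params)}
        model = DecoderModel(
            "MUDrive", list(self.ids), np.array([slope]), intercept, lag,
            bounds=bounds, unit_twitches=twitches,
        )
        return model, rmse


def fit_mudrive(
    units: list[MotorUnit],
    bounds: PoolParameterBounds,
    torque: FeatureSeries,
    span: tuple[float, float],
    fs: float = 100.0,
    config: SignalConfig | None = None,
) -> DecoderModel:
    """Convenience wrapper: rescale -> convolve -> smooth -> align -> OLS."""
    return MudriveFitter(units, torque, span, fs, config).fit(bounds)[0]


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def predict(model: DecoderModel, features) -> FeatureSeries:
    """Apply a fitted model's stored lag and linear map to new features.

    ``features`` is a single :class:`FeatureSeries` for aEMG/MUDrive, or a
    dict of per-unit rate series (keyed by unit id) for ND.
    """
    if model.method == "ND":
        missing = [uid for uid in model.retained_unit_ids if uid not in features]
        if missing:
            raise KeyError(f"missing retained unit(s): {missing}")
        series = [features[uid].shifted(model.lag) for uid in model.retained_unit_ids]
        ref = series[0]
        for s in series[1:]:
            ref, _ = index_align(ref, s)
        cols = [index_align(s, ref)[0].values for s in series]
        values = np.column_stack(cols) @ model.coefficients + model.intercept
        return FeatureSeries(ref.times.copy(), values, ref.step)
    shifted = features.shifted(model.lag)
    values = shifted.values * model.coefficients[0] + model.intercept
    return FeatureSeries(shifted.times.copy(), values, shifted.step)
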