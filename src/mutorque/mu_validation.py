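"""Spike-triggered-averaging (STA) validation of decomposed motor units.

A decomposed unit is trusted only if (a) the STA of the filtered EMG locked to
its firing times reproduces its decomposed MUAP template (squared peak
normalized cross-correlation R^2 > 0.6) and (b) the unit is stable over time:
the coefficient of variation of the peak-to-peak amplitude of STAs computed in
a moving 8 s window (4 s step) stays below 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("mutorque")


@dataclass
class MotorUnit:
    """One decomposed (or simulated) motor unit.

    ``truth_twitch`` is the ground-truth (P, Tr, Thr) triple for synthetic
    units; it is absent for real decompositions.
    """

    id: int | str
    firings: np.ndarray = field(default_factory=lambda: np.empty(0))
    muap_template: np.ndarray | None = None
    recruitment_threshold: float | None = None
    accepted: bool | None = None
    truth_twitch: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.firings = np.asarray(self.firings, dtype=float)
        if self.firings.size > 1 and np.any(np.diff(self.firings) <= 0):
            raise ValueError(f"unit {self.id}: firing times must be strictly increasing")


@dataclass
class ValidationReport:
    r_squared: float
    p2p_cv: float
    n_segments: int
    accepted: bool
    reason: str = ""


def sta_template(
    emg: np.ndarray,
    fs: float,
    firings: np.ndarray,
    window: float = 0.080,
    t0: float = 0.0,
) -> np.ndarray:
    """Average of EMG windows centered at each firing time.

    Firings whose window would run off the trace are skipped (counted in the
    log) rather than zero-padded, to avoid biasing the template tails.
    """
    x = np.asarray(emg, dtype=float)
    f = np.asarray(firings, dtype=float)
    half = int(round(window * fs / 2.0))
    idx = np.round((f - t0) * fs).astype(np.int64)
    ok = (idx - half >= 0) & (idx + half <= x.size)
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.debug("sta_template: skipped %d firings without full window support", n_skipped)
    idx = idx[ok]
    if idx.size == 0:
        raise ValueError("no firings with full window support")
    offsets = np.arange(-half, half)
    return x[idx[:, None] + offsets[None, :]].mean(axis=0)


def _peak_normalized_xcorr(a: np.ndarray, b: np.ndarray) -> float:
    """Peak |normalized cross-correlation| over all shifts (global demeaning)."""
    ac = a - a.mean()
    bc = b - b.mean()
    denom = np.linalg.norm(ac) * np.linalg.norm(bc)
    if denom == 0.0:
        return 0.0
    return float(np.abs(np.correlate(ac, bc, mode="full")).max() / denom)


def validate_mu(
    emg: np.ndarray,
    fs: float,
    unit: MotorUnit,
    seg_window: float = 8.0,
    seg_step: float = 4.0,
    t0: float = 0.0,
    sta_window: float = 0.080,
    r2_gate: float = 0.6,
    cv_gate: float = 0.5,
    min_seg_firings: int = 4,
) -> ValidationReport:
    """Two-step STA validation of one unit against its decomposed template.

    R^2 is the squared peak normalized cross-correlation between the
    whole-trial STA and the decomposed template (alignment by the
    correlation-maximizing shift); the CV gate uses peak-to-peak amplitudes of
    per-segment STAs over segments containing at least ``min_seg_firings``
    usable firings.  Both measures are invariant to a global EMG gain.
    """
    if unit.muap_template is None:
        raise ValueError(f"unit {unit.id} has no decomposed template")
    try:
        sta = sta_template(emg, fs, unit.firings, sta_window, t0)
    except ValueError:
        return ValidationReport(0.0, np.nan, 0, False, reason="no usable firings")
    r2 = _peak_normalized_xcorr(sta, np.asarray(unit.muap_template, float)) ** 2

    duration = len(emg) / fs
    half = int(round(sta_window * fs / 2.0))
    idx = np.round((unit.firings - t0) * fs).astype(np.int64)
    usable = unit.firings[(idx - half >= 0) & (idx + half <= len(emg))]
    p2ps = []
    s = t0
    while s + seg_window <= t0 + duration + 1e-9:
        seg_firings = usable[(usable >= s) & (usable < s + seg_window)]
        if seg_firings.size >= min_seg_firings:
            seg_sta = sta_template(emg, fs, seg_firings, sta_window, t0)
            p2ps.append(float(np.ptp(seg_sta)))
        s += seg_step
    n_segments = len(p2ps)
    if n_segments < 2:
        return ValidationReport(r2, np.nan, n_segments, False, reason="insufficient segments")
    p2ps = np.asarray(p2ps)
    mean_p2p = p2ps.mean()
    cv = float(p2ps.std(ddof=1) / mean_p2p) if mean_p2p > 0 else np.inf
    accepted = (r2 > r2_gate) and (cv < cv_gate)
    return ValidationReport(r2, cv, n_segments, accepted)
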