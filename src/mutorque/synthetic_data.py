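"""Synthetic motor-unit-pool trial generator.

Emulates the trapezoid activation protocol used for isometric ankle torque
tracking: a 5 s quiescent baseline, then trapezoids ramping at 10 %MVC/s to a
20 or 35 %MVC target, holding 12 s, ramping down, with 10 s of rest between
trapezoids.  A recruitment-ordered pool of motor units fires with
excitation-driven rate coding and ISI jitter; surface EMG is formed by
superposing each unit's MUAP at its firing times (so amplitude cancellation
occurs naturally), and torque is formed by superposing rate-gain-scaled force
twitches built from ground-truth pool bounds - the same twitch model the
MUDrive decoder fits, which is what makes the generator a useful ground truth
for every downstream stage.

All randomness is drawn from per-stage streams keyed on the configured seed,
so identical configurations produce bit-identical bundles.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .decoders import PoolParameterBounds, mudrive_signal, rescale_twitch_params
from .mu_validation import MotorUnit

logger = logging.getLogger("mutorque")

SEGMENT_LABELS = ("quiescent", "ramp_up", "hold", "ramp_down", "rest")


def _smoothed_unit_noise(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """Zero-mean, unit-SD band-limited noise (moving-average smoothed)."""
    k = max(1, min(k, n))
    w = np.convolve(rng.standard_normal(n), np.ones(k) / k, mode="same")[:n]
    sd = w.std()
    return w / sd if sd > 0 else w


def _default_true_bounds() -> PoolParameterBounds:
    # ground-truth pool bounds, inside the physiologic constraint box
    return PoolParameterBounds(p_max=60.0, tr_min=0.050, tr_max=0.180,
                               thr_min=0.030, thr_max=0.125)


@dataclass
class PoolConfig:
    """Parameters of one simulated muscle (motor unit pool + noise model).

    ``torque_scale`` maps summed twitch force (arb. units) onto the Nm scale
    of a dynamometer; the default was calibrated once so the default pool's
    plateau torque at a 35 %MVC target is a few tens of Nm.  The decoders fit
    a regression, so the scale only matters for absolute-threshold rules
    (e.g. the sensitivity convergence tolerance).
    """

    n_units: int = 16
    rt_min: float = 1.0                 # %MVC of the lowest recruitment threshold
    recruitment_range: float = 30.0     # max RT / min RT
    recruitment_shape: float = 1.0      # >1 clusters thresholds toward rt_min
    n_background: int = 100             # additional active units beyond the decomposed count
    visibility_sigma: float = 0.6       # lognormal SD of per-unit surface visibility
    detection_min_firings: int = 30     # discharges needed for a unit to be decomposable
    miss_rate: float = 0.08             # decomposition false-negative rate per discharge
    false_rate: float = 0.05            # false-positive discharges, fraction of true count
    min_rate: float = 8.0               # Hz at recruitment
    peak_rate: float = 35.0             # Hz cap
    rate_gain: float = 1.0              # Hz per %MVC above threshold
    isi_cv: float = 0.15                # ISI coefficient of variation
    recruitment_hysteresis: float = 2.0 # %MVC below RT at which a unit derecruits
    drive_fluctuation_cv: float = 0.05  # common-drive tracking error, fraction of target
    true_bounds: PoolParameterBounds = field(default_factory=_default_true_bounds)
    muap_duration: float = 0.015        # s
    muap_amp_scaling: float = 0.6       # MUAP amplitude ~ RT ** exponent (sublinear)
    emg_fs: float = 2222.0
    torque_fs: float = 100.0
    emg_snr_db: float = 15.0
    emg_gain_drift_cv: float = 0.05     # slow multiplicative EMG amplitude drift
    torque_noise_sd: float = 0.2        # Nm, after torque_scale
    twitch_gain_cv: float = 0.05        # slow per-unit force-gain drift (potentiation-like)
    torque_scale: float = 0.0035        # arb. twitch force units -> Nm
    seed: int = 0

    def validate(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if not (0 < self.min_rate < self.peak_rate):
            raise ValueError("need 0 < min_rate < peak_rate")
        if self.isi_cv < 0:
            raise ValueError("isi_cv must be >= 0")
        if self.emg_fs <= 0 or self.torque_fs <= 0:
            raise ValueError("sampling rates must be positive")


@dataclass
class ExcitationProfile:
    """Piecewise-linear excitation in %MVC with labelled segments.

    ``times``/``excitation`` are the breakpoints; ``segment_labels[i]`` labels
    the span [times[i], times[i+1]].
    """

    times: np.ndarray
    excitation: np.ndarray
    segment_labels: list[str]

    def value_at(self, t) -> np.ndarray:
        return np.interp(t, self.times, self.excitation)

    @property
    def duration(self) -> float:
        return float(self.times[-1])

    def trapezoid_spans(self) -> list[tuple[float, float]]:
        """(start of ramp_up, end of ramp_down) for each trapezoid."""
        spans = []
        start = None
        for i, lab in enumerate(self.segment_labels):
            if lab == "ramp_up" and start is None:
                start = float(self.times[i])
            if lab == "ramp_down":
                spans.append((start, float(self.times[i + 1])))
                start = None
        return spans


@dataclass
class TrialBundle:
    """One simulated (or loaded) trial: raw signals, units, references, metadata."""

    emg: np.ndarray                     # (n_samples,) or (n_samples, n_channels)
    emg_fs: float
    torque: np.ndarray                  # (n_samples,)
    torque_fs: float
    units: list[MotorUnit]
    mvc_rms: float
    target_mvc: float
    muscle: str = "ta"
    profile: ExcitationProfile | None = None
    meta: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return len(self.torque) / self.torque_fs

    @property
    def trapezoids(self) -> list[tuple[float, float]]:
        return [tuple(span) for span in self.meta["trapezoids"]]

    def emg_channel(self, channel: int = 0) -> np.ndarray:
        e = np.asarray(self.emg)
        return e if e.ndim == 1 else e[:, channel]


# ---------------------------------------------------------------------------
# excitation profile
# ---------------------------------------------------------------------------

def build_trapezoid_profile(
    target_mvc: float,
    n_trapezoids: int = 2,
    ramp_rate: float = 10.0,
    quiescent: float = 5.0,
    hold: float = 12.0,
    rest: float = 10.0,
    tail: float = 5.0,
) -> ExcitationProfile:
    """Trapezoid tracking profile: ramp at ``ramp_rate`` %MVC/s, hold 12 s."""
    if target_mvc <= 0 or ramp_rate <= 0:
        raise ValueError("target_mvc and ramp_rate must be positive")
    if n_trapezoids < 1:
        raise ValueError("n_trapezoids must be >= 1")
    ramp = target_mvc / ramp_rate
    times = [0.0, quiescent]
    exc = [0.0, 0.0]
    labels = ["quiescent"]
    for k in range(n_trapezoids):
        t = times[-1]
        times += [t + ramp, t + ramp + hold, t + ramp + hold + ramp]
        exc += [target_mvc, target_mvc, 0.0]
        labels += ["ramp_up", "hold", "ramp_down"]
        if k < n_trapezoids - 1:
            times.append(times[-1] + rest)
            exc.append(0.0)
            labels.append("rest")
    times.append(times[-1] + tail)
    exc.append(0.0)
    labels.append("rest")
    return ExcitationProfile(np.asarray(times), np.asarray(exc, dtype=float), labels)


# ---------------------------------------------------------------------------
# pool generation
# ---------------------------------------------------------------------------

def _make_muap(rng: np.random.Generator, amp: float, duration: float, fs: float) -> np.ndarray:
    """Zero-mean biphasic waveform: windowed first derivative of a Gaussian."""
    n = max(5, int(round(duration * fs)))
    t = np.arange(n) / fs - duration / 2.0
    sigma = duration / 6.0 * rng.uniform(0.8, 1.2)
    w = -t * np.exp(-(t**2) / (2.0 * sigma**2))
    w = w - w.mean()
    polarity = 1.0 if rng.random() < 0.5 else -1.0
    return polarity * amp * w / np.ptp(w)


def generate_pool(config: PoolConfig) -> list[MotorUnit]:
    """Build a recruitment-ordered pool with ground-truth twitch parameters.

    Thresholds follow an exponential ladder
    RT_i = rt_min * range^(((i-1)/(n-1))^shape) (a single unit sits at
    rt_min; shape > 1 skews the distribution further toward low thresholds); ground-truth twitches come from the same
    linear rescaling rule the decoder uses, applied to ``true_bounds``; MUAP
    peak-to-peak amplitude grows monotonically with RT.
    """
    config.validate()
    rng = np.random.default_rng([1, config.seed])
    n = config.n_units
    if n == 1:
        rts = np.array([config.rt_min])
    else:
        expo = (np.arange(n) / (n - 1)) ** config.recruitment_shape
        rts = config.rt_min * config.recruitment_range**expo
    truth = rescale_twitch_params(rts, config.true_bounds)
    units = []
    for i in range(n):
        amp = (rts[i] / config.rt_min) ** config.muap_amp_scaling
        muap = _make_muap(rng, amp, config.muap_duration, config.emg_fs)
        units.append(
            MotorUnit(
                id=i,
                firings=np.empty(0),
                muap_template=muap,
                recruitment_threshold=float(rts[i]),
                truth_twitch=tuple(truth[i]),
            )
        )
    return units


def generate_full_pool(config: PoolConfig) -> list[MotorUnit]:
    """The whole active pool (n_units + n_background on one threshold ladder)
    with per-unit surface visibility applied to the MUAP templates.

    Surface decomposition only recovers the units whose action potentials
    stand out at the electrode, which depends on unit size *and* depth.
    Visibility is a lognormal per-unit factor (sigma ``visibility_sigma``)
    multiplying the size-scaled MUAP amplitude; it affects the EMG and
    detectability only, never the force side.
    """
    total = replace(config, n_units=config.n_units + config.n_background)
    pool = generate_pool(total)
    if config.visibility_sigma <= 0:
        return pool
    rng = np.random.default_rng([8, config.seed])
    vis = np.exp(config.visibility_sigma * rng.standard_normal(len(pool)))
    return [replace(u, muap_template=u.muap_template * v) for u, v in zip(pool, vis)]


# ---------------------------------------------------------------------------
# spike trains
# ---------------------------------------------------------------------------

def perturb_profile(
    profile: ExcitationProfile,
    cv: float,
    seed: int,
    grid_hz: float = 20.0,
    smooth_s: float = 0.4,
) -> ExcitationProfile:
    """Common-drive tracking fluctuation around the target profile.

    Human subjects do not trace the target perfectly: the drive all units
    share wobbles around it, with an amplitude proportional to the target
    level (signal-dependent motor noise).  The fluctuation is band-limited
    (Gaussian noise smoothed over ``smooth_s``), multiplicative (so it
    vanishes during quiescence), and deterministic under a fixed seed.
    """
    if cv == 0.0:
        return profile
    rng = np.random.default_rng([5, seed])
    t = np.arange(0.0, profile.duration + 1.0 / grid_hz, 1.0 / grid_hz)
    base = profile.value_at(t)
    smooth = _smoothed_unit_noise(rng, t.size, int(round(smooth_s * grid_hz)))
    exc = np.maximum(base * (1.0 + cv * smooth), 0.0)
    mids = 0.5 * (t[:-1] + t[1:])
    seg_idx = np.clip(np.searchsorted(profile.times, mids, side="right") - 1,
                      0, len(profile.segment_labels) - 1)
    labels = [profile.segment_labels[i] for i in seg_idx]
    return ExcitationProfile(t, exc, labels)


def _segment_crossing(profile: ExcitationProfile, rt: float, t_from: float) -> float | None:
    """First time >= t_from at which excitation rises strictly above rt."""
    tt, ee = profile.times, profile.excitation
    start = max(0, int(np.searchsorted(tt, t_from, side="right")) - 1)
    for i in range(start, len(tt) - 1):
        t0, t1, e0, e1 = tt[i], tt[i + 1], ee[i], ee[i + 1]
        if t1 <= t_from:
            continue
        lo = max(t0, t_from)
        e_lo = np.interp(lo, tt, ee)
        if e_lo > rt:
            return float(lo)
        if e1 > rt and e1 != e0:
            tc = t0 + (rt - e0) * (t1 - t0) / (e1 - e0)
            if tc >= t_from - 1e-12:
                # nudge past the exact crossing so excitation is strictly above
                return float(max(tc, t_from)) + 1e-6
    return None


def simulate_spike_trains(
    pool: list[MotorUnit],
    profile: ExcitationProfile,
    config: PoolConfig,
    trial_seed: int | None = None,
) -> list[MotorUnit]:
    """Rate-coded firing with Gaussian ISI jitter; fills ``firings`` per unit.

    A unit starts firing when excitation exceeds its recruitment threshold,
    at mean rate min_rate + rate_gain * max(excitation - RT, 0) capped at
    peak_rate; successive ISIs are perturbed with coefficient of variation
    ``isi_cv`` and floored at 2 ms.  Once recruited, a unit keeps firing
    until excitation falls ``recruitment_hysteresis`` %MVC below its
    threshold (derecruitment hysteresis: near-threshold units fire steadily
    at their minimum rate rather than flickering with drive fluctuations).
    Units never recruited keep empty firing lists.
    """
    config.validate()
    seed = config.seed if trial_seed is None else trial_seed
    t_end = profile.duration
    out = []
    for k, unit in enumerate(pool):
        rng = np.random.default_rng([2, seed, k])
        rt = unit.recruitment_threshold
        rt_off = max(rt - config.recruitment_hysteresis, 1e-9)
        firings: list[float] = []
        recruited = False
        t = _segment_crossing(profile, rt, 0.0)
        while t is not None and t < t_end:
            exc = float(profile.value_at(t))
            if exc > (rt_off if recruited else rt):
                recruited = True
                firings.append(t)
                rate = min(
                    config.peak_rate,
                    config.min_rate + config.rate_gain * max(exc - rt, 0.0),
                )
                isi = (1.0 / rate) * (1.0 + config.isi_cv * rng.standard_normal())
                t = t + max(isi, 0.002)
            else:
                recruited = False
                t = _segment_crossing(profile, rt, t)
        out.append(replace(unit, firings=np.asarray(firings)))
    return out


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------

def synthesize_emg(
    pool: list[MotorUnit],
    config: PoolConfig,
    duration: float,
    profile: ExcitationProfile | None = None,
    trial_seed: int | None = None,
    noise: bool = True,
) -> np.ndarray:
    """Superpose each unit's MUAP at its firing times, plus white noise.

    Noise power is set from the clean signal's RMS over active segments
    (excitation > 0 when a profile is given, else the whole trace) at the
    configured SNR in dB.
    """
    fs = config.emg_fs
    n = int(round(duration * fs)) + 1
    x = np.zeros(n)
    for unit in pool:
        w = np.asarray(unit.muap_template, dtype=float)
        half = len(w) // 2
        for t in unit.firings:
            i0 = int(round(t * fs)) - half
            a, b = max(i0, 0), min(i0 + len(w), n)
            if b > a:
                x[a:b] += w[a - i0 : b - i0]
    if not noise:
        return x
    seed = config.seed if trial_seed is None else trial_seed
    rng = np.random.default_rng([3, seed])
    if profile is not None:
        t = np.arange(n) / fs
        active = profile.value_at(t) > 0
    else:
        active = np.ones(n, dtype=bool)
    clean_rms = np.sqrt(np.mean(x[active] ** 2)) if active.any() else 0.0
    sigma = clean_rms * 10.0 ** (-config.emg_snr_db / 20.0)
    x = x + sigma * rng.standard_normal(n)
    if config.emg_gain_drift_cv > 0:
        # slow multiplicative amplitude drift (electrode/impedance
        # nonstationarity): invisible to spike-train-based decoders, a direct
        # handicap for amplitude-based decoding
        rng_g = np.random.default_rng([7, seed])
        t_grid = np.arange(0.0, duration + 0.5, 0.5)
        gain = 1.0 + config.emg_gain_drift_cv * _smoothed_unit_noise(rng_g, t_grid.size, 10)
        x = x * np.interp(np.arange(n) / fs, t_grid, gain)
    return x


def synthesize_torque(
    pool: list[MotorUnit],
    config: PoolConfig,
    duration: float,
    trial_seed: int | None = None,
    noise: bool = True,
) -> np.ndarray:
    """Ground-truth torque: gain-scaled twitch superposition plus noise.

    Two noise sources when enabled: additive white sensor noise
    (``torque_noise_sd``), and slow per-unit drift of the twitch force gain
    (``twitch_gain_cv``, potentiation/fatigue-like) that is invisible to the
    EMG side, so no decoder can explain it - the physiologic reason tracking
    error grows with the activation level.
    """
    seed = config.seed if trial_seed is None else trial_seed
    params = np.array([u.truth_twitch for u in pool], dtype=float).reshape(-1, 3)
    firings = [u.firings for u in pool]
    scales = None
    if noise and config.twitch_gain_cv > 0:
        scales = []
        t_grid = np.arange(0.0, duration + 0.5, 0.5)
        for ui, f in enumerate(firings):
            rng_u = np.random.default_rng([6, seed, ui])
            # ~5 s smoothing of the per-unit gain drift
            gain = 1.0 + config.twitch_gain_cv * _smoothed_unit_noise(rng_u, t_grid.size, 10)
            scales.append(np.interp(f, t_grid, gain) if len(f) else None)
    x = config.torque_scale * mudrive_signal(
        firings, params, duration, config.torque_fs, spike_scales=scales
    )
    if not noise:
        return x
    rng = np.random.default_rng([4, seed])
    return x + config.torque_noise_sd * rng.standard_normal(x.size)


def _corrupt_firings(
    firings: np.ndarray, config: PoolConfig, trial_seed: int, unit_index: int
) -> np.ndarray:
    """Decomposition-error emulation: missed and spurious discharges.

    Each true discharge is dropped with probability ``miss_rate``; spurious
    discharges amounting to ``false_rate`` of the true count are inserted
    uniformly over the unit's active span.  A 2 ms refractory separation is
    enforced on the result.
    """
    if firings.size == 0 or (config.miss_rate == 0 and config.false_rate == 0):
        return firings
    rng = np.random.default_rng([9, trial_seed, unit_index])
    keep = firings[rng.random(firings.size) >= config.miss_rate]
    n_false = rng.poisson(config.false_rate * firings.size)
    false = rng.uniform(firings[0], firings[-1], n_false)
    out = np.sort(np.concatenate([keep, false]))
    if out.size > 1:
        out = out[np.concatenate([[True], np.diff(out) > 0.002])]
    return out


def _simulate_mvc_rms(config: PoolConfig, pool: list[MotorUnit], trial_seed: int) -> float:
    """Reference MVC: a short 100 %MVC burst, band-passed, max windowed RMS."""
    from .signal_processing import bandpass_emg, compute_mvc

    prof = ExcitationProfile(
        np.array([0.0, 0.5, 3.5, 4.0]),
        np.array([0.0, 100.0, 100.0, 0.0]),
        ["ramp_up", "hold", "ramp_down"],
    )
    mvc_pool = simulate_spike_trains(pool, prof, config, trial_seed=trial_seed + 1)
    emg = synthesize_emg(mvc_pool, config, prof.duration, prof, trial_seed=trial_seed + 1)
    return compute_mvc(bandpass_emg(emg, config.emg_fs), config.emg_fs)


def generate_trial_bundle(
    config: PoolConfig,
    target_mvc: float,
    n_trapezoids: int = 2,
    muscle: str = "ta",
    trial_seed: int | None = None,
) -> TrialBundle:
    """Full trial: profile -> pool -> spikes -> EMG + torque + MVC reference.

    ``trial_seed`` (default: ``config.seed``) drives the spike/noise streams
    while the pool itself is keyed on ``config.seed``, so the same virtual
    muscle can perform several trials.
    """
    config.validate()
    seed = config.seed if trial_seed is None else trial_seed
    profile = build_trapezoid_profile(target_mvc, n_trapezoids)
    drive = perturb_profile(profile, config.drive_fluctuation_cv, seed)
    full_pool = generate_full_pool(config)
    full_pool = simulate_spike_trains(full_pool, drive, config, trial_seed=seed)
    emg = synthesize_emg(full_pool, config, profile.duration, profile, trial_seed=seed)
    torque = synthesize_torque(full_pool, config, profile.duration, trial_seed=seed)
    mvc_rms = _simulate_mvc_rms(config, generate_full_pool(config), seed)
    # the emulated decomposition output: the n_units most visible units that
    # fired enough to be tracked, with imperfect discharge identification
    # (EMG and torque always come from the true spikes of the whole pool)
    candidates = [
        (k, u) for k, u in enumerate(full_pool)
        if u.firings.size >= config.detection_min_firings
    ]
    candidates.sort(key=lambda ku: (-float(np.ptp(ku[1].muap_template)), ku[0]))
    detected = sorted(candidates[: config.n_units], key=lambda ku: ku[0])
    exposed = [
        replace(u, firings=_corrupt_firings(u.firings, config, seed, k))
        for k, u in detected
    ]
    meta = {
        "seed": int(config.seed),
        "trial_seed": int(seed),
        "trapezoids": [list(s) for s in profile.trapezoid_spans()],
        "n_trapezoids": int(n_trapezoids),
        "n_background": int(config.n_background),
    }
    return TrialBundle(
        emg=emg, emg_fs=config.emg_fs, torque=torque, torque_fs=config.torque_fs,
        units=exposed, mvc_rms=mvc_rms, target_mvc=float(target_mvc),
        muscle=muscle, profile=profile, meta=meta,
    )


# ---------------------------------------------------------------------------
# bundle I/O (JSON manifest + TSV arrays; text-only and diffable)
# ---------------------------------------------------------------------------

_FMT = "%.17g"  # exact float64 round-trip


def write_trial_bundle(bundle: TrialBundle, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    emg = np.asarray(bundle.emg)
    emg2d = emg[:, None] if emg.ndim == 1 else emg
    np.savetxt(path / f"emg_{bundle.muscle}.tsv", emg2d, fmt=_FMT, delimiter="\t")
    np.savetxt(path / "torque.tsv", bundle.torque[:, None], fmt=_FMT, delimiter="\t")
    unit_meta = []
    for u in bundle.units:
        np.savetxt(path / f"mu_{u.id}_firings.tsv", np.asarray(u.firings)[:, None]
                   if len(u.firings) else np.empty((0, 1)), fmt=_FMT, delimiter="\t")
        np.savetxt(path / f"mu_{u.id}_muap.tsv", np.asarray(u.muap_template)[:, None],
                   fmt=_FMT, delimiter="\t")
        unit_meta.append({
            "id": u.id,
            "recruitment_threshold": u.recruitment_threshold,
            "truth_twitch": list(u.truth_twitch) if u.truth_twitch is not None else None,
        })
    manifest = {
        "emg_fs": bundle.emg_fs,
        "torque_fs": bundle.torque_fs,
        "muscle": bundle.muscle,
        "mvc_rms": bundle.mvc_rms,
        "target_mvc": bundle.target_mvc,
        "units": unit_meta,
        "meta": bundle.meta,
        "profile": None if bundle.profile is None else {
            "times": bundle.profile.times.tolist(),
            "excitation": bundle.profile.excitation.tolist(),
            "segment_labels": list(bundle.profile.segment_labels),
        },
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def _require(path: Path, component: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"trial bundle is missing its '{component}' file: {path}")
    return path


def _read_tsv(path: Path) -> np.ndarray:
    arr = np.loadtxt(path, delimiter="\t", ndmin=2)
    return arr


def read_trial_bundle(path) -> TrialBundle:
    path = Path(path)
    manifest_path = _require(path / "manifest.json", "manifest")
    manifest = json.loads(manifest_path.read_text())
    muscle = manifest["muscle"]
    emg = _read_tsv(_require(path / f"emg_{muscle}.tsv", "emg"))
    if emg.shape[1] == 1:
        emg = emg[:, 0]
    torque = _read_tsv(_require(path / "torque.tsv", "torque"))[:, 0]
    units = []
    for um in manifest["units"]:
        uid = um["id"]
        firings = _read_tsv(_require(path / f"mu_{uid}_firings.tsv", f"mu_{uid}_firings"))
        muap = _read_tsv(_require(path / f"mu_{uid}_muap.tsv", f"mu_{uid}_muap"))[:, 0]
        units.append(MotorUnit(
            id=uid,
            firings=firings[:, 0] if firings.size else np.empty(0),
            muap_template=muap,
            recruitment_threshold=um["recruitment_threshold"],
            truth_twitch=None if um["truth_twitch"] is None else tuple(um["truth_twitch"]),
        ))
    prof = manifest.get("profile")
    profile = None if prof is None else ExcitationProfile(
        np.asarray(prof["times"], float),
        np.asarray(prof["excitation"], float),
        list(prof["segment_labels"]),
    )
    return TrialBundle(
        emg=emg, emg_fs=manifest["emg_fs"], torque=torque,
        torque_fs=manifest["torque_fs"], units=units, mvc_rms=manifest["mvc_rms"],
        target_mvc=manifest["target_mvc"], muscle=muscle, profile=profile,
        meta=manifest["meta"],
    )


def bundles_equal(a: TrialBundle, b: TrialBundle) -> bool:
    """Field-for-field equality (floating point exact); used by round-trip tests."""
    if (a.emg_fs, a.torque_fs, a.muscle, a.mvc_rms, a.target_mvc) != (
        b.emg_fs, b.torque_fs, b.muscle, b.mvc_rms, b.target_mvc
    ):
        return False
    if not np.array_equal(np.asarray(a.emg), np.asarray(b.emg)):
        return False
    if not np.array_equal(a.torque, b.torque):
        return False
    if len(a.units) != len(b.units):
        return False
    for ua, ub in zip(a.units, b.units):
        if ua.id != ub.id or not np.array_equal(ua.firings, ub.firings):
            return False
        if not np.array_equal(ua.muap_template, ub.muap_template):
            return False
        if ua.recruitment_threshold != ub.recruitment_threshold:
            return False
        if ua.truth_twitch != ub.truth_twitch:
            return False
    return a.meta == b.meta
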