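"""Two-fold cross-validation, RMSE scoring, paired statistics and cohorts.

A trial contains exactly two trapezoids; the folds split at the midpoint of
the inter-trapezoid rest.  Everything a model needs - unit validation, unit
refinement, recruitment thresholds, alignment lag, GA-optimized bounds and
the regression itself - is estimated on the training fold alone, then frozen
and applied to the held-out fold, so no test data influences the fit.

Cohort-level runs simulate several virtual subjects (independent motor-unit
pools), evaluate the three decoders on each subject x target level, and
summarize with per-condition descriptives plus paired t-tests
(Bonferroni-corrected over the three method pairs) and Cohen's d on the
paired differences.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .decoders import (
    CANONICAL_PARAM_ORDER,
    DecoderModel,
    MudriveFitter,
    PoolParameterBounds,
    compute_rt,
    fit_aemg,
    fit_nd,
    mudrive_signal,
    predict,
    refine_units,
)
from .mu_validation import MotorUnit, validate_mu
from .optimization import GAConfig, ga_optimize
from .signal_processing import (
    FeatureSeries,
    SignalConfig,
    align_by_xcorr,
    bandpass_emg,
    firing_rate_series,
    index_align,
    kalman_smooth,
    moving_rms,
    normalize_to_mvc,
    preprocess_torque,
    windowed_mean,
)
from .synthetic_data import PoolConfig, TrialBundle, generate_trial_bundle

logger = logging.getLogger("mutorque")

METHODS = ("aEMG", "ND", "MUDrive")


@dataclass
class EvaluationResult:
    method: str
    subject: str
    muscle: str
    target_mvc: float
    fold_rmse: tuple[float, float]
    mean_rmse: float


@dataclass
class PairwiseComparison:
    pair: tuple[str, str]
    t: float
    p: float
    p_adjusted: float
    cohen_d: float
    degenerate: bool = False


@dataclass
class CohortReport:
    descriptives: pd.DataFrame          # mean / SE of RMSE by method x level
    comparisons: list[PairwiseComparison]
    n_subjects: int
    warnings: list[str] = field(default_factory=list)


def rmse(estimate: FeatureSeries, reference: FeatureSeries) -> float:
    """Root-mean-square error between two index-aligned series."""
    if len(estimate) != len(reference):
        raise ValueError("series length mismatch")
    d = estimate.values - reference.values
    return float(np.sqrt(np.mean(d * d)))


# ---------------------------------------------------------------------------
# fold preparation and per-method fit/predict pipelines
# ---------------------------------------------------------------------------

@dataclass
class _Fold:
    t0: float
    t1: float
    emg: np.ndarray          # band-passed fold EMG (channel used for feedback)
    torque: FeatureSeries    # preprocessed 10 Hz reference


def _prepare_fold(bundle: TrialBundle, span: tuple[float, float], cfg: SignalConfig) -> _Fold:
    t0, t1 = span
    tq = bundle.torque[int(round(t0 * bundle.torque_fs)): int(round(t1 * bundle.torque_fs)) + 1]
    torque = preprocess_torque(tq, bundle.torque_fs, cfg, t0=t0)
    raw = bundle.emg_channel()
    e0, e1 = int(round(t0 * bundle.emg_fs)), int(round(t1 * bundle.emg_fs)) + 1
    emg = bandpass_emg(raw[e0:e1], bundle.emg_fs, cfg.emg_band_hz)
    return _Fold(t0, t1, emg, torque)


def _fold_firings(unit: MotorUnit, fold: _Fold) -> np.ndarray:
    return unit.firings[(unit.firings >= fold.t0) & (unit.firings < fold.t1)]


def _accepted_units(bundle: TrialBundle, fold: _Fold, cfg: SignalConfig) -> list[MotorUnit]:
    accepted = []
    for unit in bundle.units:
        fold_unit = replace(unit, firings=_fold_firings(unit, fold))
        if fold_unit.firings.size == 0:
            continue
        report = validate_mu(fold.emg, bundle.emg_fs, fold_unit, t0=fold.t0)
        if report.accepted:
            accepted.append(replace(fold_unit, accepted=True))
    return accepted


def _rate_features(units: list[MotorUnit], fold: _Fold, cfg: SignalConfig) -> dict:
    rates = {}
    for unit in units:
        series = firing_rate_series(
            _fold_firings(unit, fold), (fold.t0, fold.t1), cfg.rms_window_s, cfg.step_s
        )
        rates[unit.id] = kalman_smooth(series, cfg.kalman_process_var, cfg.kalman_measurement_var)
    return rates


def _aemg_feature(bundle: TrialBundle, fold: _Fold, cfg: SignalConfig) -> FeatureSeries:
    feat = moving_rms(fold.emg, bundle.emg_fs, cfg.rms_window_s, cfg.step_s, fold.t0)
    feat = normalize_to_mvc(feat, bundle.mvc_rms)
    return kalman_smooth(feat, cfg.kalman_process_var, cfg.kalman_measurement_var)


def _population_mean(rates: dict) -> FeatureSeries:
    first = next(iter(rates.values()))
    values = np.mean([s.values for s in rates.values()], axis=0)
    return FeatureSeries(first.times.copy(), values, first.step)


def _nd_context(bundle, fold, cfg):
    """Accepted units -> smoothed rates -> population lag -> refined top 10."""
    accepted = _accepted_units(bundle, fold, cfg)
    if not accepted:
        raise ValueError("no unit passed STA validation on the training fold")
    rates = _rate_features(accepted, fold, cfg)
    lag, _ = align_by_xcorr(_population_mean(rates), fold.torque, cfg.max_lag_s)
    shifted = {uid: s.shifted(lag) for uid, s in rates.items()}
    retained = refine_units(shifted, fold.torque)
    return accepted, rates, shifted, lag, retained


def _mudrive_units(bundle, fold, cfg, accepted, rates, retained) -> list[MotorUnit]:
    by_id = {u.id: u for u in accepted}
    out = []
    for uid in retained:
        rt = compute_rt(fold.emg, bundle.emg_fs, rates[uid], bundle.mvc_rms, t0=fold.t0)
        if rt is None:
            logger.info("unit %s: no recruitment detected, excluded from MUDrive", uid)
            continue
        out.append(replace(by_id[uid], recruitment_threshold=rt))
    return out


def _mudrive_test_feature(model: DecoderModel, bundle, fold, cfg) -> FeatureSeries:
    by_id = {u.id: u for u in bundle.units}
    firings = [_fold_firings(by_id[uid], fold) for uid in model.retained_unit_ids]
    params = np.array([model.unit_twitches[uid] for uid in model.retained_unit_ids])
    raw = mudrive_signal(firings, params, fold.t1 - fold.t0, bundle.torque_fs, fold.t0)
    feat = windowed_mean(raw, bundle.torque_fs, cfg.rms_window_s, cfg.step_s, fold.t0)
    return kalman_smooth(feat, cfg.kalman_process_var, cfg.kalman_measurement_var)


def _fit_fold(bundle, fold, method, cfg, ga_config, seed, mudrive_k, sensitivity_rank):
    if method == "aEMG":
        feat = _aemg_feature(bundle, fold, cfg)
        lag, shifted = align_by_xcorr(feat, fold.torque, cfg.max_lag_s)
        return fit_aemg(shifted, fold.torque, lag=lag)
    accepted, rates, shifted, lag, retained = _nd_context(bundle, fold, cfg)
    if method == "ND":
        return fit_nd({uid: shifted[uid] for uid in retained}, fold.torque, lag=lag)
    if method == "MUDrive":
        md_units = _mudrive_units(bundle, fold, cfg, accepted, rates, retained)
        fitter = MudriveFitter(md_units, fold.torque, (fold.t0, fold.t1),
                               bundle.torque_fs, cfg)
        rank = sensitivity_rank or list(CANONICAL_PARAM_ORDER)
        k = 5 if mudrive_k is None else mudrive_k
        mask = {name: name in rank[:k] for name in rank}
        opt = ga_optimize(fitter, mask, PoolParameterBounds.midpoint(), ga_config, seed)
        return fitter.fit(opt.best_bounds)[0]
    raise ValueError(f"unknown method {method!r}")


def _eval_fold(model: DecoderModel, bundle, fold, cfg) -> float:
    if model.method == "aEMG":
        feat = _aemg_feature(bundle, fold, cfg)
        pred = predict(model, feat)
    elif model.method == "ND":
        by_id = {u.id: u for u in bundle.units}
        rates = _rate_features([by_id[uid] for uid in model.retained_unit_ids], fold, cfg)
        pred = predict(model, rates)
    elif model.method == "MUDrive":
        feat = _mudrive_test_feature(model, bundle, fold, cfg)
        pred = predict(model, feat)
    else:
        raise ValueError(model.method)
    a, b = index_align(pred, fold.torque)
    return rmse(a, b)


def fold_spans(bundle: TrialBundle, step: float = 0.1) -> list[tuple[float, float]]:
    """The two fold windows, split at the midpoint of the inter-trapezoid rest."""
    traps = bundle.trapezoids
    if len(traps) != 2:
        raise ValueError(f"two-fold CV needs exactly 2 trapezoids, got {len(traps)}")
    split = round(((traps[0][1] + traps[1][0]) / 2.0) / step) * step
    return [(0.0, split), (split, bundle.duration)]


def two_fold_cv(
    bundle: TrialBundle,
    method: str,
    config: SignalConfig | None = None,
    seed: int = 0,
    ga_config: GAConfig | None = None,
    mudrive_k: int | None = None,
    sensitivity_rank: list[str] | None = None,
    subject: str = "s0",
) -> EvaluationResult:
    """Train on each trapezoid, test on the other; report both fold RMSEs."""
    cfg = config or SignalConfig()
    spans = fold_spans(bundle, cfg.step_s)
    folds = [_prepare_fold(bundle, span, cfg) for span in spans]
    out = []
    for i, (train, test) in enumerate([(0, 1), (1, 0)]):
        fold_seed = int(np.random.SeedSequence((seed, i)).generate_state(1)[0] % 2**31)
        model = _fit_fold(bundle, folds[train], method, cfg, ga_config,
                          fold_seed, mudrive_k, sensitivity_rank)
        out.append(_eval_fold(model, bundle, folds[test], cfg))
    return EvaluationResult(
        method=method, subject=subject, muscle=bundle.muscle,
        target_mvc=bundle.target_mvc, fold_rmse=(out[0], out[1]),
        mean_rmse=float(np.mean(out)),
    )


def make_mudrive_fitter(
    bundle: TrialBundle,
    config: SignalConfig | None = None,
    train_fold: int = 0,
) -> MudriveFitter:
    """Training-fold MUDrive fitter via the standard pipeline (validation,
    refinement, recruitment thresholds)."""
    cfg = config or SignalConfig()
    fold = _prepare_fold(bundle, fold_spans(bundle, cfg.step_s)[train_fold], cfg)
    accepted, rates, shifted, lag, retained = _nd_context(bundle, fold, cfg)
    md_units = _mudrive_units(bundle, fold, cfg, accepted, rates, retained)
    return MudriveFitter(md_units, fold.torque, (fold.t0, fold.t1), bundle.torque_fs, cfg)


def mudrive_rmse_fn(
    bundle: TrialBundle,
    config: SignalConfig | None = None,
    use_test_fold: bool = True,
    units: list[MotorUnit] | None = None,
    fitted_at: PoolParameterBounds | None = None,
) -> Callable[[PoolParameterBounds], float]:
    """Closure mapping pool bounds -> MUDrive RMSE for one trial.

    Intended for the Monte-Carlo sensitivity loop: all fold preparation is
    done once so each evaluation is cheap.  ``units`` overrides the
    pipeline's refined units (used for constructed degenerate pools).

    When ``fitted_at`` is given, the regression (slope, intercept, lag) is
    fitted *once* at those bounds and then frozen; each closure call only
    perturbs the twitch parameters inside the otherwise-unchanged model, as
    in a one-at-a-time perturbation of an already-trained decoder.  Without
    it, the regression is refit for every candidate (the optimization cost).
    """
    cfg = config or SignalConfig()
    spans = fold_spans(bundle, cfg.step_s)
    train = _prepare_fold(bundle, spans[0], cfg)
    if units is None:
        accepted, rates, shifted, lag, retained = _nd_context(bundle, train, cfg)
        units = _mudrive_units(bundle, train, cfg, accepted, rates, retained)
    fitter = MudriveFitter(units, train.torque, (train.t0, train.t1), bundle.torque_fs, cfg)
    eval_fold = _prepare_fold(bundle, spans[1], cfg) if use_test_fold else train
    # whole-trial firing times (the pipeline units carry train-fold slices)
    by_id = {u.id: u for u in bundle.units}
    by_id.update({u.id: u for u in units if u.id not in by_id})
    eval_firings = [
        by_id[uid].firings[
            (by_id[uid].firings >= eval_fold.t0) & (by_id[uid].firings < eval_fold.t1)
        ]
        for uid in fitter.ids
    ]

    def _feature_on_eval_fold(bounds: PoolParameterBounds) -> FeatureSeries:
        from .decoders import rescale_twitch_params

        params = rescale_twitch_params(fitter.rts, bounds)
        raw = mudrive_signal(eval_firings, params, eval_fold.t1 - eval_fold.t0,
                             bundle.torque_fs, eval_fold.t0)
        feat = windowed_mean(raw, bundle.torque_fs, cfg.rms_window_s, cfg.step_s,
                             eval_fold.t0)
        return kalman_smooth(feat, cfg.kalman_process_var, cfg.kalman_measurement_var)

    if fitted_at is not None:
        # one-at-a-time perturbation of the trained model: the alignment lag
        # stays frozen at its trained value (alignment happens once per
        # trial), while the regression scale is refit per candidate so pure
        # amplitude changes are absorbed, exactly as in training
        base_model, _ = fitter.fit(fitted_at)
        from .decoders import _ols_simple

        def fn(bounds: PoolParameterBounds) -> float:
            bounds.validate()
            train_feat = fitter.feature(bounds).shifted(base_model.lag)
            a, b = index_align(train_feat, train.torque)
            slope, intercept = _ols_simple(a.values, b.values)
            feat = _feature_on_eval_fold(bounds).shifted(base_model.lag)
            a, b = index_align(feat, eval_fold.torque)
            pred = FeatureSeries(a.times, a.values * slope + intercept)
            return rmse(pred, b)

        return fn

    if not use_test_fold:
        return lambda bounds: fitter.fit(bounds)[1]

    def fn(bounds: PoolParameterBounds) -> float:
        model, _ = fitter.fit(bounds)
        return _eval_fold(model, bundle, eval_fold, cfg)

    return fn


# ---------------------------------------------------------------------------
# paired statistics
# ---------------------------------------------------------------------------

def paired_posthoc(per_subject: pd.DataFrame, methods=METHODS) -> list[PairwiseComparison]:
    """Paired t-tests over method pairs with Bonferroni correction.

    ``per_subject`` has one row per subject and one column per method (mean
    RMSE).  Cohen's d for paired data is mean(diff) / SD(diff).
    """
    if len(per_subject) < 3:
        raise ValueError("paired post-hoc tests need at least 3 subjects")
    for m in methods:
        if m not in per_subject.columns or per_subject[m].isna().any():
            missing = per_subject.index[per_subject.get(m, pd.Series(np.nan, per_subject.index)).isna()]
            raise ValueError(f"missing RMSE for method {m!r} (subjects {list(missing)})")
    pairs = [(methods[0], methods[1]), (methods[0], methods[2]), (methods[1], methods[2])]
    n_comparisons = len(pairs)
    out = []
    for a, b in pairs:
        diff = (per_subject[a] - per_subject[b]).to_numpy(dtype=float)
        sd = diff.std(ddof=1)
        scale = max(float(np.abs(diff).max()), 1e-300)
        if sd <= 1e-12 * scale:  # all paired differences equal (to float precision)
            degenerate = True
            if np.allclose(diff, 0.0):
                t, p = 0.0, 1.0
            else:
                t, p = np.inf * np.sign(diff.mean()), 0.0
            d = 0.0 if np.allclose(diff, 0.0) else np.inf * np.sign(diff.mean())
        else:
            degenerate = False
            t, p = _stats.ttest_rel(per_subject[a], per_subject[b])
            d = float(diff.mean() / sd)
        out.append(PairwiseComparison(
            (a, b), float(t), float(p), float(min(1.0, p * n_comparisons)), float(d), degenerate
        ))
    return out


# ---------------------------------------------------------------------------
# cohort orchestration
# ---------------------------------------------------------------------------

def _default_cohort_ga() -> GAConfig:
    # cohort-scale GA (smaller than the single-trial default, for tractability)
    return GAConfig(population=15, generations=20)


@dataclass
class CohortConfig:
    n_subjects: int = 8
    target_levels: tuple[float, ...] = (20.0, 35.0)
    n_units_range: tuple[int, int] = (12, 22)
    base_pool: PoolConfig = field(default_factory=PoolConfig)
    methods: tuple[str, ...] = METHODS
    mudrive_k: int | None = None        # None = optimize all five parameters
    ga: GAConfig = field(default_factory=_default_cohort_ga)
    signal: SignalConfig = field(default_factory=SignalConfig)


def run_cohort(config: CohortConfig, seed: int = 0) -> tuple[CohortReport, pd.DataFrame]:
    """Simulate a cohort of virtual subjects and evaluate every decoder.

    Each subject is an independent pool realization (n_units drawn from
    ``n_units_range``); each performs one two-trapezoid trial per target
    level; every method goes through two-fold CV.  Returns the report and the
    long-format per-fold results table.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 900)))
    rows = []
    warnings: list[str] = []
    for s in range(config.n_subjects):
        subject = f"s{s}"
        pool_seed = int(np.random.SeedSequence((seed, 901, s)).generate_state(1)[0] % 2**31)
        n_units = int(rng.integers(config.n_units_range[0], config.n_units_range[1] + 1))
        pool_cfg = replace(config.base_pool, n_units=n_units, seed=pool_seed)
        for li, level in enumerate(config.target_levels):
            trial_seed = int(
                np.random.SeedSequence((seed, 902, s, li)).generate_state(1)[0] % 2**31
            )
            bundle = generate_trial_bundle(pool_cfg, level, n_trapezoids=2,
                                           trial_seed=trial_seed)
            for method in config.methods:
                res = two_fold_cv(
                    bundle, method, config.signal, seed=trial_seed,
                    ga_config=config.ga, mudrive_k=config.mudrive_k,
                    subject=subject,
                )
                for fold, value in enumerate(res.fold_rmse):
                    rows.append({
                        "subject": subject, "muscle": bundle.muscle, "method": method,
                        "level": level, "fold": fold, "rmse": value,
                    })
    df = pd.DataFrame(rows)
    desc = (
        df.groupby(["method", "level"])["rmse"]
        .agg(mean="mean", se=lambda v: v.std(ddof=1) / np.sqrt(len(v)))
        .reset_index()
    )
    comparisons: list[PairwiseComparison] = []
    if config.n_subjects >= 3 and set(config.methods) >= set(METHODS):
        per_subject = df.pivot_table(index="subject", columns="method", values="rmse")
        comparisons = paired_posthoc(per_subject)
    else:
        warnings.append("statistics suppressed: need >= 3 subjects and all three methods")
        logger.warning(warnings[-1])
    report = CohortReport(desc, comparisons, config.n_subjects, warnings)
    return report, df


def write_cohort_report(report: CohortReport, df: pd.DataFrame, outdir) -> None:
    """Write report.tsv (long format), stats.json and a plain-text log.

    Output is deterministic (no timestamps), so identical configurations and
    seeds produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df.to_csv(outdir / "report.tsv", sep="\t", index=False, float_format="%.10g")
    stats = {
        "n_subjects": report.n_subjects,
        "descriptives": report.descriptives.to_dict(orient="records"),
        "comparisons": [
            {
                "pair": list(c.pair), "t": c.t, "p": c.p,
                "p_adjusted": c.p_adjusted, "cohen_d": c.cohen_d,
                "degenerate": c.degenerate,
            }
            for c in report.comparisons
        ],
        "warnings": report.warnings,
    }
    (outdir / "stats.json").write_text(json.dumps(stats, indent=1, sort_keys=True))
    lines = [f"subjects: {report.n_subjects}"]
    for c in report.comparisons:
        lines.append(
            f"{c.pair[0]} vs {c.pair[1]}: t={c.t:.4g} p_adj={c.p_adjusted:.4g} d={c.cohen_d:.4g}"
        )
    lines.extend(report.warnings)
    (outdir / "run.log").write_text("\n".join(lines) + "\n")
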