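# Methods

## Signals and features

All decoders operate on a common 10 Hz feature grid of *window centers*
(0.5 s windows, 0.1 s step, half-open `[c - w/2, c + w/2)`). Windows are
defined in time rather than sample counts because the EMG rate (2222 Hz)
does not divide the step evenly; this keeps every feature of a trial
index-aligned regardless of its source sampling rate. Centered (not
trailing) windows are used throughout.

The torque reference is DC-corrected (mean of the first second), low-pass
filtered at 2 Hz (4th-order Butterworth) and reduced by a windowed mean. EMG
is band-passed 20–450 Hz (4th-order Butterworth) and enveloped by a windowed
RMS normalized to the MVC reference (largest sliding 0.5 s RMS window of a
maximal contraction). Firing rates are windowed spike counts divided by the
window length. All filters run zero-phase (forward–backward), so the
electromechanical delay is absorbed explicitly by a cross-correlation
alignment on the feature grid (±1 s search, ties toward zero lag) rather
than implicitly by filter group delay.

Features are smoothed by a scalar random-walk Kalman filter. Its noise
variances default to equal fractions (1e-1) of the series variance, which
puts the steady-state one-pole cutoff near 1.5 Hz — deliberately matched to
the 2 Hz bandwidth of the conditioned torque reference. This matters more
than it looks: a much heavier smoother (e.g. process/measurement variance
ratio 0.01) distorts the model feature relative to the reference it is
regressed against, and we found it biases the genetic-algorithm twitch
parameter estimates all the way to the constraint-box edge even on
noise-free data where the model family contains the truth. With the matched
default, the noise-free training cost is unimodal at the generator's true
parameter value. The variance scaling also makes smoothing commute with
unit changes.

The MUDrive force signal is reduced by the windowed *mean*, like the torque
reference, not the RMS: for a strictly nonnegative signal the RMS adds a
`var/(2·mean)` convexity bias wherever the twitch ripple is strong, which is
a systematic shape error against a mean-windowed reference. The RMS window
is reserved for the zero-mean EMG, where "amplitude" genuinely means RMS.

## Unit validation

Each decomposed unit is screened by spike-triggered averaging: the 80 ms STA
of the filtered EMG must correlate with the decomposed MUAP template
(squared peak normalized cross-correlation R² > 0.6, alignment by the
correlation-maximizing shift), and the unit must be stable over time
(coefficient of variation of per-segment STA peak-to-peak amplitudes below
0.5, 8 s segments stepped by 4 s). Segments contribute only if they contain
at least 4 usable firings — a CV over one-spike "averages" is meaningless —
and units with fewer than two usable segments are rejected outright.
Firings whose window would run off the trace are skipped, not zero-padded.
Both gates are invariant to a global EMG gain.

## Decoders

**aEMG** is a simple OLS of torque on the smoothed %MVC envelope. **ND**
first ranks accepted units by the R² of their smoothed rate against torque,
keeps the top 10 (all, if fewer), and fits a multiple OLS; exactly collinear
rates fall back to a tiny ridge penalty (1e-8) so degenerate inputs stay
defined. A single alignment lag per method and fold is estimated from the
aggregate feature (population-mean rate for ND) and applied to all
regressors — physically there is one electromechanical delay, not one per
unit.

**MUDrive** assigns each retained unit a twitch by linearly rescaling the
pool bounds with its recruitment threshold (RT): with
`r_i = (RT_i − min RT)/(max RT − min RT)`, every parameter interpolates its
bound pair, so higher-threshold units get larger, slower twitches. RT is
estimated as the EMG RMS (as %MVC) in a 200 ms window centered at the first
time the unit's smoothed rate exceeds 5 Hz. The twitch waveform is a
critically-damped-style rise `P·(t/Tr)·exp(1 − t/Tr)` peaking at exactly P
at t = Tr, spliced to an exponential decay `P·2^(−(t−Tr)/Thr)` so the
half-relaxation time is exactly Thr; the tail is truncated below 1e-4·P.
Downstream code relies only on the contract {f(0)=0, max = P at Tr,
f(Tr+Thr) = P/2}, so any waveform honoring it is interchangeable. Spike
gains follow the sigmoidal fusion model `g = [S(x)/x]/[S(0.4)/0.4]` with
`S(x) = 1 − exp(−2x³)`, `x = Tr/ISI`, g = 1 below the knee and for the first
spike of a train. Spikes are placed on the 100 Hz force grid by
nearest-sample rounding (≤5 ms quantization against 30–240 ms twitch time
constants); the vectorized convolution engine is verified against an
independent per-spike loop at 1e-9 relative tolerance.

## Optimization

The five pool parameters are searched by a real-coded genetic algorithm
inside the physiologic box (P_max ∈ [1.1, 150], Tr_min ∈ [30, 110] ms,
Tr_max ∈ [150, 240] ms, Thr_min ∈ [15, 60] ms, Thr_max ∈ [110, 140] ms):
tournament selection (size 3), blend crossover (α = 0.5, probability 0.7),
Gaussian mutation (per-gene probability 0.25, SD 10 % of the box range),
elitism of one, early stop after 10 stagnant generations (1e-6). The cost of
a candidate is the *training* RMSE with the regression refit, so the cost is
well-defined; the box midpoint is always injected into generation 0, which
makes the optimized result provably no worse than the no-optimization
baseline. Defaults are 30×40 (population × generations) for single trials
and 15×20 inside cohort evaluations, where the GA runs once per training
fold; the refinement sweep (k = 0..5 optimized parameters, the rest pinned
at box midpoints) warm-starts each k with the k−1 optimum — which lies
inside the k search space — so its best cost is nonincreasing in k by
construction.

## Sensitivity analysis

One parameter at a time is redrawn uniformly over its constraint-box range
while the other four stay at their optimized values; the perturbed decoder's
held-out RMSE is recorded. The perturbation evaluates the *trained* model:
the alignment lag stays frozen at its trained value (alignment happens once
per trial), while the regression scale is refit per draw exactly as during
training, so pure amplitude changes are absorbed and shape/timing changes
are not. Iterations continue until the running SD of RMSE (over all
iterations so far, sample SD) changes by less than 1e-4 Nm across 50
iterations, with a 1000-iteration minimum and a 20 000 cap; infeasible draws
are rejected without counting. Parameters are ranked by converged SD, ties
broken by a fixed canonical order.

Two model properties shape what this analysis can show. Rise time has a
*nonlinear* channel into the summed force — it drives the rate-dependent
gain — so `Tr_min`, which moves the rise time of the bulk of a
low-threshold-skewed pool, is reliably the most sensitive parameter.
Half-relaxation time has no such channel in this gain model: it enters only
through twitch area and centroid timing, both largely absorbed by the scale
refit and the 2 Hz reference bandwidth, so `Thr_min` does *not* reliably
outrank `Tr_max` here (see Limitations).

## Synthetic study conditions

The generator emulates trapezoid tracking trials: 5 s quiescence, ramps at
10 %MVC/s, 12 s holds at 20 or 35 %MVC, 10 s rest between the two
trapezoids. The defaults, chosen once as the study conditions:

* **Pool**: 16 decomposed units atop 100 undetected background units, one
  exponential recruitment ladder spanning 1–30 %MVC
  (`RT_i = rt_min · range^(((i−1)/(n−1))^shape)`, shape 1 by default;
  shape > 1 clusters thresholds low). Ground-truth twitches come from the
  same rescaling rule the decoder uses, applied to generator bounds
  (P_max 60, Tr 50–180 ms, Thr 30–125 ms) over the combined ladder.
* **Rate coding**: 8 Hz at recruitment, +1 Hz per %MVC above threshold,
  35 Hz cap, ISI CV 0.15 (Gaussian jitter, 2 ms floor), and 2 %MVC
  derecruitment hysteresis — near-threshold units fire steadily at their
  minimum rate instead of flickering with drive fluctuations.
* **Common drive**: the pool tracks the target with a band-limited
  multiplicative wobble (5 % of the target level), the signal-dependent
  tracking error of a human subject.
* **EMG**: MUAPs are zero-mean biphasic Gaussian-derivative waveforms
  (15 ms), amplitude ∝ RT^0.6 times a lognormal per-unit surface visibility
  (σ = 0.6, electrode depth); the *decomposed* subset is the 16 most visible
  units with ≥ 30 discharges — surface decomposition finds the units that
  stand out, not a uniform sample. White noise at 15 dB SNR plus a slow 5 %
  multiplicative amplitude drift (electrode nonstationarity, invisible to
  spike-based decoders). Observed firing times carry decomposition errors:
  8 % missed and 5 % spurious discharges (EMG and torque are always built
  from the true spikes of the whole pool).
* **Torque**: twitch superposition scaled to a dynamometer-like range
  (35 %MVC plateau ≈ 38 Nm), 0.2 Nm white sensor noise, and a slow 5 %
  per-unit twitch-gain drift (potentiation/fatigue-like) that no decoder can
  explain from the EMG side — the mechanism that makes tracking error grow
  with the target level for every method.

Pool size rationale: decomposed counts of 12–22 units (cohort draw) sit in
the empirically observed range; with the fixed top-10 retention rule, much
larger decomposed sets leave most of the *decomposed* force unmodeled, a
regime in which the single-slope MUDrive map is structurally handicapped
against the free-coefficient ND regression while real data is not.
The background pool restores the realistic regime in which no decoder can
invert the torque-generating pool and no single unmodeled unit is
individually visible in torque.

What the generator does **not** emulate: volume-conductor physics and
electrode geometry, MU synchronization, fatigue beyond slow gain drift,
crosstalk from synergist muscles, antagonist co-contraction, and real
decomposition failure modes beyond random miss/insert errors. Passing tests
therefore show that the pipelines are correct and that the decoder ordering
follows from the modeled mechanisms (cancellation, EMG drift, decomposition
noise, twitch dynamics) — not that the same margins would be observed on any
particular human dataset.

## Evaluation

Two-fold cross-validation splits each two-trapezoid trial at the midpoint of
the inter-trapezoid rest. Everything — validation, retention, recruitment
thresholds, alignment lag, GA bounds, regression — is estimated on the
training fold alone (validation runs on training-fold EMG precisely so that
zeroing the test fold provably cannot change the fitted model) and frozen
for prediction on the held-out fold; fold RMSEs are averaged. Virtual
cohorts draw independent subjects (pool seed and size), evaluate all
decoders at both target levels, and compare per-subject mean RMSEs with
paired t-tests (Bonferroni ×3) and Cohen's d on paired differences
(mean/SD); a zero-SD difference column is flagged degenerate and reported as
p = 0. Statistics are suppressed with a warning below 3 subjects.

Problem sizes in the shipped tests and acceptance script (8-subject
cohorts, 15×20 cohort GA, 3000-iteration sensitivity caps, 10×12 refinement
sweeps) were chosen so a full run completes in minutes on one CPU while
leaving the qualitative outcomes far from their decision thresholds.

## Numerical choices and edge cases

Grid times are matched through integer lattice keys (0.05 s quantum) so
index alignment is exact under float arithmetic. Lag search ties break
toward the smallest |lag|; an all-zero feature gets lag 0. A single-unit (or
all-equal-RT) pool rescales to r = 0, i.e. the minimum twitch parameters —
a documented degenerate case, not an error. Units whose rate never crosses
5 Hz are excluded from MUDrive with a logged reason. Infeasible bound
combinations cost +inf inside the GA and are redrawn in the sensitivity
loop. Serialized outputs (bundles, models, reports) contain no wall-clock
state; optimization wall time is kept in memory but deliberately excluded
from files so reruns are byte-identical.

## Known limitations

* The twitch functional form and the Kalman design are contract-backed
  substitutions; only {onset, peak, half-relaxation} and the smoothing
  bandwidth are load-bearing.
* Recruitment-threshold estimates inherit the concavity of the EMG
  amplitude–drive relation, compressing the upper threshold range; the
  min–max rescaling preserves ranks but not spacing.
* Under this gain model the half-relaxation minimum lacks a nonlinear
  channel, so the sensitivity ranking reproduces the primacy of `Tr_min`
  robustly but not a strict ordering of `Thr_min` above `Tr_max`.
* Absolute optimization wall times are hardware-dependent; only relative
  timing trends across k are meaningful.
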