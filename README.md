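# mutorque

Motor-unit-based decoding of isometric ankle torque from surface EMG.

Proportional myoelectric control of powered ankle prostheses conventionally
drives the joint with the *amplitude* of the surface EMG (aEMG): the RMS
envelope, normalized to maximum voluntary contraction (MVC), regressed onto
joint torque. EMG amplitude is a lossy readout of the neural command —
overlapping motor unit action potentials (MUAPs) cancel, electrodes drift,
and the amplitude-to-force map is nonlinear. Modern EMG decomposition
recovers individual motor unit (MU) spike trains, which opens two
alternatives:

* **ND (neural drive)** — regress torque on the smoothed firing rates
  FR_i(t) of the best decomposed units:

      tau(t) = sum_i a_i FR_i(t) + b

* **MUDrive** — convolve each unit's spike train with a modeled force
  twitch and sum across the pool. A twitch is parameterized by peak force P,
  rise time Tr, and half-relaxation time Thr; each spike is scaled by a
  rate-dependent gain g(Tr/ISI) so summation saturates physiologically.
  Per-unit parameters are a linear rescaling — by recruitment threshold,
  following the size principle — of five pool-level bounds
  (P_max, Tr_min, Tr_max, Thr_min, Thr_max; P_min fixed at 1) which a
  genetic algorithm fits inside physiologic ranges. The summed, smoothed
  signal is regressed onto torque.

The package implements all three decoders as fit/predict pipelines with
two-fold cross-validation over trapezoid tracking trials (10 %MVC/s ramps,
12 s holds at 20 or 35 %MVC), spike-triggered-averaging validation of
decomposed units, Monte-Carlo one-at-a-time sensitivity analysis of the five
pool parameters, warm-started optimization refinement (optimizing only the
k most sensitive parameters), and paired cohort statistics. Because suitable
human recordings are not publicly available, it ships a first-class
synthetic generator: a recruitment-ordered MU pool with rate coding, ISI
jitter, common-drive tracking error, an undetected background pool,
decomposition discharge errors, EMG formed by MUAP superposition (so
amplitude cancellation occurs), and torque formed by twitch superposition
with ground-truth parameters — so every stage can be tested against known
truth.

## Worked example

```python
from mutorque import PoolConfig, generate_trial_bundle, two_fold_cv, GAConfig

bundle = generate_trial_bundle(PoolConfig(seed=7), target_mvc=20.0)
print(f"trial: {bundle.duration:.0f} s, {len(bundle.units)} decomposed units")
for method in ("aEMG", "ND", "MUDrive"):
    res = two_fold_cv(bundle, method, seed=1,
                      ga_config=GAConfig(population=15, generations=20))
    print(f"{method:>8}: fold RMSEs = {res.fold_rmse[0]:.3f} / "
          f"{res.fold_rmse[1]:.3f} Nm, mean = {res.mean_rmse:.3f} Nm")
```

prints

```
trial: 52 s, 16 decomposed units
    aEMG: fold RMSEs = 1.913 / 1.707 Nm, mean = 1.810 Nm
      ND: fold RMSEs = 1.075 / 1.034 Nm, mean = 1.054 Nm
 MUDrive: fold RMSEs = 0.876 / 0.846 Nm, mean = 0.861 Nm
```

One simulated 20 %MVC trial (two trapezoids, plateau torque ~25 Nm): each
decoder is trained on one trapezoid and scored on the other, and the fold
RMSEs are averaged. The twitch-convolution decoder tracks torque about twice
as accurately as the EMG envelope here, with the rate-based decoder in
between — the ordering the cohort-level statistics test systematically.

A full virtual cohort (8 subjects x 2 target levels x 3 decoders, paired
t-tests with Bonferroni correction):

```python
from mutorque import CohortConfig, run_cohort
report, table = run_cohort(CohortConfig(), seed=1)
```

## Command line

`mutorque simulate | validate | fit | optimize | sensitivity | evaluate` —
thin wrappers over the library that read/write plain-text trial bundles
(JSON manifest + TSV arrays) and deterministic JSON/TSV reports. Re-running
any command with the same configuration and seed reproduces its outputs byte
for byte.

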