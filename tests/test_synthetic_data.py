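import numpy as np
import pytest
from dataclasses import replace

from mutorque.decoders import twitch_waveform
from mutorque.synthetic_data import (
    PoolConfig,
    build_trapezoid_profile,
    bundles_equal,
    generate_full_pool,
    generate_pool,
    generate_trial_bundle,
    read_trial_bundle,
    simulate_spike_trains,
    synthesize_emg,
    synthesize_torque,
    write_trial_bundle,
)
from mutorque.mu_validation import MotorUnit
from mutorque.synthetic_data import ExcitationProfile, TrialBundle


class TestTrapezoidProfile:
    def test_single_trapezoid_timing(self):
        p = build_trapezoid_profile(20.0, 1, 10.0)
        spans = p.trapezoid_spans()
        assert len(spans) == 1
        start, end = spans[0]
        assert start == pytest.approx(5.0)          # 5 s quiescent lead-in
        assert end - start == pytest.approx(16.0)   # 2 s + 12 s + 2 s
        assert p.value_at(start + 2.0 + 6.0) == pytest.approx(20.0)

    def test_two_trapezoids_rest_gap(self):
        p = build_trapezoid_profile(35.0, 2, 10.0)
        (s1, e1), (s2, e2) = p.trapezoid_spans()
        assert s2 - e1 == pytest.approx(10.0)
        assert e1 - s1 == pytest.approx(12.0 + 2 * 3.5)

    def test_infinite_ramp_limit_is_rectangle(self):
        p = build_trapezoid_profile(20.0, 1, 1e9)
        (s, e) = p.trapezoid_spans()[0]
        assert e - s == pytest.approx(12.0, abs=1e-6)
        assert p.value_at((s + e) / 2) == pytest.approx(20.0)

    @pytest.mark.parametrize("target,rate", [(-5.0, 10.0), (20.0, 0.0)])
    def test_invalid_configuration(self, target, rate):
        with pytest.raises(ValueError):
            build_trapezoid_profile(target, 1, rate)


class TestPoolGeneration:
    def test_geometric_threshold_ladder(self):
        cfg = PoolConfig(n_units=3, rt_min=2.0, recruitment_range=16.0, seed=0)
        pool = generate_pool(cfg)
        np.testing.assert_allclose(
            [u.recruitment_threshold for u in pool], [2.0, 8.0, 32.0]
        )

    def test_lowest_unit_gets_minimum_twitch(self):
        cfg = PoolConfig(n_units=8, seed=1)
        pool = generate_pool(cfg)
        tb = cfg.true_bounds
        assert pool[0].truth_twitch == pytest.approx((tb.p_min, tb.tr_min, tb.thr_min))
        assert pool[-1].truth_twitch == pytest.approx((tb.p_max, tb.tr_max, tb.thr_max))

    def test_muap_amplitude_monotone_in_rt(self):
        pool = generate_pool(PoolConfig(n_units=12, seed=4))
        p2p = [np.ptp(u.muap_template) for u in pool]
        assert np.all(np.diff(p2p) >= -1e-12)

    def test_templates_are_zero_mean_biphasic(self):
        pool = generate_pool(PoolConfig(n_units=5, seed=2))
        for u in pool:
            assert abs(u.muap_template.mean()) < 1e-12 * np.ptp(u.muap_template)
            assert u.muap_template.min() < 0 < u.muap_template.max()

    def test_single_unit_pool(self):
        pool = generate_pool(PoolConfig(n_units=1, rt_min=3.0, seed=0))
        assert pool[0].recruitment_threshold == 3.0


class TestSpikeTrains:
    def test_zero_excitation_no_firing(self):
        cfg = PoolConfig(n_units=3, seed=0)
        prof = ExcitationProfile(
            np.array([0.0, 10.0]), np.array([0.0, 0.0]), ["rest"]
        )
        pool = simulate_spike_trains(generate_pool(cfg), prof, cfg)
        assert all(u.firings.size == 0 for u in pool)

    def test_deterministic_isis_without_jitter(self):
        cfg = PoolConfig(n_units=1, rt_min=5.0, isi_cv=0.0, min_rate=8.0,
                         rate_gain=1.0, peak_rate=35.0, seed=0)
        prof = ExcitationProfile(
            np.array([0.0, 20.0]), np.array([15.0, 15.0]), ["hold"]
        )
        pool = simulate_spike_trains(generate_pool(cfg), prof, cfg)
        isis = np.diff(pool[0].firings)
        expect = 1.0 / (8.0 + 1.0 * (15.0 - 5.0))
        np.testing.assert_allclose(isis, expect, rtol=1e-9)

    def test_rate_cap_respected(self):
        cfg = PoolConfig(n_units=1, rt_min=1.0, isi_cv=0.0, min_rate=8.0,
                         rate_gain=5.0, peak_rate=20.0, seed=0)
        prof = ExcitationProfile(
            np.array([0.0, 10.0]), np.array([30.0, 30.0]), ["hold"]
        )
        pool = simulate_spike_trains(generate_pool(cfg), prof, cfg)
        np.testing.assert_allclose(np.diff(pool[0].firings), 1.0 / 20.0, rtol=1e-9)

    def test_hold_rate_matches_model(self):
        """Spike count over the 12 s hold vs the closed-form recruitment model."""
        cfg = PoolConfig(seed=5, n_background=0, drive_fluctuation_cv=0.0)
        prof = build_trapezoid_profile(20.0, 1, 10.0)
        pool = simulate_spike_trains(generate_pool(cfg), prof, cfg)
        u = pool[0]
        expect = min(
            cfg.peak_rate,
            cfg.min_rate + cfg.rate_gain * (20.0 - u.recruitment_threshold),
        )
        hold = u.firings[(u.firings >= 7.0) & (u.firings < 19.0)]
        assert len(hold) / 12.0 == pytest.approx(expect, rel=0.05)

    def test_recruitment_ordered_by_threshold(self):
        cfg = PoolConfig(n_units=10, seed=3, isi_cv=0.0)
        prof = build_trapezoid_profile(35.0, 1, 10.0)
        pool = simulate_spike_trains(generate_pool(cfg), prof, cfg)
        onsets = [u.firings[0] for u in pool if u.firings.size]
        assert np.all(np.diff(onsets) > 0)

    def test_seed_determinism(self):
        cfg = PoolConfig(seed=9)
        prof = build_trapezoid_profile(20.0, 1)
        a = simulate_spike_trains(generate_pool(cfg), prof, cfg)
        b = simulate_spike_trains(generate_pool(cfg), prof, cfg)
        for ua, ub in zip(a, b):
            np.testing.assert_array_equal(ua.firings, ub.firings)


class TestEmgSynthesis:
    def _unit(self, firings, template):
        return MotorUnit(id=0, firings=np.asarray(firings, float),
                         muap_template=np.asarray(template, float))

    def test_single_firing_places_template(self):
        cfg = PoolConfig(seed=0, emg_fs=1000.0)
        tpl = np.array([0.0, 1.0, -1.0, 0.0])
        u = self._unit([0.5], tpl)
        out = synthesize_emg([u], cfg, 1.0, noise=False)
        i0 = 500 - len(tpl) // 2
        np.testing.assert_allclose(out[i0 : i0 + 4], tpl)
        assert np.count_nonzero(out) == 2

    def test_destructive_interference_sums_pointwise(self):
        cfg = PoolConfig(seed=0, emg_fs=1000.0)
        tpl = np.array([0.0, 1.0, -1.0, 0.0])
        a = self._unit([0.5], tpl)
        b = MotorUnit(id=1, firings=np.array([0.5]), muap_template=-tpl)
        out = synthesize_emg([a, b], cfg, 1.0, noise=False)
        np.testing.assert_allclose(out, 0.0, atol=1e-15)

    def test_snr_within_one_db(self):
        cfg = PoolConfig(seed=12, emg_snr_db=20.0, emg_gain_drift_cv=0.0)
        prof = build_trapezoid_profile(20.0, 1)
        pool = simulate_spike_trains(generate_full_pool(cfg), prof, cfg)
        clean = synthesize_emg(pool, cfg, prof.duration, prof, noise=False)
        noisy = synthesize_emg(pool, cfg, prof.duration, prof)
        t = np.arange(len(clean)) / cfg.emg_fs
        active = prof.value_at(t) > 0
        p_sig = np.mean(clean[active] ** 2)
        p_noise = np.mean((noisy - clean) ** 2)
        snr = 10 * np.log10(p_sig / p_noise)
        assert snr == pytest.approx(20.0, abs=1.0)

    def test_cancellation_bounds_summed_rms(self):
        """RMS of the superposition never exceeds the sum of unit RMS values."""
        cfg = PoolConfig(seed=6, n_units=6, n_background=0)
        prof = build_trapezoid_profile(20.0, 1)
        pool = simulate_spike_trains(generate_pool(cfg), prof, cfg)
        total = synthesize_emg(pool, cfg, prof.duration, noise=False)
        rms_sum = sum(
            np.sqrt(np.mean(synthesize_emg([u], cfg, prof.duration, noise=False) ** 2))
            for u in pool
        )
        assert np.sqrt(np.mean(total**2)) <= rms_sum + 1e-12


class TestTorqueSynthesis:
    def test_no_firings_is_pure_noise(self):
        cfg = PoolConfig(n_units=2, n_background=0, seed=0, torque_noise_sd=0.3)
        pool = generate_pool(cfg)
        out = synthesize_torque(pool, cfg, 5.0)
        assert abs(out.mean()) < 0.1
        assert out.std() == pytest.approx(0.3, rel=0.15)

    def test_single_spike_gives_scaled_twitch(self):
        cfg = PoolConfig(n_units=1, n_background=0, seed=0, torque_noise_sd=0.0,
                         twitch_gain_cv=0.0)
        pool = generate_pool(cfg)
        u = replace(pool[0], firings=np.array([1.0]))
        out = synthesize_torque([u], cfg, 4.0, noise=False)
        p, tr, thr = u.truth_twitch
        w = cfg.torque_scale * twitch_waveform(p, tr, thr, cfg.torque_fs)
        i0 = 100
        np.testing.assert_allclose(out[i0 : i0 + len(w)], w, atol=1e-12)

    def test_matches_brute_force_oracle(self):
        """Full pool vs an independently coded loop over every spike."""
        cfg = PoolConfig(n_units=6, n_background=0, seed=8, torque_noise_sd=0.0,
                         twitch_gain_cv=0.0)
        prof = build_trapezoid_profile(20.0, 1)
        pool = simulate_spike_trains(generate_pool(cfg), prof, cfg)
        out = synthesize_torque(pool, cfg, prof.duration, noise=False)
        from mutorque.decoders import spike_gain, twitch_waveform as tw

        oracle = np.zeros_like(out)
        for u in pool:
            p, tr, thr = u.truth_twitch
            w = cfg.torque_scale * tw(p, tr, thr, cfg.torque_fs)
            for k, t in enumerate(u.firings):
                g = 1.0 if k == 0 else spike_gain(tr, t - u.firings[k - 1])
                i0 = int(round(t * cfg.torque_fs))
                seg = w[: len(oracle) - i0]
                oracle[i0 : i0 + len(seg)] += g * seg
        np.testing.assert_allclose(out, oracle, atol=1e-9 * np.abs(oracle).max())


class TestBundleIO:
    def test_round_trip_identity(self, tmp_path):
        bundle = generate_trial_bundle(PoolConfig(seed=2, n_units=4, n_background=10), 20.0)
        write_trial_bundle(bundle, tmp_path / "b")
        back = read_trial_bundle(tmp_path / "b")
        assert bundles_equal(bundle, back)

    def test_missing_torque_file_named_in_error(self, tmp_path):
        bundle = generate_trial_bundle(PoolConfig(seed=2, n_units=4, n_background=10), 20.0)
        write_trial_bundle(bundle, tmp_path / "b")
        (tmp_path / "b" / "torque.tsv").unlink()
        with pytest.raises(FileNotFoundError, match="torque"):
            read_trial_bundle(tmp_path / "b")

    def test_zero_unit_bundle_round_trips(self, tmp_path):
        bundle = TrialBundle(
            emg=np.zeros(100), emg_fs=2222.0, torque=np.zeros(10), torque_fs=100.0,
            units=[], mvc_rms=1.0, target_mvc=20.0,
            meta={"trapezoids": [], "seed": 0},
        )
        write_trial_bundle(bundle, tmp_path / "b0")
        back = read_trial_bundle(tmp_path / "b0")
        assert bundles_equal(bundle, back)

    def test_bundle_generation_deterministic(self):
        a = generate_trial_bundle(PoolConfig(seed=5, n_units=4, n_background=10), 20.0)
        b = generate_trial_bundle(PoolConfig(seed=5, n_units=4, n_background=10), 20.0)
        assert bundles_equal(a, b)


class TestExposure:
    def test_exposed_units_are_most_visible_active(self, default_bundle):
        assert len(default_bundle.units) <= 16
        assert all(u.firings.size > 0 for u in default_bundle.units)

    def test_torque_independent_of_visibility(self):
        a = generate_trial_bundle(PoolConfig(seed=3), 20.0)
        b = generate_trial_bundle(PoolConfig(seed=3, visibility_sigma=0.0), 20.0)
        np.testing.assert_array_equal(a.torque, b.torque)
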