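import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from ringmotor.energetics import BP_RISE_NM
from ringmotor.fv_models import v_linear
from ringmotor.model_fitting import VelocityPoint
from ringmotor.synthetic_data import (
    CycleConfig,
    TetherTrapConfig,
    Trace,
    simulate_trace,
    wlc_extension,
    wlc_force,
)
from ringmotor.trace_processing import (
    consolidate_force_velocity,
    correct_pause_stats,
    detect_pauses,
    detect_slips,
    detection_threshold,
    extension_to_contour,
    pause_free_velocity,
)
from conftest import noisy_fv_points, piecewise_trace


class TestContourConversion:
    def test_noise_free_round_trip(self):
        cfg = CycleConfig(atp=3000.0, seed=61)
        tether = TetherTrapConfig(mode="constant_force", setpoint_force=8.0,
                                  noise_sd=0.0)
        trace, _ = simulate_trace(cfg, tether, duration=0.4)
        contour = extension_to_contour(trace, tether.persistence_length)
        np.testing.assert_allclose(contour, trace.contour_length, atol=1e-6)

    def test_forward_map_half_extension(self):
        # (x, F) generated at x/L = 1/2 recovers L exactly
        L_nm = 3400.0
        f = wlc_force(L_nm / 2, L_nm, 50.0)
        trace = Trace(
            time=np.array([0.0]),
            extension=np.array([L_nm / 2]),
            force=np.array([f]),
            contour_length=np.array([np.nan]),
        )
        contour = extension_to_contour(trace, 50.0)
        assert contour[0] == pytest.approx(L_nm / BP_RISE_NM, rel=1e-9)

    def test_nonpositive_force_flagged(self):
        trace = Trace(
            time=np.array([0.0, 1.0]),
            extension=np.array([100.0, 100.0]),
            force=np.array([0.0, 5.0]),
            contour_length=np.array([np.nan, np.nan]),
        )
        contour = extension_to_contour(trace, 50.0)
        assert np.isnan(contour[0]) and np.isfinite(contour[1])

    def test_extensible_round_trip(self):
        L_nm = 3400.0
        x = wlc_extension(30.0, L_nm, 50.0, stretch_modulus=1200.0)
        trace = Trace(
            time=np.array([0.0]), extension=np.array([x]),
            force=np.array([30.0]), contour_length=np.array([np.nan]),
        )
        contour = extension_to_contour(trace, 50.0, stretch_modulus=1200.0)
        assert contour[0] == pytest.approx(L_nm / BP_RISE_NM, rel=1e-9)


FIVE_PAUSE_SEGMENTS = [
    (0.3, 1500.0), (0.12, 0.0), (0.25, 1500.0), (0.2, 0.0), (0.3, 1500.0),
    (0.15, 0.0), (0.25, 1500.0), (0.1, 0.0), (0.3, 1500.0), (0.3, 0.0),
    (0.25, 1500.0),
]


class TestPauseDetection:
    def test_noise_free_pause_recovery(self):
        trace, true_pauses = piecewise_trace(FIVE_PAUSE_SEGMENTS, noise_sd=0.0)
        _, pauses = detect_pauses(trace, min_duration=0.05)
        assert len(pauses) == 5
        for det, (start, dur) in zip(pauses, true_pauses):
            assert det.start == pytest.approx(start, abs=4 / 2500.0)
            assert det.duration == pytest.approx(dur, abs=8 / 2500.0)

    def test_constant_velocity_no_pauses(self):
        trace, _ = piecewise_trace([(1.0, 1500.0)], noise_sd=0.0)
        fit, pauses = detect_pauses(trace, min_duration=0.05)
        assert pauses == []
        assert fit.n_segments == 1

    def test_empty_trace_rejected(self):
        trace = Trace(time=np.array([]), extension=np.array([]),
                      force=np.array([]), contour_length=np.array([]))
        with pytest.raises(ValueError):
            detect_pauses(trace, min_duration=0.05)

    def test_detection_threshold_schedule(self):
        assert detection_threshold(250.0) == 0.05
        assert detection_threshold(500.0) == 0.05
        assert detection_threshold(750.0) == 0.03
        assert detection_threshold(5000.0) == 0.03

    def test_recall_and_fdr_on_noisy_traces(self):
        # pauses of twice the detection threshold, 2 nm extension noise:
        # recall >= 0.95 and false-discovery <= 0.05 over 50 seeded traces
        min_dur = 0.05
        hits = misses = false = 0
        for seed in range(50):
            rng = np.random.default_rng(1234 + seed)
            segments = []
            true_p = []
            t0 = 0.0
            for k in range(4):
                run = 0.25 + 0.1 * rng.random()
                segments.append((run, 1500.0))
                t0 += run
                segments.append((2 * min_dur, 0.0))
                true_p.append((t0, 2 * min_dur))
                t0 += 2 * min_dur
            segments.append((0.3, 1500.0))
            trace, _ = piecewise_trace(segments, noise_sd=2.0, seed=seed)
            contour = extension_to_contour(trace)
            _, detected = detect_pauses(trace, min_duration=min_dur,
                                        contour=contour)
            for start, dur in true_p:
                if any(d.start < start + dur and d.start + d.duration > start
                       for d in detected):
                    hits += 1
                else:
                    misses += 1
            for d in detected:
                if not any(d.start < s + dur and d.start + d.duration > s
                           for s, dur in true_p):
                    false += 1
        recall = hits / (hits + misses)
        fdr = false / max(hits + false, 1)
        assert recall >= 0.95
        assert fdr <= 0.05


class TestPauseFreeVelocity:
    def test_noise_free_velocity_exact(self):
        trace, _ = piecewise_trace([(1.0, 1500.0)], noise_sd=0.0)
        point = pause_free_velocity(trace, [], force_window=(4.0, 6.0))
        assert point.velocity == pytest.approx(1500.0, rel=1e-9)

    def test_all_pause_trace_skipped(self):
        trace, pauses = piecewise_trace([(1.0, 0.0)], noise_sd=0.0)
        from ringmotor.trace_processing import PauseEvent

        events = [PauseEvent(start=s, duration=d, force=5.0) for s, d in pauses]
        assert pause_free_velocity(trace, events, (4.0, 6.0)) is None

    def test_pause_removal_minor_effect_when_pauses_sparse(self):
        # sparse pausing: excising the pauses shifts the velocity by < 5%
        segments = [(0.45, 1500.0), (0.03, 0.0), (0.52, 1500.0)]
        trace, pauses = piecewise_trace(segments, noise_sd=0.0)
        from ringmotor.trace_processing import PauseEvent

        events = [PauseEvent(start=s, duration=d, force=5.0) for s, d in pauses]
        with_removal = pause_free_velocity(trace, events, (4.0, 6.0)).velocity
        without = pause_free_velocity(trace, [], (4.0, 6.0)).velocity
        assert abs(without - with_removal) / with_removal < 0.05

    def test_pause_excision_recovers_translocation_rate(self, linear_defaults):
        # heavy pausing at low [ATP]: excising detected pauses recovers the
        # pause-free rate of the kinetic model, not the time-averaged rate
        v = []
        for seed in range(3):
            cfg = CycleConfig(atp=250.0, pause_entry=7.0, seed=500 + seed)
            tether = TetherTrapConfig(mode="constant_force", setpoint_force=5.0)
            trace, _ = simulate_trace(cfg, tether, duration=4.0)
            contour = extension_to_contour(trace)
            _, pauses = detect_pauses(trace, min_duration=0.05, contour=contour)
            v.append(pause_free_velocity(trace, pauses, (4.0, 6.0),
                                         contour=contour).velocity)
        v_theory = float(v_linear(5.0, 250.0, linear_defaults))
        assert np.mean(v) == pytest.approx(v_theory, rel=0.08)

    def test_corpus_velocity_matches_calibration_point(self, linear_defaults):
        # constant-force cells at 5 pN / 3 mM average to ~4000 bp/s
        v = []
        for seed in range(6):
            cfg = CycleConfig(atp=3000.0, seed=300 + seed)
            tether = TetherTrapConfig(mode="constant_force", setpoint_force=5.0,
                                      noise_sd=2.0)
            trace, _ = simulate_trace(cfg, tether, duration=0.6)
            contour = extension_to_contour(trace)
            point = pause_free_velocity(trace, [], (4.0, 6.0), contour=contour)
            v.append(point.velocity)
        sem = np.std(v, ddof=1) / np.sqrt(len(v))
        assert np.mean(v) == pytest.approx(4000.0, abs=max(3 * sem, 120.0))

    def test_passive_and_constant_force_agree(self, linear_defaults):
        # velocity in a matching force bin agrees between operating modes
        vp = []
        for seed in range(4):
            cfg = CycleConfig(atp=3000.0, seed=71 + seed)
            passive = TetherTrapConfig(mode="passive", setpoint_force=None,
                                       noise_sd=0.0, contour_length0=40000.0)
            tr_p, _ = simulate_trace(cfg, passive, duration=1.2)
            vp.append(pause_free_velocity(tr_p, [], (10.0, 12.0)).velocity)
        vc = []
        for seed in range(4):
            cfg_c = CycleConfig(atp=3000.0, seed=81 + seed)
            const = TetherTrapConfig(mode="constant_force", setpoint_force=11.0,
                                     noise_sd=0.0)
            tr_c, _ = simulate_trace(cfg_c, const, duration=0.4)
            vc.append(pause_free_velocity(tr_c, [], (10.0, 12.0)).velocity)
        sem = np.hypot(np.std(vp, ddof=1) / 2, np.std(vc, ddof=1) / 2)
        assert abs(np.mean(vp) - np.mean(vc)) < max(3 * sem, 0.06 * np.mean(vc))


class TestPauseCorrection:
    def test_worked_example(self):
        stats = correct_pause_stats([0.1, 0.2, 0.4], min_duration=0.05)
        assert stats.tau_hat == pytest.approx(0.7 / 3 - 0.05, rel=1e-12)
        assert stats.tau_hat == pytest.approx(0.1833, abs=5e-4)
        assert stats.detected_fraction == pytest.approx(0.761, abs=1e-3)
        assert stats.corrected_count == pytest.approx(3.94, abs=0.01)

    def test_zero_threshold_is_plain_mean(self):
        stats = correct_pause_stats([0.1, 0.2, 0.4], min_duration=0.0)
        assert stats.tau_hat == pytest.approx(0.7 / 3, rel=1e-12)
        assert stats.corrected_count == pytest.approx(3.0, rel=1e-12)

    def test_matches_brute_force_likelihood(self):
        # analytic MLE equals a numerical maximization of the censored
        # exponential likelihood to 1e-6 relative
        rng = np.random.default_rng(8)
        min_dur = 0.05
        samples = min_dur + rng.exponential(0.2, size=200)
        stats = correct_pause_stats(samples, min_dur)

        def nll(tau):
            # left-truncated exponential: density exp(-(d-min)/tau)/tau
            return np.sum((samples - min_dur) / tau + np.log(tau))

        res = minimize_scalar(nll, bounds=(1e-4, 10.0), method="bounded",
                              options={"xatol": 1e-10})
        assert stats.tau_hat == pytest.approx(res.x, rel=1e-6)

    def test_recovery_of_generator_truth(self):
        # censored observations of exponential pauses recover tau within 2 SE
        tau_true = 1.0 / (0.012 * 250.0)  # mean pause at 250 μM ATP
        min_dur = 0.05
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(9000 + seed)
            d = rng.exponential(tau_true, size=200)
            d = d[d >= min_dur]
            errs.append(correct_pause_stats(d, min_dur).tau_hat - tau_true)
        se = np.std(errs, ddof=1) / np.sqrt(len(errs))
        assert abs(np.mean(errs)) < 2 * se + 1e-3

    def test_empty_input_flagged(self):
        stats = correct_pause_stats([], min_duration=0.05)
        assert not stats.valid and stats.observed_count == 0

    def test_sub_threshold_durations_rejected(self):
        with pytest.raises(ValueError):
            correct_pause_stats([0.01], min_duration=0.05)


class TestSlips:
    def test_noise_free_slip_recovery(self):
        cfg = CycleConfig(atp=500.0, slip_hazard0=2.0, slip_mean_bp=1500.0,
                          seed=91)
        tether = TetherTrapConfig(mode="passive", setpoint_force=None,
                                  noise_sd=0.0, contour_length0=40000.0)
        trace, log = simulate_trace(cfg, tether, duration=3.0)
        big_true = [s for s in log.slips if s[1] >= 50.0]
        assert big_true
        detected = detect_slips(trace, min_release=50.0)
        assert len(detected) == len(big_true)
        for det, (t_true, released, _) in zip(detected, big_true):
            assert det.time == pytest.approx(t_true, abs=2 / 2500.0)
            assert det.released_bp == pytest.approx(released, rel=0.05)

    def test_monotone_contour_no_slips(self):
        trace, _ = piecewise_trace([(0.5, 1500.0)], noise_sd=0.0)
        assert detect_slips(trace) == []


class TestConsolidation:
    def test_identical_cells_mean_invariance(self):
        cell = [VelocityPoint(5.0, 3000.0, 4000.0, sem=100.0),
                VelocityPoint(9.0, 3000.0, 3500.0, sem=100.0)]
        out = consolidate_force_velocity([cell, cell, cell])
        assert [p.velocity for p in out] == [4000.0, 3500.0]

    def test_pooled_sem_not_larger_than_worst(self):
        rng = np.random.default_rng(17)
        cells = [
            [VelocityPoint(5.0, 3000.0, 4000.0 + 50 * rng.standard_normal(),
                           sem=s)]
            for s in (80.0, 120.0, 200.0)
        ]
        out = consolidate_force_velocity(cells)
        assert len(out) == 1
        assert out[0].sem <= 200.0

    def test_out_of_range_windows_rejected(self):
        cell = [VelocityPoint(60.0, 3000.0, 1000.0, sem=50.0)]
        with pytest.raises(ValueError):
            consolidate_force_velocity([cell])

    def test_consolidated_curve_is_biphasic(self, linear_defaults,
                                            force_bin_centers):
        # pooled 2/3/5 mM synthetic curves keep the two-phase force response
        rng = np.random.default_rng(23)
        cells = [
            noisy_fv_points(v_linear(force_bin_centers, atp, linear_defaults),
                            force_bin_centers, atp, 0.02, rng)
            for atp in (2000.0, 3000.0, 5000.0) for _ in range(3)
        ]
        out = consolidate_force_velocity(cells)
        F = np.array([p.force_bin_center for p in out])
        v = np.array([p.velocity for p in out])
        drop_low = (v[F == 3.0][0] - v[F == 14.5][0]) / (14.5 - 3.0)
        plateau = abs(v[F == 18.0][0] - v[F == 27.5][0]) / (27.5 - 18.0)
        drop_high = (v[F == 42.5][0] - v[F == 47.5][0]) / 5.0
        assert drop_low > 3 * plateau
        assert drop_high > 1.5 * plateau
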