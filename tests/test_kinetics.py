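import numpy as np
import pytest
from scipy import stats

from phtrace import (
    DegenerateFitError,
    SimulationParams,
    UndefinedRFError,
    compute_amplitude,
    compute_rf,
    fit_decay,
    fit_rise,
    normalize_dff,
    simulate_trace_mechanistic,
    simulate_trace_phenomenological,
    standard_protocol,
    subtract_background,
)
from phtrace.trace_io import NormalizedTrace

from conftest import grid_search_tau


def normalized(protocol, params):
    raw, truth = simulate_trace_phenomenological(params, protocol)
    return normalize_dff(subtract_background(raw)), truth


class TestFitRise:
    def test_exact_recovery_with_true_plateau(self, protocol):
        p = SimulationParams(tau_rise_s=2.0, noise_sd_au=0.0,
                             bleach_rate_per_s=0.0)
        n, truth = normalized(protocol, p)
        fit = fit_rise(n, max_override=truth["amp"])
        assert fit.tau_s == pytest.approx(2.0, rel=1e-3)
        assert fit.converged and fit.plateau > fit.f0

    def test_flat_stimulus_window_degenerate(self, protocol):
        p = SimulationParams(amp=0.0, noise_sd_au=0.0, bleach_rate_per_s=0.0)
        n, _ = normalized(protocol, p)
        with pytest.raises(DegenerateFitError):
            fit_rise(n)

    def test_agrees_with_grid_search(self, protocol):
        p = SimulationParams(seed=21)
        n, _ = normalized(protocol, p)
        fit = fit_rise(n)
        lo = 1.0 / protocol.frame_rate_hz
        hi = 10.0 * (fit.window[1] - fit.window[0])
        sl = slice(*np.searchsorted(n.time_s, fit.window))
        best, taus = grid_search_tau(n.time_s[sl] - fit.t0_s, n.dff[sl],
                                     fit.f0, fit.plateau, True, lo, hi)
        step = np.log(taus[1] / taus[0])
        assert abs(np.log(fit.tau_s / best)) <= step

    def test_time_unit_covariance(self, protocol):
        # compressing time by c scales the fitted tau by exactly c
        p = SimulationParams(seed=22)
        n, _ = normalized(protocol, p)
        fit1 = fit_rise(n)
        c = 2.0
        proto2 = standard_protocol(frame_rate_hz=protocol.frame_rate_hz * c,
                                   baseline_s=10.0 / c, stim_s=10.0 / c,
                                   total_s=90.0 / c)
        n2 = NormalizedTrace(animal_id=n.animal_id, time_s=n.time_s / c,
                             dff=n.dff, f0_baseline=n.f0_baseline,
                             protocol=proto2)
        fit2 = fit_rise(n2)
        assert fit2.tau_s == pytest.approx(fit1.tau_s / c, rel=1e-6)


class TestFitDecay:
    def test_exact_recovery_with_true_plateaus(self, protocol):
        p = SimulationParams(tau_decay_s=15.0, noise_sd_au=0.0,
                             bleach_rate_per_s=0.0)
        n, truth = normalized(protocol, p)
        fit = fit_decay(n, f0_override=truth["level_end"], min_override=0.0)
        assert fit.tau_s == pytest.approx(15.0, rel=1e-3)
        assert fit.f0 > fit.plateau

    def test_flat_post_stimulus_degenerate(self, protocol):
        # plateau persists after the stimulus: f0 equals Min, nothing decays
        t = protocol.times()
        dff = np.where(t >= 10.0, 0.2, 0.0)
        dff[(t >= 10.0) & (t < 20.0)] = 0.2 * (t[(t >= 10.0) & (t < 20.0)] - 10.0) / 10.0
        dff[t >= 20.0] = 0.2
        n = NormalizedTrace(animal_id="t", time_s=t, dff=dff,
                            f0_baseline=100.0, protocol=protocol)
        with pytest.raises(DegenerateFitError):
            fit_decay(n)

    def test_agrees_with_grid_search(self, protocol):
        p = SimulationParams(seed=23)
        n, _ = normalized(protocol, p)
        fit = fit_decay(n)
        lo = 1.0 / protocol.frame_rate_hz
        hi = 10.0 * (fit.window[1] - fit.window[0])
        sl = slice(np.searchsorted(n.time_s, fit.window[0]), len(n.time_s))
        best, taus = grid_search_tau(n.time_s[sl] - fit.t0_s, n.dff[sl],
                                     fit.f0, fit.plateau, False, lo, hi)
        step = np.log(taus[1] / taus[0])
        assert abs(np.log(fit.tau_s / best)) <= step

    def test_rank_correlation_over_noiseless_sweep(self, protocol):
        taus = [2.0, 5.0, 10.0, 20.0, 40.0]
        rec_rise, rec_decay = [], []
        for tau in taus:
            p = SimulationParams(tau_rise_s=tau, tau_decay_s=tau,
                                 noise_sd_au=0.0, bleach_rate_per_s=0.0)
            n, truth = normalized(protocol, p)
            rec_rise.append(fit_rise(n, max_override=truth["amp"]).tau_s)
            rec_decay.append(
                fit_decay(n, f0_override=truth["level_end"],
                          min_override=0.0).tau_s
            )
        assert stats.spearmanr(taus, rec_rise).statistic == pytest.approx(1.0, abs=1e-9)
        assert stats.spearmanr(taus, rec_decay).statistic == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(rec_rise, taus, rtol=1e-3)
        np.testing.assert_allclose(rec_decay, taus, rtol=1e-3)


class TestAmplitude:
    def test_constant_plateau_window(self, protocol):
        t = protocol.times()
        dff = np.where((t >= 15.0) & (t < 20.0), 0.21, 0.0)
        n = NormalizedTrace(animal_id="t", time_s=t, dff=dff,
                            f0_baseline=100.0, protocol=protocol)
        res = compute_amplitude(n)
        assert res.value == pytest.approx(0.21)
        assert res.window == (15.0, 20.0)

    def test_zero_trace(self, protocol):
        n = NormalizedTrace(animal_id="t", time_s=protocol.times(),
                            dff=np.zeros(protocol.n_frames),
                            f0_baseline=100.0, protocol=protocol)
        assert compute_amplitude(n).value == 0.0

    def test_phuji_uses_first_second_after_stimulus(self):
        proto = standard_protocol(frame_rate_hz=20.0, reporter_mode="phuji")
        t = proto.times()
        dff = np.where((t >= 20.0) & (t < 21.0), 0.19, 0.0)
        n = NormalizedTrace(animal_id="t", time_s=t, dff=dff,
                            f0_baseline=100.0, protocol=proto)
        res = compute_amplitude(n)
        assert res.value == pytest.approx(0.19)
        assert res.window == (20.0, 21.0)

    def test_cohort_mean_matches_closed_form_expectation(self, protocol):
        # amp 0.21, tau 2.3: expected window mean is amp * mean of the
        # association curve over [15, 20) s
        t_w = protocol.times()
        mask = (t_w >= 15.0) & (t_w < 20.0)
        expected = 0.21 * (1 - np.exp(-(t_w[mask] - 10.0) / 2.3)).mean()
        vals = []
        for seed in range(40):
            p = SimulationParams(amp=0.21, tau_rise_s=2.3,
                                 bleach_rate_per_s=0.0, seed=seed)
            raw, _ = simulate_trace_phenomenological(p, protocol)
            vals.append(
                compute_amplitude(normalize_dff(subtract_background(raw))).value
            )
        vals = np.asarray(vals)
        sem = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean() - expected) <= 3 * sem


class TestReleasableFraction:
    def test_trivial_ratio(self, rf_protocol):
        t = rf_protocol.times()
        dff = np.zeros_like(t)
        dff[(t >= 10.0) & (t < 20.0)] = 0.2
        dff[(t >= 60.0)] = 1.0
        n = NormalizedTrace(animal_id="t", time_s=t, dff=dff,
                            f0_baseline=100.0, protocol=rf_protocol)
        res = compute_rf(n)
        assert res.rf == pytest.approx(0.2)
        assert res.f_nh4cl == pytest.approx(1.0)

    @pytest.mark.parametrize("rho", [0.1, 0.2, 0.5])
    def test_mechanistic_recovery(self, rf_protocol, rho):
        p = SimulationParams(tau_rise_s=0.02, noise_sd_au=0.0,
                             bleach_rate_per_s=0.0, releasable_fraction=rho,
                             quench_factor=0.0)
        raw, _ = simulate_trace_mechanistic(p, rf_protocol,
                                            substeps_per_frame=200)
        res = compute_rf(normalize_dff(subtract_background(raw)))
        assert res.rf == pytest.approx(rho, rel=0.02)

    def test_zero_reference_is_undefined(self, rf_protocol):
        t = rf_protocol.times()
        dff = np.zeros_like(t)
        dff[(t >= 10.0) & (t < 20.0)] = 0.2
        n = NormalizedTrace(animal_id="t", time_s=t, dff=dff,
                            f0_baseline=100.0, protocol=rf_protocol)
        with pytest.raises(UndefinedRFError):
            compute_rf(n)

    def test_requires_nh4cl_event(self, protocol):
        n = NormalizedTrace(animal_id="t", time_s=protocol.times(),
                            dff=np.zeros(protocol.n_frames),
                            f0_baseline=100.0, protocol=protocol)
        with pytest.raises(UndefinedRFError):
            compute_rf(n)
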