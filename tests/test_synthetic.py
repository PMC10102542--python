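import numpy as np
import pytest

from phtrace import (
    CohortSpec,
    IntegrationInstabilityError,
    SimulationParams,
    culture_protocol,
    simulate_cohort,
    simulate_trace_mechanistic,
    simulate_trace_phenomenological,
    standard_protocol,
)


class TestPhenomenological:
    def test_flat_when_amp_zero(self, protocol):
        p = SimulationParams(amp=0.0, noise_sd_au=0.0, bleach_rate_per_s=0.0)
        raw, _ = simulate_trace_phenomenological(p, protocol)
        np.testing.assert_allclose(raw.roi, p.baseline_au + p.background_au)
        np.testing.assert_allclose(raw.background, p.background_au)

    def test_rise_closed_form_at_stim_end(self, protocol):
        p = SimulationParams(amp=0.2, tau_rise_s=2.0, noise_sd_au=0.0,
                             bleach_rate_per_s=0.0)
        _, truth = simulate_trace_phenomenological(p, protocol)
        # 10 s stimulus, tau 2 s: level approaches 0.2*(1-e^-5)
        assert truth["level_end"] == pytest.approx(0.2 * (1 - np.exp(-5.0)))
        dff = truth["dff_true"]
        t = protocol.times()
        k = np.searchsorted(t, 19.8)
        assert dff[k] == pytest.approx(0.2 * (1 - np.exp(-9.8 / 2.0)), rel=1e-12)

    def test_decay_closed_form(self, protocol):
        p = SimulationParams(noise_sd_au=0.0, bleach_rate_per_s=0.0)
        _, truth = simulate_trace_phenomenological(p, protocol)
        t = protocol.times()
        dff = truth["dff_true"]
        after = t >= 20.0
        expected = truth["level_end"] * np.exp(-(t[after] - 20.0) / p.tau_decay_s)
        np.testing.assert_allclose(dff[after], expected, rtol=1e-12)

    def test_pulsed_mode_inflates_rise_by_inverse_duty(self):
        proto = standard_protocol(stim_mode="pulsed", pulse_rate_hz=2.0,
                                  pulse_width_s=0.1)
        p = SimulationParams(noise_sd_au=0.0, bleach_rate_per_s=0.0)
        _, truth = simulate_trace_phenomenological(p, proto)
        assert truth["tau_rise_eff_s"] == pytest.approx(p.tau_rise_s / 0.2)

    def test_non_responder_has_zero_signal(self, protocol):
        p = SimulationParams(responder=False, noise_sd_au=0.0,
                             bleach_rate_per_s=0.0)
        _, truth = simulate_trace_phenomenological(p, protocol)
        np.testing.assert_array_equal(truth["dff_true"], 0.0)

    def test_phuji_photoswitch_artifact_after_stim(self):
        proto = standard_protocol(frame_rate_hz=20.0, reporter_mode="phuji")
        p = SimulationParams(amp=0.0, photoswitch_amp=0.05, noise_sd_au=0.0,
                             bleach_rate_per_s=0.0)
        _, truth = simulate_trace_phenomenological(p, proto)
        t = proto.times()
        dff = truth["dff_true"]
        assert np.all(dff[t < 20.0] == 0.0)
        k = np.searchsorted(t, 20.0)
        assert dff[k] == pytest.approx(0.05, rel=1e-9)

    def test_determinism_under_fixed_seed(self, protocol):
        p = SimulationParams(seed=42)
        a, _ = simulate_trace_phenomenological(p, protocol)
        b, _ = simulate_trace_phenomenological(p, protocol)
        np.testing.assert_array_equal(a.roi, b.roi)
        np.testing.assert_array_equal(a.background, b.background)


class TestMechanistic:
    def test_no_drive_is_flat(self, rf_protocol):
        p = SimulationParams(responder=False, noise_sd_au=0.0,
                             bleach_rate_per_s=0.0, quench_factor=0.0)
        raw, truth = simulate_trace_mechanistic(p, rf_protocol)
        t = raw.time_s
        pre_nh4cl = t < 60.0
        np.testing.assert_allclose(truth["dff_true"][pre_nh4cl], 0.0, atol=1e-12)
        # surface pool never moves without light
        np.testing.assert_allclose(truth["pool_state"].S[pre_nh4cl],
                                   p.surface_fraction_rest, atol=1e-12)

    def test_two_pool_closure(self, rf_protocol):
        p = SimulationParams(noise_sd_au=0.0)
        _, truth = simulate_trace_mechanistic(p, rf_protocol,
                                              substeps_per_frame=20)
        pool = truth["pool_state"]
        assert np.max(np.abs(pool.S + pool.V - 1.0)) < 1e-12

    def test_nh4cl_dequench_and_acid_quench(self):
        proto = culture_protocol(acid_start_s=92.0, total_s=95.0)
        p = SimulationParams(noise_sd_au=0.0, bleach_rate_per_s=0.0,
                             quench_factor=0.05)
        raw, truth = simulate_trace_mechanistic(p, proto)
        t = raw.time_s
        dff = truth["dff_true"]
        s0, q = p.surface_fraction_rest, p.quench_factor
        baseline_rel = s0 + q * (1 - s0)
        # NH4Cl dequenches everything: F_rel = 1
        nh4 = (t >= 85.0) & (t < 90.0)
        np.testing.assert_allclose(dff[nh4], 1.0 / baseline_rel - 1.0, rtol=1e-6)
        # acid quenches the surface pool too: fluorescence below baseline
        assert np.all(dff[t >= 92.0] < 0.0)

    def test_saturating_stimulation_releases_rho_of_pool(self, rf_protocol):
        p = SimulationParams(tau_rise_s=0.02, noise_sd_au=0.0,
                             bleach_rate_per_s=0.0, releasable_fraction=0.2,
                             quench_factor=0.0)
        _, truth = simulate_trace_mechanistic(p, rf_protocol,
                                              substeps_per_frame=200)
        S = truth["pool_state"].S
        s0 = p.surface_fraction_rest
        plateau = S.max() - s0
        assert plateau == pytest.approx(0.2 * (1 - s0), rel=5e-3)

    def test_converges_to_phenomenological_shape(self, protocol):
        # weak drive, q=0: the two-pool model is itself a one-phase
        # association toward rho*V0*k_exo/(k_exo+k_endo), then a one-phase
        # decay; Euler output must approach that closed form as the step
        # count grows
        p = SimulationParams(tau_rise_s=20.0, tau_decay_s=15.0,
                             noise_sd_au=0.0, bleach_rate_per_s=0.0,
                             releasable_fraction=0.2, quench_factor=0.0)
        k_exo, k_endo = 1 / 20.0, 1 / 15.0
        k_tot = k_exo + k_endo
        s0 = p.surface_fraction_rest
        pool = 0.2 * (1 - s0)
        t = protocol.times()
        e = np.zeros_like(t)
        during = (t >= 10.0) & (t < 20.0)
        e[during] = pool * k_exo / k_tot * (1 - np.exp(-k_tot * (t[during] - 10.0)))
        e_off = pool * k_exo / k_tot * (1 - np.exp(-k_tot * 10.0))
        after = t >= 20.0
        e[after] = e_off * np.exp(-k_endo * (t[after] - 20.0))
        exact = e / s0
        errs = []
        for sub in (10, 40, 160):
            _, truth = simulate_trace_mechanistic(p, protocol,
                                                  substeps_per_frame=sub)
            errs.append(np.max(np.abs(truth["dff_true"] - exact)))
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 2e-4

    def test_unstable_step_raises(self, rf_protocol):
        p = SimulationParams(tau_rise_s=0.005, noise_sd_au=0.0)
        with pytest.raises(IntegrationInstabilityError):
            simulate_trace_mechanistic(p, rf_protocol, substeps_per_frame=10)

    def test_nh4cl_frame_subsampling(self, rf_protocol):
        p = SimulationParams(noise_sd_au=0.0)
        raw, _ = simulate_trace_mechanistic(p, rf_protocol,
                                            nh4cl_frame_interval_s=5.0)
        assert raw.protocol.n_frames < rf_protocol.n_frames
        gaps = np.diff(raw.time_s[raw.time_s > 61.0])
        assert np.all(gaps >= 5.0 - 1e-9)


class TestCohort:
    def test_all_responders(self, protocol):
        spec = CohortSpec(n_animals=10, protocol=protocol,
                          responder_fraction=1.0, master_seed=5)
        traces, truth = simulate_cohort(spec)
        assert len(traces) == 10
        assert (truth["amp"] > 0).all()
        assert truth["responder"].all()

    def test_bit_identical_under_same_master_seed(self, protocol):
        spec = CohortSpec(n_animals=6, protocol=protocol, master_seed=9)
        t1, g1 = simulate_cohort(spec)
        t2, g2 = simulate_cohort(spec)
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.roi, b.roi)
        assert g1.equals(g2)

    def test_independent_animal_substreams(self, protocol):
        # growing the cohort must not perturb the animals already drawn
        small = simulate_cohort(CohortSpec(n_animals=4, protocol=protocol,
                                           master_seed=13))[0]
        large = simulate_cohort(CohortSpec(n_animals=8, protocol=protocol,
                                           master_seed=13))[0]
        for a, b in zip(small, large[:4]):
            np.testing.assert_array_equal(a.roi, b.roi)

    def test_responder_count_binomial(self, protocol):
        spec = CohortSpec(n_animals=2000, protocol=protocol,
                          responder_fraction=0.5, master_seed=77)
        _, truth = simulate_cohort(spec)
        count = int(truth["responder"].sum())
        sigma = np.sqrt(2000 * 0.25)
        assert abs(count - 1000) <= 3 * sigma
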