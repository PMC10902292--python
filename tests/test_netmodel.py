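"""QIF network dynamics, model LFP kinetics, regime indicators, and
spike-presence decoding plumbing."""

import numpy as np
import pytest

from gammaens import netmodel as nm

FS = 1000.0


def uncoupled(n=10, I0=1.0, dt=0.01, **kw):
    return nm.NetworkParams(n=n, frac_E=0.8, K=1.0, g0_EE=0.0, g0_II=0.0,
                            g0_EI=0.0, g0_IE=0.0, I0_E=I0, I0_I=I0,
                            D_E=0.0, D_I=0.0, theta_A=0.0, dt_ms=dt, seed=0,
                            **kw)


class TestQIFDynamics:
    def test_tonic_rate_close_to_closed_form_at_coarse_dt(self):
        sim = nm.simulate_network(uncoupled(dt=0.01), 2000.0)
        expected = nm.qif_tonic_rate(1.0, 10.0)  # ~31.83 Hz
        assert abs(sim.e_rates().mean() / expected - 1) < 0.10

    def test_subthreshold_network_is_silent(self):
        p = uncoupled(I0=-0.5)
        sim = nm.simulate_network(p, 1000.0)
        assert len(sim.spike_times) == 0

    def test_same_seed_reproduces_identical_raster(self):
        p = nm.NetworkParams(n=100, K=10.0, dt_ms=0.01, seed=7)
        a = nm.simulate_network(p, 2000.0)
        p2 = nm.NetworkParams(n=100, K=10.0, dt_ms=0.01, seed=7)
        b = nm.simulate_network(p2, 2000.0)
        assert np.array_equal(a.spike_times, b.spike_times)
        assert np.array_equal(a.spike_ids, b.spike_ids)

    def test_rate_converges_when_dt_shrinks(self):
        r = {}
        for dt in (0.01, 0.001):
            sim = nm.simulate_network(uncoupled(dt=dt), 2000.0)
            r[dt] = sim.e_rates().mean()
        assert abs(r[0.001] / r[0.01] - 1) < 0.02

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            nm.NetworkParams(tau_E=-1.0)
        with pytest.raises(ValueError):
            nm.NetworkParams(frac_E=1.5)


class TestModelLFP:
    def test_empty_raster_zero_lfp(self):
        p = nm.NetworkParams(n=10, seed=0)
        lfp = nm.synthesize_model_lfp(p, np.array([]), np.array([]), 100.0)
        assert np.allclose(lfp, 0.0)

    def test_single_spike_matches_closed_form_double_exponential(self):
        p = nm.NetworkParams(n=10, seed=0)
        lfp = nm.synthesize_model_lfp(p, np.array([5.0]), np.array([0]), 60.0,
                                      ee_drive_counts=np.array([1] + [0] * 7))
        jump = 2 * p.tau_E * (p.g0_EE / np.sqrt(p.K)) / p.tau_rA
        ref = nm.double_exp_impulse(np.arange(60.0) - 5.0, p.tau_rA, p.tau_dA,
                                    jump)
        assert np.abs(lfp - ref).max() < 1e-14
        # peak lies between the rise and decay time scales
        t_peak = np.argmax(lfp) - 5
        assert p.tau_rA < t_peak < 3 * p.tau_dA

    def test_prefilter_lfp_is_nonnegative(self, fringe_sim):
        assert fringe_sim.lfp_raw.min() >= 0.0


class TestIndicators:
    def test_flat_noise_has_near_maximal_spectral_entropy(self):
        x = np.random.default_rng(0).normal(size=int(20 * FS))
        # periodogram estimation noise keeps it just below the ideal 1.0
        assert nm.spectral_entropy(x, FS) > 0.95

    def test_pure_tone_has_near_zero_spectral_entropy(self):
        t = np.arange(0, 20, 1 / FS)
        assert nm.spectral_entropy(np.sin(2 * np.pi * 60 * t), FS) < 0.05

    def test_two_equal_tones_give_two_atom_entropy(self):
        t = np.arange(0, 20, 1 / FS)
        x = np.sin(2 * np.pi * 40 * t) + np.sin(2 * np.pi * 80 * t)
        assert nm.spectral_entropy(x, FS) == pytest.approx(
            np.log2(2) / np.log2(1000), abs=0.02)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            nm.spectral_entropy(np.ones(int(5 * FS)), FS)

    def test_gamma_ratio_signs_follow_printed_formula(self):
        t = np.arange(0, 20, 1 / FS)
        assert nm.gamma_power_ratio(np.sin(2 * np.pi * 40 * t), FS) == \
            pytest.approx(1.0, abs=1e-6)
        assert nm.gamma_power_ratio(np.sin(2 * np.pi * 80 * t), FS) == \
            pytest.approx(-1.0, abs=1e-6)
        both = np.sin(2 * np.pi * 40 * t) + np.sin(2 * np.pi * 80 * t)
        assert abs(nm.gamma_power_ratio(both, FS)) < 0.01

    @pytest.mark.parametrize("p,expected", [(0.5, 1.0), (0.0, 0.0), (1.0, 0.0)])
    def test_spike_entropy_binary_formula(self, p, expected):
        assert nm.spike_train_entropy(p * 80.0, 80.0) == pytest.approx(expected)

    def test_spike_entropy_quarter_occupancy(self):
        assert nm.spike_train_entropy(20.0, 80.0) == pytest.approx(0.8113, abs=1e-4)

    def test_spike_entropy_clips_with_warning(self):
        with pytest.warns(UserWarning):
            assert nm.spike_train_entropy(100.0, 80.0) == 0.0

    def test_phase_concentration_limits(self):
        assert nm.phase_concentration(np.zeros(10)) == pytest.approx(1.0)
        assert nm.phase_concentration(np.array([0.0, np.pi])) == \
            pytest.approx(0.0, abs=1e-12)
        uniform = np.deg2rad(np.arange(360.0))
        assert nm.phase_concentration(uniform) < 1e-10
        with pytest.raises(ValueError):
            nm.phase_concentration(np.array([]))


class TestSweep:
    def test_single_point_grid_gives_one_record(self):
        base = nm.NetworkParams(n=100, dt_ms=0.02, seed=0)
        out = nm.sweep_regimes([20.0], [0.01], base, duration_ms=12000.0)
        assert len(out) == 1
        assert np.isfinite(out["spectral_entropy"].iloc[0])


class TestForcingCycles:
    def test_cycles_tile_the_forcing_period(self):
        cycles = nm.forcing_theta_cycles(1000, FS, 10.0)
        assert len(cycles) == 9
        assert all(c.end_peak - c.start_peak == 100 for c in cycles)
        assert cycles[3].trough - cycles[3].start_peak == 50


class TestSpikeDecoding:
    def test_report_schema_and_decodable_definition(self, model_run):
        sim, elements, report = model_run
        assert {"tp", "tn", "precision", "recall", "decodable",
                "phi"} <= set(report.columns)
        ok = report[report["skipped"] == ""]
        assert len(ok) > 0
        # decodable flag consistent with its segmentation rule
        flag = (ok["tp"] > 0.6) & (ok["tn"] > 0.6)
        assert (ok["decodable"] == flag).all()

    def test_dense_firing_neurons_flagged_single_class(self, model_run):
        sim, elements, report = model_run
        dense = report[report["skipped"] == "single_class"]
        assert (dense["tp"].dropna() == 1.0).all()

    def test_elements_come_from_model_lfp(self, model_run):
        sim, elements, report = model_run
        assert len(elements) > 100
        eps = 1e-9
        assert elements["gamma_frequency"].between(30 - eps, 200 + eps).all()
        assert elements["gamma_phase"].between(0, 360).all()
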