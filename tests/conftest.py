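"""Shared fixtures: synthetic recordings run through the full pipeline and
reduced-scale network simulations.  Expensive artifacts are session-scoped so
detection, decoding and model tests reuse the same material."""

import warnings

import numpy as np
import pandas as pd
import pytest

from gammaens import decode, netmodel, pipeline, synth

warnings.filterwarnings("ignore", category=UserWarning)

#: high-SNR, one-burst-per-cycle spec used for parameter-recovery checks
RECOVERY_BURSTS = synth.BurstSpec(
    freq_mean=90.0, freq_sd=12.0, phase_mean_deg=180.0, phase_sd_deg=45.0,
    amp_mean=2.0, amp_sd=0.15, rate_per_cycle=1.0, deterministic_count=True)

#: strong section-dependent frequency shifts driving the decodable structure
STRONG_MODULATION = {
    "reward_RF": {"freq_shift": 45.0},
    "target_arm": {"freq_shift": -30.0},
    "other_RF": {"freq_shift": 20.0},
}


@pytest.fixture(scope="session")
def behavior():
    """Eight trials over two days at 20 Hz; covers > 60 s of navigation."""
    return synth.generate_behavior(n_trials=8, n_days=2, seed=3, mean_speed=25.0,
                                   detours_first_day=1.5, detours_last_day=0.5)


def _make_run(behavior, modulation, seed=4, duration=60.0):
    spec = synth.RecordingSpec(
        n_channels=7, fissure_channel=5, pyr_channel=1, noise_sd=0.02,
        burst_specs={3: RECOVERY_BURSTS}, modulation_map=modulation, seed=seed)
    rec, gt = synth.generate_recording(spec, behavior, duration=duration)
    res = pipeline.extract_elements(rec, behavior, fissure_channel=5,
                                    n_realizations=12, channels=[3])
    return rec, gt, res


@pytest.fixture(scope="session")
def recovery_run(behavior):
    """60 s unmodulated recording + extraction + ground truth."""
    return _make_run(behavior, modulation={})


@pytest.fixture(scope="session")
def modulated_run(behavior):
    """Same recording conditions with strong section modulation of burst
    frequency."""
    return _make_run(behavior, modulation=STRONG_MODULATION)


@pytest.fixture(scope="session")
def fringe_sim():
    """Reduced-scale working point at the fringe of synchrony (n=500, 20 s
    after transient, dt=0.01 ms)."""
    p = netmodel.NetworkParams(n=500, K=20.0, dt_ms=0.01, seed=1)
    return netmodel.simulate_network(p, 21000.0)


@pytest.fixture(scope="session")
def sync_sim():
    """Strongly synchronized contrast point (large K), same scale."""
    p = netmodel.NetworkParams(n=500, K=640.0, dt_ms=0.01, seed=1)
    return netmodel.simulate_network(p, 21000.0)


@pytest.fixture(scope="session")
def model_run():
    """Full-size network (n=2000) at the working point, one minute of
    activity, with gamma elements extracted from the model LFP and
    spike-presence decoding over a sample of active E neurons."""
    p = netmodel.NetworkParams(n=2000, K=20.0, dt_ms=0.01, seed=1)
    sim = netmodel.simulate_network(p, 61000.0)
    elements = netmodel.extract_model_elements(sim.lfp, fs=sim.fs_out)
    rates = sim.e_rates()
    active = np.nonzero(rates > 0.5)[0]
    neurons = np.random.default_rng(0).choice(active, 80, replace=False)
    report = netmodel.decode_spiking(sim, elements=elements, neurons=neurons,
                                     n_estimators=100, seed=0)
    return sim, elements, report


def make_element_table(n_cycles=600, shift=0.0, seed=0, n_sections=4):
    """Synthetic element table with optional section-dependent frequency shift
    (bypasses the signal pipeline; used for decoder/information unit tests)."""
    rng = np.random.default_rng(seed)
    secs = np.array(["reward_RF", "target_arm", "other_RF", "other"])[:n_sections]
    rows = []
    for c in range(n_cycles):
        sec = secs[rng.integers(len(secs))]
        k = int(np.nonzero(secs == sec)[0][0])
        for _ in range(rng.integers(1, 4)):
            rows.append(dict(
                gamma_amplitude=rng.lognormal(0, 0.3),
                gamma_frequency=float(np.clip(rng.normal(80 + shift * k, 18), 30, 200)),
                gamma_phase=rng.uniform(0, 360),
                theta_amplitude=rng.normal(1, 0.2),
                theta_frequency=rng.normal(8, 0.7),
                theta_asymmetry=rng.lognormal(0, 0.2),
                channel=3, layer="rad", trial=c // 50, cycle_id=c,
                section=sec, section_alt=sec, speed=rng.uniform(2, 40)))
    return pd.DataFrame(rows)


@pytest.fixture
def element_table():
    return make_element_table


@pytest.fixture
def small_decoder_config():
    return decode.DecoderConfig(max_learners=60, seed=0)
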