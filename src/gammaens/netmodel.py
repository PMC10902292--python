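"""Theta-driven quadratic integrate-and-fire (QIF) excitatory-inhibitory
network, model LFP synthesis, dynamic-regime indicators, and decoding of
single-neuron spiking from gamma elements.

The network holds n neurons (80% excitatory), each integrating
``tau_m dv/dt = v^2 + I_j + I_theta(t) + synaptic delta pulses``; a spike is
registered when v crosses +v_b and v resets to -v_b (the escape-time
correction to infinity is omitted; v_b is configurable and large).  Within-
population connectivity is random and quenched with Gaussian in-degrees
(mean K, SD Delta), cross-population coupling is all-to-all.  Excitabilities
are Gaussian; currents scale as I = I_0 sqrt(K) and couplings as
g = g_0 / sqrt(K), the balanced-network scaling.  The theta drive is
``A sqrt(K) cos(2 pi nu t)`` with nu = 10 Hz.

The model LFP is the sum over excitatory neurons of |AMPA| + |GABA| currents,
each a difference of exponentials driven by presynaptic spikes through
auxiliary first-order kinetics (rise 0.4 / 0.25 ms, decay 2 / 5 ms), then
high-pass filtered at 1 Hz with a 4th-order Butterworth filter.  Because the
I-to-E coupling is all-to-all, the GABA current is identical across
excitatory neurons and is integrated once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.signal import butter, filtfilt, welch

from . import decode as _decode
from .gammael import characterize_element, detect_patches
from .lfp import SPEC_FREQS, wavelet_amplitude
from .thetacycles import ThetaCycle, build_cycle_snippet


@dataclass
class NetworkParams:
    """Full parameterization of the QIF E-I network."""

    n: int = 2000
    frac_E: float = 0.8
    tau_E: float = 10.0        # ms
    tau_I: float = 4.5         # ms
    I0_E: float = 0.3
    I0_I: float = 0.25
    D_E: float | None = None   # default 0.1 * I0_E
    D_I: float | None = None   # default I0_I
    K: float = 20.0
    delta_EE: float | None = None  # default 2 K (final-value reading)
    delta_II: float | None = None  # default 0.2 K
    g0_EE: float = 0.27
    g0_II: float = 0.0144
    g0_EI: float = 0.01
    g0_IE: float = 0.01
    gii_reading: str = "small"  # "small": g0_II=1.44*g0_EI; "large": g0_II=1.44
    theta_A: float = 0.042
    theta_nu: float = 10.0     # Hz
    v_b: float = 100.0
    dt_ms: float = 0.001
    seed: int = 0
    tau_rA: float = 0.4
    tau_rG: float = 0.25
    tau_dA: float = 2.0
    tau_dG: float = 5.0

    def __post_init__(self) -> None:
        if self.tau_E <= 0 or self.tau_I <= 0:
            raise ValueError("time constants must be positive")
        if not (0 < self.frac_E < 1):
            raise ValueError("frac_E must be in (0, 1)")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.D_E is None:
            self.D_E = 0.1 * self.I0_E
        if self.D_I is None:
            self.D_I = self.I0_I
        if self.delta_EE is None:
            self.delta_EE = 2.0 * self.K
        if self.delta_II is None:
            self.delta_II = 0.2 * self.K
        if self.gii_reading == "small":
            self.g0_II = 1.44 * self.g0_EI
        elif self.gii_reading == "large":
            self.g0_II = 1.44
        else:
            raise ValueError("gii_reading must be 'small' or 'large'")

    @property
    def n_E(self) -> int:
        return int(round(self.n * self.frac_E))

    @property
    def n_I(self) -> int:
        return self.n - self.n_E


def qif_tonic_rate(I: float, tau_ms: float) -> float:
    """Closed-form firing rate (Hz) of an uncoupled suprathreshold QIF neuron:
    period pi * tau / sqrt(I) for threshold/reset at +/- infinity."""
    if I <= 0:
        return 0.0
    return np.sqrt(I) * 1000.0 / (np.pi * tau_ms)


def _quenched_csr(n_pop: int, K: float, delta: float,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Random within-population connectivity with Gaussian in-degrees.

    In-degrees are drawn N(K, delta), rounded and truncated to [1, n_pop - 1];
    presynaptic partners are drawn without replacement excluding self.
    Returns CSR (indptr, targets) indexed by *presynaptic* neuron.
    """
    pre_of: list[list[int]] = [[] for _ in range(n_pop)]
    for j in range(n_pop):
        k = int(np.clip(round(rng.normal(K, delta)), 1, n_pop - 1))
        others = np.delete(np.arange(n_pop), j)
        pres = rng.choice(others, size=k, replace=False)
        for p in pres:
            pre_of[p].append(j)
    indptr = np.zeros(n_pop + 1, dtype=np.int64)
    for p in range(n_pop):
        indptr[p + 1] = indptr[p] + len(pre_of[p])
    targets = np.empty(indptr[-1], dtype=np.int64)
    for p in range(n_pop):
        targets[indptr[p]:indptr[p + 1]] = pre_of[p]
    return indptr, targets


@njit(cache=True)
def _run(vE, vI, IE, II, tauE, tauI, gEE, gII, gEI, gIE,
         ee_indptr, ee_tgt, ii_indptr, ii_tgt,
         A_eff, nu, dt, n_steps, vb,
         tau_rA, tau_dA, tau_rG, tau_dG,
         out_stride, spike_ids, spike_times):
    nE = vE.shape[0]
    nI = vI.shape[0]
    n_out = n_steps // out_stride
    lfp = np.zeros(n_out)
    mean_vI = np.zeros(n_out)
    xA = np.zeros(nE)
    IA = np.zeros(nE)
    xG = 0.0
    IG = 0.0
    jump_A = 2.0 * tauE * gEE / tau_rA
    jump_G = 2.0 * tauE * gEI / tau_rG
    max_spikes = spike_ids.shape[0]
    n_spikes = 0
    two_pi_nu = 2.0 * np.pi * nu * 0.001  # per ms

    for step in range(n_steps):
        t = step * dt
        Ith = A_eff * np.cos(two_pi_nu * t)
        for j in range(nE):
            v = vE[j]
            vE[j] = v + dt * (v * v + IE[j] + Ith) / tauE
        for j in range(nI):
            v = vI[j]
            vI[j] = v + dt * (v * v + II[j] + Ith) / tauI
        for j in range(nE):
            IA[j] += dt * (-IA[j] + xA[j]) / tau_dA
            xA[j] += dt * (-xA[j]) / tau_rA
        IG += dt * (-IG + xG) / tau_dG
        xG += dt * (-xG) / tau_rG

        e_kick = 0.0
        i_kick = 0.0
        xg_kick = 0.0
        for j in range(nE):
            if vE[j] >= vb:
                vE[j] = -vb
                if n_spikes < max_spikes:
                    spike_ids[n_spikes] = j
                    spike_times[n_spikes] = t
                n_spikes += 1
                for m in range(ee_indptr[j], ee_indptr[j + 1]):
                    tgt = ee_tgt[m]
                    vE[tgt] += 2.0 * gEE
                    xA[tgt] += jump_A
                i_kick += 2.0 * gIE
        for j in range(nI):
            if vI[j] >= vb:
                vI[j] = -vb
                if n_spikes < max_spikes:
                    spike_ids[n_spikes] = nE + j
                    spike_times[n_spikes] = t
                n_spikes += 1
                for m in range(ii_indptr[j], ii_indptr[j + 1]):
                    vI[ii_tgt[m]] -= 2.0 * gII
                e_kick += 2.0 * gEI
                xg_kick += jump_G
        if i_kick != 0.0:
            for j in range(nI):
                vI[j] += i_kick
        if e_kick != 0.0:
            for j in range(nE):
                vE[j] -= e_kick
        xG += xg_kick

        if step % out_stride == 0:
            oi = step // out_stride
            acc = 0.0
            for j in range(nE):
                acc += abs(IA[j])
            lfp[oi] = acc + nE * abs(IG)
            s = 0.0
            for j in range(nI):
                s += vI[j]
            mean_vI[oi] = s / nI
    return lfp, mean_vI, n_spikes


@dataclass
class SimResult:
    """Spike raster, model LFP and membrane summaries of one simulation."""

    params: NetworkParams
    duration_ms: float
    spike_times: np.ndarray    # ms, sorted
    spike_ids: np.ndarray      # 0..nE-1 excitatory, then inhibitory
    lfp_raw: np.ndarray        # pre-filter |I_A|+|I_G| at fs_out
    lfp: np.ndarray            # 1 Hz high-passed
    mean_vI: np.ndarray        # population-mean inhibitory potential at fs_out
    fs_out: float = 1000.0

    @property
    def n_E(self) -> int:
        return self.params.n_E

    def e_rates(self) -> np.ndarray:
        """Firing rate (Hz) of each excitatory neuron."""
        nE = self.n_E
        counts = np.bincount(self.spike_ids[self.spike_ids < nE], minlength=nE)
        return counts / (self.duration_ms / 1000.0)

    def spikes_of(self, neuron: int) -> np.ndarray:
        return self.spike_times[self.spike_ids == neuron]


def simulate_network(params: NetworkParams, duration_ms: float,
                     fs_out: float = 1000.0) -> SimResult:
    """Euler-integrate the network and synthesize the model LFP.

    Deterministic given ``params.seed`` (quenched disorder plus deterministic
    integration).  Output traces are sampled at ``fs_out``.
    """
    rng = np.random.default_rng(params.seed)
    nE, nI = params.n_E, params.n_I
    sqK = np.sqrt(params.K)
    IE = rng.normal(params.I0_E, params.D_E, nE) * sqK
    II = rng.normal(params.I0_I, params.D_I, nI) * sqK
    gEE = params.g0_EE / sqK
    gII = params.g0_II / sqK
    gEI = params.g0_EI / sqK
    gIE = params.g0_IE / sqK
    ee_indptr, ee_tgt = _quenched_csr(nE, params.K, params.delta_EE, rng)
    ii_indptr, ii_tgt = _quenched_csr(nI, params.K, params.delta_II, rng)
    # start below v = 0 so subthreshold (I < 0) networks stay at rest
    vE = rng.uniform(-1.0, 0.0, nE)
    vI = rng.uniform(-1.0, 0.0, nI)

    dt = params.dt_ms
    n_steps = int(round(duration_ms / dt))
    out_stride = max(1, int(round(1000.0 / (fs_out * dt))))
    max_spikes = int(params.n * duration_ms / 1000.0 * 400) + 1000
    spike_ids = np.empty(max_spikes, dtype=np.int64)
    spike_times = np.empty(max_spikes, dtype=np.float64)

    lfp_raw, mean_vI, n_spikes = _run(
        vE, vI, IE, II, params.tau_E, params.tau_I, gEE, gII, gEI, gIE,
        ee_indptr, ee_tgt, ii_indptr, ii_tgt,
        params.theta_A * sqK, params.theta_nu, dt, n_steps, params.v_b,
        params.tau_rA, params.tau_dA, params.tau_rG, params.tau_dG,
        out_stride, spike_ids, spike_times)
    if not np.all(np.isfinite(lfp_raw)):
        raise FloatingPointError(
            "integration unstable (non-finite LFP); reduce dt_ms")
    if n_spikes > max_spikes:
        warnings.warn("spike buffer saturated; raster truncated")
        n_spikes = max_spikes
    b, a = butter(4, 1.0, btype="highpass", fs=fs_out)
    lfp = filtfilt(b, a, lfp_raw) if len(lfp_raw) > 20 else lfp_raw.copy()
    return SimResult(params=params, duration_ms=duration_ms,
                     spike_times=spike_times[:n_spikes].copy(),
                     spike_ids=spike_ids[:n_spikes].copy(),
                     lfp_raw=lfp_raw, lfp=lfp, mean_vI=mean_vI, fs_out=fs_out)


def synthesize_model_lfp(params: NetworkParams, raster_times_ms: np.ndarray,
                         raster_ids: np.ndarray, duration_ms: float,
                         ee_drive_counts: np.ndarray | None = None,
                         fs_out: float = 1000.0) -> np.ndarray:
    """Stand-alone double-exponential LFP synthesis from an arbitrary raster.

    Each presynaptic spike of an excitatory (inhibitory) neuron injects a
    rise/decay double-exponential AMPA (GABA) current into its targets; the
    LFP is the sum of current magnitudes over the excitatory population.
    Connectivity detail is reduced to the effective per-spike drive: by
    default every E spike drives K excitatory targets and every I spike all of
    them (the all-to-all cross coupling).  Mostly useful for closed-form
    impulse-response checks; `simulate_network` computes the LFP in-line.
    """
    sqK = np.sqrt(params.K)
    nE = params.n_E
    dt = 1000.0 / fs_out
    n = int(round(duration_ms / dt))
    jump_A = 2.0 * params.tau_E * (params.g0_EE / sqK) / params.tau_rA
    jump_G = 2.0 * params.tau_E * (params.g0_EI / sqK) / params.tau_rG
    drive_A = np.zeros(n)
    drive_G = np.zeros(n)
    fan_E = params.K if ee_drive_counts is None else None
    for t, i in zip(raster_times_ms, raster_ids):
        b = int(t / dt)
        if b >= n:
            continue
        if i < nE:
            fan = fan_E if fan_E is not None else ee_drive_counts[int(i)]
            drive_A[b] += jump_A * fan
        else:
            drive_G[b] += jump_G * nE
    def propagate(drive: np.ndarray, tau_r: float, tau_d: float) -> np.ndarray:
        # exact two-exponential propagation between impulses
        er, ed = np.exp(-dt / tau_r), np.exp(-dt / tau_d)
        c = tau_r / (tau_r - tau_d)
        x, I = 0.0, 0.0
        out = np.zeros(n)
        for b in range(n):
            x += drive[b]
            out[b] = I
            I = (I - c * x) * ed + c * x * er
            x *= er
        return out

    IA = propagate(drive_A, params.tau_rA, params.tau_dA)
    IG = propagate(drive_G, params.tau_rG, params.tau_dG)
    return np.abs(IA) + np.abs(IG)


def double_exp_impulse(t_ms: np.ndarray, tau_r: float, tau_d: float,
                       amplitude: float) -> np.ndarray:
    """Closed-form response of the auxiliary-variable pair to one input pulse:
    x jumps by ``amplitude`` and relaxes with tau_r; I follows with tau_d."""
    t = np.asarray(t_ms, dtype=float)
    out = amplitude * tau_r / (tau_d - tau_r) * (
        np.exp(-t / tau_d) - np.exp(-t / tau_r))
    out[t < 0] = 0.0
    return out


# ---------------------------------------------------------------- indicators

GAMMA_FMIN, GAMMA_FMAX, GAMMA_DF = 25.0, 125.0, 0.1


def _band_psd(signal: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    nper = int(round(10.0 * fs))  # 0.1 Hz resolution
    if len(signal) < nper:
        raise ValueError("need at least 10 s of signal for 0.1 Hz resolution")
    f, p = welch(signal, fs=fs, window="boxcar", nperseg=nper, noverlap=0)
    m = (f >= GAMMA_FMIN) & (f < GAMMA_FMAX)
    return f[m], p[m]


def spectral_entropy(signal: np.ndarray, fs: float = 1000.0) -> float:
    """Normalized Shannon entropy of the 25-125 Hz power density (0.1 Hz grid).

    1 for spectrally flat band power, near 0 for a single line.
    """
    f, p = _band_psd(signal, fs)
    total = p.sum()
    if total <= 0:
        raise ValueError("zero power in the gamma band")
    p = p / total
    nz = p > 0
    M = int(round((GAMMA_FMAX - GAMMA_FMIN) / GAMMA_DF))
    return float(-np.sum(p[nz] * np.log2(p[nz])) / np.log2(M))


def gamma_power_ratio(signal: np.ndarray, fs: float = 1000.0) -> float:
    """r_gamma = (P_low - P_high) / (P_high + P_low), bands 25-50 / 50-100 Hz."""
    f, p = _band_psd(signal, fs)
    p_low = p[(f >= 25.0) & (f < 50.0)].sum()
    p_high = p[(f >= 50.0) & (f < 100.0)].sum()
    if p_low + p_high <= 0:
        raise ValueError("zero power in both gamma bands")
    return float((p_low - p_high) / (p_high + p_low))


def band_peak_frequency(signal: np.ndarray, fs: float = 1000.0) -> float:
    f, p = _band_psd(signal, fs)
    return float(f[np.argmax(p)])


def spike_train_entropy(rate_hz: float, gamma_freq_hz: float) -> float:
    """Binary entropy (bits) of per-gamma-cycle firing probability
    p = rate / gamma frequency."""
    p = rate_hz / gamma_freq_hz
    if p > 1.0:
        warnings.warn("rate exceeds gamma frequency; clipping p to 1")
        p = 1.0
    p = min(max(p, 0.0), 1.0)
    if p in (0.0, 1.0):
        return 0.0
    return float(-p * np.log2(p) - (1 - p) * np.log2(1 - p))


def phase_concentration(phases_rad: np.ndarray) -> float:
    """Modulus of the mean unit phasor of spike theta phases, in [0, 1]."""
    ph = np.asarray(phases_rad, dtype=float)
    if len(ph) == 0:
        raise ValueError("no spikes")
    return float(np.abs(np.mean(np.exp(-1j * ph))))


def regime_indicators(sim: SimResult) -> dict:
    """Spectral entropy, r_gamma, inhibitory mean-potential SD and mean
    excitatory spike-train entropy of one simulation (first second dropped as
    transient)."""
    fs = sim.fs_out
    skip = int(fs)  # 1 s transient
    lfp = sim.lfp[skip:]
    ent = spectral_entropy(lfp, fs)
    r = gamma_power_ratio(lfp, fs)
    v_sd = float(np.std(sim.mean_vI[skip:]))
    f_gamma = band_peak_frequency(lfp, fs)
    rates = sim.e_rates()
    spk_ent = float(np.mean([spike_train_entropy(r_, f_gamma) for r_ in rates]))
    return {"spectral_entropy": ent, "r_gamma": r, "mean_vI_sd": v_sd,
            "spike_entropy": spk_ent, "gamma_peak_hz": f_gamma}


def sweep_regimes(K_values, g0_IE_values, base: NetworkParams,
                  duration_ms: float = 20000.0, dt_ms: float | None = None,
                  n: int | None = None) -> pd.DataFrame:
    """Grid scan over within-population connectivity K and I-to-E coupling.

    Per grid point the four regime indicators are computed; failed points are
    recorded with NaNs.
    """
    from dataclasses import replace
    rows = []
    for K in K_values:
        for gIE in g0_IE_values:
            p = replace(base, K=float(K), g0_IE=float(gIE),
                        delta_EE=None, delta_II=None,
                        dt_ms=dt_ms or base.dt_ms, n=n or base.n)
            try:
                sim = simulate_network(p, duration_ms)
                ind = regime_indicators(sim)
            except (FloatingPointError, ValueError) as exc:
                warnings.warn(f"grid point K={K}, g0_IE={gIE} failed: {exc}")
                ind = {k: np.nan for k in ("spectral_entropy", "r_gamma",
                                           "mean_vI_sd", "spike_entropy",
                                           "gamma_peak_hz")}
            rows.append({"K": K, "g0_IE": gIE, **ind})
    return pd.DataFrame(rows)


# --------------------------------------------- decoding spiking from elements

def forcing_theta_cycles(n_samples: int, fs: float, nu: float) -> list[ThetaCycle]:
    """Theta cycles taken from the known sinusoidal forcing phase.

    The model has no fissure channel, so cycle landmarks come from the
    10 Hz drive: peaks at multiples of the period, trough midway, flanks at
    the quarter points.
    """
    period = fs / nu
    cycles = []
    k = 0
    while (k + 1) * period < n_samples:
        p0 = int(round(k * period))
        p1 = int(round((k + 1) * period))
        cycles.append(ThetaCycle(
            start_peak=p0, desc_flank=p0 + (p1 - p0) // 4,
            trough=p0 + (p1 - p0) // 2, asc_flank=p0 + 3 * (p1 - p0) // 4,
            end_peak=p1, fs=fs, amplitude=1.0, duration_ms=(p1 - p0) / fs * 1e3,
            frequency=nu, asymmetry=1.0))
        k += 1
    return cycles


def extract_model_elements(lfp_signal: np.ndarray, fs: float = 1000.0,
                           nu: float = 10.0,
                           max_count: int = 4) -> pd.DataFrame:
    """Run the wavelet / snippet / patch pipeline on the model LFP.

    Returns one row per gamma element with the six features, the host cycle id
    and the element time (ms) at which its phase occurs within the cycle.
    """
    spec = wavelet_amplitude(lfp_signal, fs=fs)
    cycles = forcing_theta_cycles(len(lfp_signal), fs, nu)
    snippets = [build_cycle_snippet(spec, c) for c in cycles]
    rows = []
    for i, (c, s) in enumerate(zip(cycles, snippets)):
        prev = snippets[i - 1] if i > 0 else None
        nxt = snippets[i + 1] if i < len(snippets) - 1 else None
        for patch in detect_patches(s, neighbors=(prev, nxt), max_count=max_count):
            el = characterize_element(patch, c, cycle_id=i)
            t_ms = (c.start_peak + el.gamma_phase / 360.0 * (c.end_peak - c.start_peak)) / fs * 1e3
            rows.append({**{k: getattr(el, k) for k in
                            ("gamma_amplitude", "gamma_frequency", "gamma_phase",
                             "theta_amplitude", "theta_frequency", "theta_asymmetry")},
                         "cycle_id": i, "time_ms": t_ms})
    return pd.DataFrame(rows)


def decode_spiking(sim: SimResult, elements: pd.DataFrame | None = None,
                   neurons: np.ndarray | None = None,
                   window_ms: float = 100.0, n_estimators: int = 100,
                   max_splits: int = 500, learn_rate: float = 0.01,
                   n_folds: int = 4, seed: int = 0,
                   skip_ms: float = 1000.0) -> pd.DataFrame:
    """Per-neuron spike-presence decoding from single gamma elements.

    For each excitatory neuron a balanced boosted-tree binary classifier
    predicts whether the neuron fired inside a ``window_ms`` chunk of its
    binarized spike train centered on the element time, from the element's
    feature vector alone.  Evaluated with cycle-grouped cross-validation.
    Returns TP/TN/FP/FN fractions, precision, recall, the decodable flag
    (TP > 0.6 and TN > 0.6) and the theta phase concentration of the neuron's
    spikes.  Neurons whose labels are single-class are skipped (flagged NaN).
    """
    if elements is None:
        elements = extract_model_elements(sim.lfp, fs=sim.fs_out,
                                          nu=sim.params.theta_nu)
    elements = elements[elements["time_ms"] >= skip_ms].reset_index(drop=True)
    if len(elements) == 0:
        raise ValueError("no gamma elements to decode from")
    med_f = float(np.median(elements["gamma_frequency"]))
    bin_ms = max(1.0, round(1000.0 / med_f))
    n_bins = int(np.ceil(sim.duration_ms / bin_ms))
    half_chunk = int(round(window_ms / 2.0 / bin_ms))
    el_bins = (elements["time_ms"].to_numpy() / bin_ms).astype(int)

    feats = elements[["gamma_amplitude", "gamma_frequency", "gamma_phase",
                      "theta_amplitude", "theta_frequency", "theta_asymmetry"]]
    X = feats.to_numpy(dtype=float)
    groups = elements["cycle_id"].to_numpy()

    if neurons is None:
        neurons = np.arange(sim.n_E)
    omega = 2 * np.pi * sim.params.theta_nu / 1000.0  # rad per ms
    rows = []
    for ni, neuron in enumerate(neurons):
        st = sim.spikes_of(int(neuron))
        row = {"neuron": int(neuron), "n_spikes": len(st)}
        if len(st) == 0:
            rows.append({**row, "tp": np.nan, "tn": np.nan, "precision": np.nan,
                         "recall": np.nan, "decodable": False, "phi": np.nan,
                         "skipped": "no_spikes"})
            continue
        row["phi"] = phase_concentration(omega * st)
        train = np.zeros(n_bins, dtype=bool)
        train[np.minimum((st / bin_ms).astype(int), n_bins - 1)] = True
        cum = np.concatenate([[0], np.cumsum(train)])
        lo = np.maximum(el_bins - half_chunk, 0)
        hi = np.minimum(el_bins + half_chunk + 1, n_bins)
        y = (cum[hi] - cum[lo]) > 0

        if y.all() or not y.any():
            rows.append({**row, "tp": 1.0 if y.all() else np.nan,
                         "tn": np.nan if y.all() else 1.0,
                         "precision": np.nan, "recall": np.nan,
                         "decodable": False, "skipped": "single_class"})
            continue
        # cycle-grouped CV
        from sklearn.model_selection import GroupKFold
        pred = np.zeros(len(y), dtype=bool)
        ok = True
        min_groups = min(len(np.unique(groups[y])), len(np.unique(groups[~y])))
        if min_groups < n_folds:
            rows.append({**row, "tp": np.nan, "tn": np.nan, "precision": np.nan,
                         "recall": np.nan, "decodable": False,
                         "skipped": "too_few_cycles"})
            continue
        for k, (tr, te) in enumerate(GroupKFold(n_splits=n_folds)
                                     .split(X, y, groups)):
            if len(np.unique(y[tr])) < 2:
                ok = False
                break
            clf = _decode.RUSBoostClassifier(
                n_estimators=n_estimators, learning_rate=learn_rate,
                max_splits=max_splits, random_state=seed + 31 * ni + k)
            clf.fit(X[tr], y[tr])
            pred[te] = clf.predict(X[te])
        if not ok:
            rows.append({**row, "tp": np.nan, "tn": np.nan, "precision": np.nan,
                         "recall": np.nan, "decodable": False,
                         "skipped": "fold_single_class"})
            continue
        tp = int(np.sum(pred & y))
        tn = int(np.sum(~pred & ~y))
        fp = int(np.sum(pred & ~y))
        fn = int(np.sum(~pred & y))
        tp_frac = tp / (tp + fn)
        tn_frac = tn / (tn + fp)
        rows.append({**row,
                     "tp": tp_frac, "tn": tn_frac,
                     "precision": tp / (tp + fp) if tp + fp else np.nan,
                     "recall": tp_frac,
                     "decodable": bool(tp_frac > 0.6 and tn_frac > 0.6),
                     "skipped": ""})
    return pd.DataFrame(rows)
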