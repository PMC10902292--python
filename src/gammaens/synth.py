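"""Synthetic behavior tracks and multichannel LFP with known gamma-burst truth.

This module emulates the study conditions of a mouse navigating an eight-arm
radial maze while laminar LFP is recorded across the CA1-dentate axis: a
20 Hz position/speed track with maze-section labels, and a 1 kHz multichannel
signal built from a depth-profiled theta carrier (peak amplitude at a
designated "fissure" channel, 180 deg phase flip superficial to the pyramidal
layer), transient theta-nested gamma bursts injected per channel with
configurable frequency / theta-phase / amplitude distributions, and white
noise.  Burst statistics can be modulated by the maze section occupied at
injection time, which is what gives downstream decoders something to find.
Every injected burst is logged to a ground-truth table so detection stages can
be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .lfp import MultichannelLFP

SECTIONS = ("reward_RF", "target_arm", "other_RF", "other")


@dataclass
class MazeGeometry:
    """Eight-arm radial maze: arms of ``arm_cm`` around a central platform."""

    n_arms: int = 8
    arm_cm: float = 55.0
    center_radius_cm: float = 26.0
    reward_field_cm: float = 10.0  # terminal stretch of each arm
    target_arm: int = 0

    def __post_init__(self) -> None:
        if self.n_arms < 2:
            raise ValueError("need at least 2 arms")
        angles = np.arange(self.n_arms) * 2 * np.pi / self.n_arms
        if len(np.unique(np.round(angles, 9))) != self.n_arms:
            raise ValueError("invalid geometry: overlapping arms")
        self.angles = angles

    def arm_xy(self, arm: int, r: float) -> tuple[float, float]:
        a = self.angles[arm % self.n_arms]
        return r * np.cos(a), r * np.sin(a)

    def section_of(self, arm: int | None, r: float) -> str:
        """Maze section for a point at radius ``r`` on ``arm`` (None = center)."""
        if arm is None or r <= self.center_radius_cm:
            return "other"
        outer = self.center_radius_cm + self.arm_cm
        in_rf = r >= outer - self.reward_field_cm
        if arm % self.n_arms == self.target_arm:
            return "reward_RF" if in_rf else "target_arm"
        return "other_RF" if in_rf else "other"


@dataclass
class BehaviorTrack:
    """20 Hz position/speed track with maze-section labels."""

    df: pd.DataFrame  # columns: time, x, y, speed, section, trial_index, day_index
    fs: float = 20.0

    @property
    def time(self) -> np.ndarray:
        return self.df["time"].to_numpy()

    @property
    def speed(self) -> np.ndarray:
        return self.df["speed"].to_numpy()

    @property
    def section(self) -> np.ndarray:
        return self.df["section"].to_numpy()

    def section_at(self, t: float) -> str:
        idx = int(np.clip(round(t * self.fs), 0, len(self.df) - 1))
        return self.df["section"].iat[idx]

    def speed_in(self, t0: float, t1: float) -> float:
        m = (self.time >= t0) & (self.time <= t1)
        if not m.any():
            idx = int(np.clip(round(0.5 * (t0 + t1) * self.fs), 0, len(self.df) - 1))
            return float(self.df["speed"].iat[idx])
        return float(self.df["speed"][m].mean())


def generate_behavior(
    maze: MazeGeometry | None = None,
    n_trials: int = 40,
    n_days: int = 10,
    seed: int | None = 0,
    mean_speed: float = 15.0,
    speed_cap: float = 90.0,
    detours_first_day: float = 4.0,
    detours_last_day: float = 0.3,
    reward_dwell_s: float = 2.0,
    fs: float = 20.0,
) -> BehaviorTrack:
    """Random-walk-with-goal trajectory over ``n_trials`` spread over ``n_days``.

    Each trial departs from one of the four arms two or three positions away
    from the target, wanders through a day-dependent number of detour arms
    (linearly fewer with training, so latency to reward falls across days) and
    ends with a dwell at the reward field.  Positions are sampled at ``fs`` Hz;
    speed is recomputed from positions by central differences and a 0.5 s
    moving average, capped at ``speed_cap``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    maze = maze or MazeGeometry()
    rng = np.random.default_rng(seed)
    departures = [(maze.target_arm + k) % maze.n_arms for k in (-3, -2, 2, 3)]
    outer = maze.center_radius_cm + maze.arm_cm

    frames = []
    t_offset = 0.0
    for trial in range(n_trials):
        day = trial * n_days // n_trials
        frac = day / max(1, n_days - 1)
        lam = detours_first_day + (detours_last_day - detours_first_day) * frac
        n_detours = rng.poisson(lam)
        arms_visited = [departures[rng.integers(len(departures))]]
        for _ in range(n_detours):
            choices = [a for a in range(maze.n_arms)
                       if a != maze.target_arm and a != arms_visited[-1]]
            arms_visited.append(choices[rng.integers(len(choices))])
        arms_visited.append(maze.target_arm)

        # piecewise path: arm end -> center -> (detour arm ends ...) -> reward
        waypoints: list[tuple[float, float]] = [maze.arm_xy(arms_visited[0], outer)]
        arms_of_leg: list[int | None] = []
        for a_prev, a_next in zip(arms_visited[:-1], arms_visited[1:]):
            waypoints.append(maze.arm_xy(a_prev, 0.6 * maze.center_radius_cm))
            waypoints.append(maze.arm_xy(a_next, 0.6 * maze.center_radius_cm))
            waypoints.append(maze.arm_xy(a_next, outer - 0.3 * maze.reward_field_cm))
            arms_of_leg += [a_prev, None, a_next]

        # walk the polyline with an Ornstein-Uhlenbeck speed profile
        xs, ys, arm_ids = [], [], []
        v = mean_speed
        leg, s = 0, 0.0
        px, py = waypoints[0]
        while leg < len(waypoints) - 1:
            xs.append(px)
            ys.append(py)
            arm_ids.append(arms_of_leg[min(leg, len(arms_of_leg) - 1)])
            v += 0.2 * (mean_speed - v) / fs + rng.normal(0, 4.0 / np.sqrt(fs))
            v = float(np.clip(v, 2.0, speed_cap * 0.9))
            step = v / fs
            while step > 0 and leg < len(waypoints) - 1:
                ax, ay = waypoints[leg]
                bx, by = waypoints[leg + 1]
                seg = np.hypot(bx - ax, by - ay)
                remain = seg - s
                if step < remain:
                    s += step
                    step = 0.0
                else:
                    step -= remain
                    leg += 1
                    s = 0.0
            if leg < len(waypoints) - 1:
                ax, ay = waypoints[leg]
                bx, by = waypoints[leg + 1]
                seg = np.hypot(bx - ax, by - ay)
                u = s / seg if seg > 0 else 0.0
                px, py = ax + u * (bx - ax), ay + u * (by - ay)
            else:
                px, py = waypoints[-1]
        # reward dwell
        n_dwell = int(reward_dwell_s * fs)
        xs += [px] * n_dwell
        ys += [py] * n_dwell
        arm_ids += [maze.target_arm] * n_dwell

        xs, ys = np.asarray(xs), np.asarray(ys)
        r = np.hypot(xs, ys)
        sections = [maze.section_of(a, ri) for a, ri in zip(arm_ids, r)]
        # alternative labeling: target arm demoted to "other", the arm
        # opposite the target promoted to its own class
        alt_arm = (maze.target_arm + maze.n_arms // 2) % maze.n_arms
        sections_alt = []
        for a, ri, sec in zip(arm_ids, r, sections):
            if sec == "reward_RF":
                sections_alt.append("reward_RF")
            elif a == alt_arm and ri > maze.center_radius_cm:
                sections_alt.append("alternative_arm")
            elif sec == "other_RF":
                sections_alt.append("other_RF")
            else:
                sections_alt.append("other")
        n = len(xs)
        frames.append(pd.DataFrame({
            "time": t_offset + np.arange(n) / fs,
            "x": xs, "y": ys,
            "section": sections,
            "section_alt": sections_alt,
            "arm": [-1 if a is None else a for a in arm_ids],
            "trial_index": trial,
            "day_index": day,
        }))
        t_offset += n / fs

    df = pd.concat(frames, ignore_index=True)
    # speed from positions: central differences then 0.5 s moving average
    vx = np.gradient(df["x"].to_numpy()) * fs
    vy = np.gradient(df["y"].to_numpy()) * fs
    raw = np.hypot(vx, vy)
    w = max(1, int(round(0.5 * fs)))
    speed = np.convolve(raw, np.ones(w) / w, mode="same")
    df["speed"] = np.clip(speed, 0.0, speed_cap)
    return BehaviorTrack(df=df, fs=fs)


def trial_latencies(track: BehaviorTrack) -> pd.Series:
    """Time from trial start to first reward_RF sample, indexed by trial."""
    out = {}
    for trial, g in track.df.groupby("trial_index"):
        hit = g[g["section"] == "reward_RF"]
        t0 = g["time"].iloc[0]
        out[trial] = (hit["time"].iloc[0] - t0) if len(hit) else np.nan
    return pd.Series(out, name="latency_s")


@dataclass
class BurstSpec:
    """Distributions of injected gamma bursts for one channel."""

    freq_mean: float = 80.0
    freq_sd: float = 10.0
    phase_mean_deg: float = 180.0
    phase_sd_deg: float = 40.0
    amp_mean: float = 1.0
    amp_sd: float = 0.15
    rate_per_cycle: float = 1.0
    n_cycles: float = 5.0  # burst envelope width in oscillation cycles
    deterministic_count: bool = False  # exactly round(rate) bursts per cycle

    def __post_init__(self) -> None:
        if not (30.0 <= self.freq_mean <= 250.0):
            raise ValueError("burst frequency must lie within 30-250 Hz")


#: per-section parameter shifts applied to a BurstSpec
ModulationMap = dict[str, dict[str, float]]


def modulate_by_section(spec: BurstSpec, section: str,
                        modulation_map: ModulationMap | None) -> BurstSpec:
    """Shift burst distribution parameters for the current maze section.

    Recognized keys per section: ``freq_shift`` (Hz, additive), ``phase_shift``
    (deg, additive), ``amp_scale`` and ``rate_scale`` (multiplicative).
    Identity when the map is empty or None.
    """
    if not modulation_map:
        return spec
    if section not in SECTIONS:
        raise ValueError(f"unknown section {section!r}")
    mods = modulation_map.get(section)
    if not mods:
        return spec
    return replace(
        spec,
        freq_mean=spec.freq_mean + mods.get("freq_shift", 0.0),
        phase_mean_deg=(spec.phase_mean_deg + mods.get("phase_shift", 0.0)) % 360.0,
        amp_mean=spec.amp_mean * mods.get("amp_scale", 1.0),
        rate_per_cycle=spec.rate_per_cycle * mods.get("rate_scale", 1.0),
    )


@dataclass
class RecordingSpec:
    """Full parameterization of a synthetic laminar recording."""

    n_channels: int = 8
    spacing_mm: float = 0.05
    fs: float = 1000.0
    layer_of_channel: list[str] = field(default_factory=list)
    theta_freq: float = 8.0
    theta_amp: float = 1.0
    theta_asymmetry: float = 1.0     # rise/decay duration ratio
    fissure_channel: int | None = None
    depth_sigma: float = 2.0         # channels; width of theta power profile
    pyr_channel: int | None = None   # phase flips 180 deg above this channel
    burst_specs: dict[int, BurstSpec] = field(default_factory=dict)
    modulation_map: ModulationMap = field(default_factory=dict)
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 3:
            raise ValueError("CSD needs at least 3 channels")
        if self.fissure_channel is None:
            self.fissure_channel = self.n_channels - 2
        if self.pyr_channel is None:
            self.pyr_channel = 1
        if not self.layer_of_channel:
            self.layer_of_channel = self._default_layers()

    def _default_layers(self) -> list[str]:
        layers = []
        for c in range(self.n_channels):
            if c < self.pyr_channel:
                layers.append("or")
            elif c == self.pyr_channel:
                layers.append("pyr")
            elif c == self.fissure_channel:
                layers.append("fissure")
            elif c > self.fissure_channel:
                layers.append("DG")
            elif c >= self.fissure_channel - max(1, (self.fissure_channel - self.pyr_channel) // 3):
                layers.append("l-m")
            else:
                layers.append("rad")
        return layers


def theta_phase_track(n_samples: int, fs: float, freq: float,
                      asymmetry: float) -> np.ndarray:
    """Waveform theta phase (deg) over time for an asymmetric carrier.

    The cycle is a time-warped sinusoid: the descending half (peak to trough,
    0-180 deg) takes ``1/(1+asymmetry)`` of the period and the ascending half
    (trough to peak) the rest, so rise/decay duration ratio = ``asymmetry``.
    """
    t = np.arange(n_samples) / fs
    u = (t * freq) % 1.0
    decay_frac = 1.0 / (1.0 + asymmetry)
    phase = np.where(
        u < decay_frac,
        180.0 * u / decay_frac,
        180.0 + 180.0 * (u - decay_frac) / (1.0 - decay_frac),
    )
    return phase


def _phase_to_cycle_fraction(phase_deg: float, asymmetry: float) -> float:
    """Inverse of the warp: fraction of the cycle at which ``phase_deg`` occurs."""
    decay_frac = 1.0 / (1.0 + asymmetry)
    p = phase_deg % 360.0
    if p < 180.0:
        return p / 180.0 * decay_frac
    return decay_frac + (p - 180.0) / 180.0 * (1.0 - decay_frac)


def generate_recording(
    spec: RecordingSpec, behavior: BehaviorTrack,
    duration: float | None = None,
) -> tuple[MultichannelLFP, pd.DataFrame]:
    """Synthesize the multichannel LFP plus the burst ground-truth table.

    The signal per channel is depth-profiled theta (Gaussian amplitude profile
    over channels peaking at the fissure, sign-flipped superficial to the
    pyramidal channel) + injected Morlet-like gamma bursts + white noise.
    Burst statistics are modulated by the maze section at injection time.
    Returns ``(lfp, ground_truth)`` where the ground truth holds one row per
    injected burst (channel, cycle, time, frequency Hz, theta phase deg,
    amplitude, section).
    """
    duration = duration if duration is not None else float(behavior.time[-1])
    if behavior.time[-1] + 1.0 / behavior.fs < duration:
        raise ValueError("behavior track does not cover the requested duration")
    rng = np.random.default_rng(spec.seed)
    n = int(round(duration * spec.fs))
    t = np.arange(n) / spec.fs

    phase = theta_phase_track(n, spec.fs, spec.theta_freq, spec.theta_asymmetry)
    theta_wave = np.cos(np.deg2rad(phase))
    chan = np.arange(spec.n_channels)
    depth_amp = spec.theta_amp * np.exp(
        -((chan - spec.fissure_channel) ** 2) / (2 * spec.depth_sigma**2))
    sign = np.where(chan < spec.pyr_channel, -1.0, 1.0)  # 180 deg flip above pyr

    samples = theta_wave[:, None] * (depth_amp * sign)[None, :]
    if spec.noise_sd > 0:
        samples = samples + rng.normal(0.0, spec.noise_sd, size=samples.shape)

    period = 1.0 / spec.theta_freq
    n_cycles_total = int(np.floor(duration / period))
    records = []
    for ch, bspec in spec.burst_specs.items():
        for k in range(n_cycles_total):
            t_mid = (k + 0.5) * period
            section = behavior.section_at(t_mid)
            eff = modulate_by_section(bspec, section, spec.modulation_map)
            n_bursts = (int(round(eff.rate_per_cycle)) if eff.deterministic_count
                        else rng.poisson(eff.rate_per_cycle))
            for _ in range(n_bursts):
                f = float(np.clip(rng.normal(eff.freq_mean, eff.freq_sd), 30.0, 250.0))
                ph = float((rng.normal(eff.phase_mean_deg, eff.phase_sd_deg)) % 360.0)
                a = float(max(0.05, rng.normal(eff.amp_mean, eff.amp_sd)))
                frac = _phase_to_cycle_fraction(ph, spec.theta_asymmetry)
                t0 = (k + frac) * period
                sigma_t = eff.n_cycles / (2.0 * np.pi * f)
                half = int(np.ceil(4 * sigma_t * spec.fs))
                i0 = int(round(t0 * spec.fs))
                lo, hi = max(0, i0 - half), min(n, i0 + half + 1)
                if hi <= lo:
                    continue
                tt = t[lo:hi] - t0
                burst = a * np.exp(-(tt**2) / (2 * sigma_t**2)) * np.cos(2 * np.pi * f * tt)
                samples[lo:hi, ch] += burst
                records.append((ch, k, t0, f, ph, a, section))

    gt = pd.DataFrame(records, columns=[
        "channel", "cycle_index", "time", "frequency", "phase", "amplitude", "section"])
    lfp = MultichannelLFP(samples=samples, fs=spec.fs, spacing_mm=spec.spacing_mm,
                          layers=list(spec.layer_of_channel))
    return lfp, gt


def export_ground_truth(gt: pd.DataFrame, path: str) -> None:
    """Write the ground-truth burst table as CSV (round-trips losslessly)."""
    gt.to_csv(path, index=False)


def load_ground_truth(path: str) -> pd.DataFrame:
    return pd.read_csv(path)
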