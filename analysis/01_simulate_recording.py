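"""Generate the synthetic study material: behavior tracks and laminar
recordings with theta-nested gamma bursts.

Writes small tables (behavior, burst ground truth, latencies) under results/
and the raw multichannel recordings (binary + JSON sidecar) under scratch/,
since downstream stages can regenerate them from the same seeds.

Two recordings share identical burst statistics except that the second
modulates burst frequency by maze section, which is the decodable structure
stages 03-04 quantify.
"""

from pathlib import Path

from gammaens import synth

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch" / "synthetic"

BURSTS = synth.BurstSpec(freq_mean=90.0, freq_sd=12.0, phase_mean_deg=180.0,
                         phase_sd_deg=45.0, amp_mean=2.0, amp_sd=0.15,
                         rate_per_cycle=1.0, deterministic_count=True)
MODULATION = {"reward_RF": {"freq_shift": 45.0},
              "target_arm": {"freq_shift": -30.0},
              "other_RF": {"freq_shift": 20.0}}
DURATION_S = 60.0


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)

    behavior = synth.generate_behavior(n_trials=8, n_days=2, seed=3,
                                       mean_speed=25.0, detours_first_day=1.5,
                                       detours_last_day=0.5)
    behavior.df.to_csv(RESULTS / "behavior.csv", index=False)
    lat = synth.trial_latencies(behavior)
    lat.to_csv(RESULTS / "trial_latencies.csv")
    print(f"behavior: {behavior.time[-1]:.1f} s over {lat.index.max() + 1} trials; "
          f"latency first/last trial {lat.iloc[0]:.1f}/{lat.iloc[-1]:.1f} s")

    for name, modulation in [("null", {}), ("modulated", MODULATION)]:
        spec = synth.RecordingSpec(
            n_channels=7, fissure_channel=5, pyr_channel=1, noise_sd=0.02,
            burst_specs={3: BURSTS}, modulation_map=modulation, seed=4)
        rec, gt = synth.generate_recording(spec, behavior, duration=DURATION_S)
        rec.save(str(SCRATCH / f"recording_{name}"))
        synth.export_ground_truth(gt, RESULTS / f"ground_truth_{name}.csv")
        print(f"{name}: {rec.samples.shape[0] / rec.fs:.0f} s x "
              f"{rec.n_channels} channels, {len(gt)} injected bursts")


if __name__ == "__main__":
    main()
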