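"""Decode maze section from single gamma elements.

Uses the element tables from 02: cross-validated performance on the
unmodulated (null) and section-modulated tables, reduced feature sets
(gamma-only / theta-only), quartile-conditioned performance, learning
windows, and cross-classification between the two generative conditions.
Writes CSV/JSON summaries under results/.
"""

import json
from pathlib import Path

import pandas as pd

from gammaens import decode

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    tables = {name: pd.read_csv(RESULTS / f"elements_{name}.csv")
              for name in ("null", "modulated")}
    summary = {}
    reports = {}
    for name, table in tables.items():
        cfg = decode.DecoderConfig(max_learners=100, seed=0)
        rep = decode.evaluate_crossval(table, cfg)
        reports[name] = rep
        summary[name] = {
            "overall": rep.overall, "class_mean": rep.class_mean,
            "chance": rep.chance, "ci": [rep.ci_low, rep.ci_high],
            "per_class": rep.per_class.to_dict(),
        }
        print(f"{name}: correct fraction {rep.overall:.3f} "
              f"(chance {rep.chance:.2f}, 95% CI {rep.ci_low:.3f}-{rep.ci_high:.3f})")
        rep.confusion.to_csv(RESULTS / f"confusion_{name}.csv")

    # reduced feature sets on the modulated table
    for fs in ("gamma", "theta"):
        cfg = decode.DecoderConfig(max_learners=100, feature_set=fs, seed=0)
        rep = decode.evaluate_crossval(tables["modulated"], cfg)
        summary[f"modulated_{fs}_only"] = {"overall": rep.overall,
                                           "chance": rep.chance}
        print(f"modulated, {fs}-only features: {rep.overall:.3f}")

    # quartile-conditioned performance on the modulated table
    cond = decode.conditional_performance(reports["modulated"],
                                          tables["modulated"],
                                          "gamma_amplitude")
    cond.to_csv(RESULTS / "performance_by_amplitude_quartile.csv")
    print("correct fraction by gamma-amplitude quartile:",
          {q: round(v, 3) for q, v in cond["overall"].items()})

    # learning windows over trials
    counts = tables["modulated"].groupby("trial").size()
    windows = decode.make_learning_windows(counts, target=500)
    pd.DataFrame([vars(w) for w in windows]).to_csv(
        RESULTS / "learning_windows.csv", index=False)
    early, late = decode.early_late_split(counts)
    summary["early_trials"], summary["late_trials"] = early, late

    # cross-classification between generative conditions
    cfg = decode.DecoderConfig(max_learners=100, seed=0)
    model = decode.train_location_classifier(tables["modulated"], cfg)
    summary["cross_modulated_to_null"] = decode.cross_classify(
        model, tables["null"])["overall"]
    summary["resub_modulated"] = decode.cross_classify(
        model, tables["modulated"])["overall"]
    print(f"cross-classification modulated->null: "
          f"{summary['cross_modulated_to_null']:.3f} "
          f"(resubstitution {summary['resub_modulated']:.3f})")

    with open(RESULTS / "decoding_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)


if __name__ == "__main__":
    main()
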