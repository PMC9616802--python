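"""Theta peak-frequency slowing with working-memory load.

Simulates a 28-participant cohort whose frontal theta oscillator is 0.08 Hz
slower in the higher-load condition, recovers per-trial most-prominent
peaks on the 0.2 Hz grid, and tests the paired slowing -- also on IRASA
residuals and smoothed spectra -- alongside the load x frequency power
ANOVA with Holm-corrected follow-ups.
"""

import json
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from thetawm import pipeline, synth  # noqa: E402
from thetawm.pipeline import AnalysisConfig  # noqa: E402

RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")


def main():
    os.makedirs(RESULTS, exist_ok=True)
    cfg = AnalysisConfig(master_seed=51)
    sessions, manifest, lay, frontal = synth.simulate_delay_cohort(
        {"1back": synth.ThetaPreset(synth.THETA_MEANS["1back"]),
         "2back": synth.ThetaPreset(synth.THETA_MEANS["2back"])},
        n_participants=28, n_trials=40, master_seed=71)
    out = pipeline.run_slowing(cfg, sessions, frontal)

    out["peak_means"].to_csv(os.path.join(RESULTS, "theta_peak_means.tsv"),
                             sep="\t", index=False)
    out["power_by_freq"].to_csv(
        os.path.join(RESULTS, "theta_power_by_freq.tsv"), sep="\t",
        index=False)
    out["anova"].to_csv(os.path.join(RESULTS, "theta_load_anova.tsv"),
                        sep="\t", index=False)
    payload = {"grand_means": out["grand_means"],
               "slowing": out["slowing"],
               "robustness": out["robustness"],
               "true_means": {"1back": synth.THETA_MEANS["1back"],
                              "2back": synth.THETA_MEANS["2back"]}}
    with open(os.path.join(RESULTS, "theta_slowing_summary.json"), "w") as f:
        json.dump(payload, f, indent=1)

    gm = out["grand_means"]
    s = out["slowing"]
    print(f"recovered grand-mean peaks: 1-back {gm['1back']:.3f} Hz, "
          f"2-back {gm['2back']:.3f} Hz "
          f"(true 5.85 / 5.77)")
    print(f"paired slowing test: t({s['df']}) = {s['t']:.2f}, "
          f"p = {s['p']:.2g}, d = {s['cohens_d']:.2f}")
    ir = out["robustness"]["irasa"]
    print(f"IRASA residual: {ir['mean_a']:.3f} vs {ir['mean_b']:.3f} Hz, "
          f"p = {ir['p']:.2g}")
    for w in cfg.smoothing_windows:
        r = out["robustness"][f"smooth_{w}"]
        print(f"smoothing {w} elements: t = {r['t']:.2f}, p = {r['p']:.2g}")


if __name__ == "__main__":
    main()
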