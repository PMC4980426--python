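#!/usr/bin/env python
"""Intrasegmental phase lag between transverse and longitudinal muscles.

Loads the simulated control muscle traces, estimates multitaper coherency
(NW = 5, K = 7) of each segment's LT2 trace against its LO1 reference at the
reference's dominant frequency, and summarizes the per-segment phases with a
circular mean and 95% CI. With the generator's default 42-degree lag the
mean phase should recover ~42 degrees and every pair should exceed the
alpha = 0.05 coherence-magnitude threshold.
"""

import json
from pathlib import Path

from motorpool.pipeline import run_phase_pipeline

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "phase_control"


def main() -> None:
    config = {
        "seed": 20160803,
        "spectral": {"time_bandwidth": 5, "n_tapers": 7, "alpha": 0.05},
        "conditions": {
            "control": {"traces": str(ROOT / "results" / "data" / "muscle_control.csv")}
        },
        "pairing": "segment",
        "reference_prefix": "LO1",
    }
    report = run_phase_pipeline(config, out_dir=OUT)
    cond = report["conditions"]["control"]
    for pair in cond["pairs"]:
        print(
            f"{pair['test']} vs {pair['reference']}: phase "
            f"{pair['phase_deg']:6.2f} deg at {pair['dominant_frequency_hz']:.3f} Hz, "
            f"|coh| {pair['magnitude']:.3f} "
            f"({'significant' if pair['significant'] else 'n.s.'}, "
            f"threshold {pair['threshold']:.3f})"
        )
    cs = cond["circular_summary"]
    ci = cs["ci95_halfwidth_deg"]
    ci_txt = f" +/- {ci:.1f}" if ci is not None else ""
    print(f"\ncircular mean phase: {cs['mean_phase_deg']:.2f}{ci_txt} deg "
          f"(resultant length {cs['resultant_length']:.3f}, n={cs['n']} segments)")
    print(f"report -> {OUT / 'phase_report.json'}")


if __name__ == "__main__":
    main()
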