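#!/usr/bin/env python
"""Does abolishing the intrasegmental delay change the phase relationship?

Two statistical designs mirror the perturbation experiments:

1. Paired design (within-animal, e.g. before/after a drug): per-animal
   phases under the control lag versus under synchronized contractions;
   Hotelling paired test on the angular shift.
2. Independent-groups design (across genotypes): control versus
   delay-silenced groups of animals; Watson-Williams test for equal mean
   directions.

Each "animal" is an independently seeded simulation; phases come from the
full coherency pipeline, never from the generator's ground truth.
"""

import json
from pathlib import Path

import numpy as np

from motorpool import (
    AngleSample,
    PairedAngleSample,
    PeristalsisConfig,
    hotelling_paired_test,
    phase_relationship,
    simulate_peristalsis,
    watson_williams_test,
)

SEED = 777
OUT = Path(__file__).resolve().parents[1] / "results"


def animal_phase(lag: float, seed: int) -> float:
    cfg = PeristalsisConfig(
        intrasegmental_lag=lag, noise_sd=0.04, n_segments=1, duration=120.0, seed=seed
    )
    traces = {m.label: m.trace for m in simulate_peristalsis(cfg)}
    return phase_relationship(traces["LO1_A1"], traces["LT2_A1"]).phase_degrees


def main() -> None:
    n_animals = 7
    pre = [animal_phase(42.0, SEED + i) for i in range(n_animals)]
    post = [animal_phase(2.0, SEED + 100 + i) for i in range(n_animals)]
    paired = hotelling_paired_test(
        PairedAngleSample(AngleSample(np.array(pre), "pre"), AngleSample(np.array(post), "post"))
    )
    print(f"paired design (n={n_animals}): mean pre {np.mean(pre):.1f} deg, "
          f"mean post {np.mean(post):.1f} deg")
    print(f"  Hotelling paired test: F({paired.df[0]},{paired.df[1]}) = "
          f"{paired.statistic:.2f}, p = {paired.p_value:.2g}")

    control = AngleSample(np.array([animal_phase(42.0, SEED + 200 + i) for i in range(7)]), "control")
    silenced = AngleSample(np.array([animal_phase(2.0, SEED + 300 + i) for i in range(7)]), "silenced")
    ww = watson_williams_test([control, silenced])
    print(f"group design (n=7 vs 7): Watson-Williams F({ww.df[0]},{ww.df[1]}) = "
          f"{ww.statistic:.2f}, p = {ww.p_value:.2g}"
          + (f" [flags: {', '.join(ww.flags)}]" if ww.flags else ""))

    OUT.mkdir(exist_ok=True)
    with open(OUT / "perturbation_tests.json", "w") as fh:
        json.dump(
            {
                "paired": {"pre_deg": pre, "post_deg": post,
                           "F": paired.statistic, "df": paired.df, "p": paired.p_value},
                "groups": {"control_deg": control.angles.tolist(),
                           "silenced_deg": silenced.angles.tolist(),
                           "F": ww.statistic, "df": ww.df, "p": ww.p_value,
                           "flags": list(ww.flags)},
                "multiple_comparison_correction": "none",
            },
            fh, indent=2,
        )
    print(f"results -> {OUT / 'perturbation_tests.json'}")


if __name__ == "__main__":
    main()
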