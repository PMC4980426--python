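#!/usr/bin/env python
"""Generate the synthetic datasets used by the downstream analyses.

Writes, under results/data/:
  - muscle traces for a control condition (42-degree intrasegmental lag)
    and a synchronized condition emulating loss of the inhibitory delay
    (lag ~0), three segments each;
  - calcium-indicator traces for a reference motor neuron and a lagged
    interneuron per segment;
  - a synthetic connectome pair (neuron table + edge list CSVs).
"""

from pathlib import Path

from motorpool import (
    PeristalsisConfig,
    SyntheticConnectomeConfig,
    simulate_calcium_traces,
    simulate_connectome,
    simulate_peristalsis,
    write_traces_csv,
)

SEED = 20160803
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    control = PeristalsisConfig(intrasegmental_lag=42.0, noise_sd=0.04, seed=SEED)
    synchronized = PeristalsisConfig(intrasegmental_lag=2.0, noise_sd=0.04, seed=SEED + 1)
    for name, cfg in (("control", control), ("synchronized", synchronized)):
        sim = simulate_peristalsis(cfg)
        path = OUT / f"muscle_{name}.csv"
        write_traces_csv(path, [m.trace for m in sim])
        print(f"{name}: {len(sim)} muscle traces ({cfg.duration:.0f} s at "
              f"{cfg.sampling_rate:g} Hz, lag {cfg.intrasegmental_lag:g} deg) -> {path.name}")

    calcium = simulate_calcium_traces(control)
    write_traces_csv(OUT / "calcium_control.csv", list(calcium))
    print(f"calcium: {len(calcium)} indicator traces -> calcium_control.csv")

    graph = simulate_connectome(SyntheticConnectomeConfig(seed=SEED))
    graph.to_csv(OUT / "connectome_neurons.csv", OUT / "connectome_edges.csv")
    print(f"connectome: {len(graph.neuron_ids())} neurons, "
          f"{graph.graph.number_of_edges()} edges -> connectome_*.csv")


if __name__ == "__main__":
    main()
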