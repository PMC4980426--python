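#!/usr/bin/env python
"""Screen a premotor network for pool-specific candidate interneurons.

Builds a small deterministic premotor graph around two motor pools — four
transverse-muscle motor neurons (pool LT) and one longitudinal motor neuron
(pool LO1) — with excitatory (ACh), inhibitory (GABA) and unannotated
interneurons, then applies the screening rule: strictly more than 35
synapses onto the target pool AND strictly more than 2.75% of the pool's
total input AND zero synapses onto the excluded pool.

The graph is constructed so that one GABAergic and two cholinergic cells
satisfy the rule for pool LT, one strong GABAergic cell fails only through
its single synapse onto MN-LO1, and one sits exactly at 35 synapses (the
strict inequality excludes it).
"""

import json
from pathlib import Path

from motorpool import (
    ConnectomeGraph,
    NeuronRecord,
    SynapticEdge,
    input_fraction,
    screen_candidates,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def build_graph() -> ConnectomeGraph:
    mns = [NeuronRecord(f"MN-LT{i}", cell_class="motor_neuron", pool="LT") for i in range(1, 5)]
    mns.append(NeuronRecord("MN-LO1", cell_class="motor_neuron", pool="LO1"))
    ins = {
        "eIN-1": ("ACh", {"MN-LT1": 60, "MN-LT2": 50, "MN-LT3": 50, "MN-LT4": 40}),
        "eIN-2": ("ACh", {"MN-LT1": 40, "MN-LT2": 45, "MN-LT3": 40, "MN-LT4": 35}),
        "iIN-1": ("GABA", {"MN-LT1": 25, "MN-LT2": 30, "MN-LT3": 25, "MN-LT4": 20}),
        "iIN-weak": ("GABA", {"MN-LT1": 20, "MN-LT2": 15}),  # exactly 35 total
        "iIN-leaky": ("GABA", {"MN-LT1": 50, "MN-LT2": 40, "MN-LO1": 1}),
        "eIN-LO1": ("ACh", {"MN-LO1": 49}),
        "misc-1": ("unknown", {"MN-LT1": 200, "MN-LT2": 180, "MN-LT3": 150, "MN-LT4": 120}),
        "misc-2": ("unknown", {"MN-LO1": 120}),
    }
    neurons = mns + [
        NeuronRecord(nid, cell_class="interneuron", transmitter=t) for nid, (t, _) in ins.items()
    ]
    edges = [
        SynapticEdge(nid, post, w)
        for nid, (_, targets) in ins.items()
        for post, w in targets.items()
    ]
    return ConnectomeGraph(neurons, edges)


def main() -> None:
    g = build_graph()
    target = g.neurons_in_pool("LT")
    excluded = g.neurons_in_pool("LO1")
    results = {}
    for transmitter in ("ACh", "GABA"):
        hits = screen_candidates(g, target, excluded, transmitter=transmitter)
        results[transmitter] = [
            {"neuron_id": h, "input_fraction": input_fraction(g, h, target)} for h in hits
        ]
        shown = ", ".join(
            f"{e['neuron_id']} ({100 * e['input_fraction']:.1f}%)" for e in results[transmitter]
        ) or "none"
        print(f"{transmitter} candidates onto pool LT (excluding LO1): {shown}")
    print("note: iIN-weak (exactly 35 synapses) and iIN-leaky (1 synapse onto "
          "MN-LO1) are correctly rejected")

    OUT.mkdir(exist_ok=True)
    with open(OUT / "interneuron_screen.json", "w") as fh:
        json.dump(
            {"min_synapses": 35, "min_fraction": 0.0275, "candidates": results},
            fh, indent=2,
        )
    print(f"results -> {OUT / 'interneuron_screen.json'}")


if __name__ == "__main__":
    main()
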