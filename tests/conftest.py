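import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from motorpool import (
    ConnectomeGraph,
    NeuronRecord,
    PeristalsisConfig,
    SynapticEdge,
    simulate_peristalsis,
)

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_graph(edges: dict[tuple[str, str], int], annotations: dict | None = None) -> ConnectomeGraph:
    """Build a graph from {(pre, post): count}; annotations override defaults.

    Motor neurons are ids starting with 'MN'; everything else is an
    interneuron.
    """
    annotations = annotations or {}
    ids = sorted({n for pair in edges for n in pair})
    neurons = []
    for nid in ids:
        kw = {"cell_class": "motor_neuron" if nid.startswith("MN") else "interneuron"}
        kw.update(annotations.get(nid, {}))
        neurons.append(NeuronRecord(nid, **kw))
    return ConnectomeGraph(
        neurons, [SynapticEdge(pre, post, c) for (pre, post), c in edges.items()]
    )


def random_graph(rng: np.random.Generator, n_neurons: int = 30, p_edge: float = 0.15) -> ConnectomeGraph:
    """Random annotated digraph for brute-force oracle comparisons."""
    ids = [f"MN{i}" if i < 4 else f"IN{i}" for i in range(n_neurons)]
    pools = {0: "LT", 1: "LT", 2: "LO1", 3: "LO1"}
    neurons = [
        NeuronRecord(
            ids[i],
            cell_class="motor_neuron" if i < 4 else "interneuron",
            pool=pools.get(i),
            transmitter=("GABA", "ACh", "glutamate", "unknown")[rng.integers(4)] if i >= 4 else "unknown",
        )
        for i in range(n_neurons)
    ]
    edges = []
    for pre in ids[4:]:
        for post in ids:
            if pre != post and rng.random() < p_edge:
                edges.append(SynapticEdge(pre, post, int(rng.integers(1, 20))))
    return ConnectomeGraph(neurons, edges)


@pytest.fixture(scope="session")
def clean_peristalsis():
    """Noise/jitter-free 42-degree simulation shared across tests."""
    cfg = PeristalsisConfig(noise_sd=0.0, cycle_jitter_sd=0.0, seed=0)
    return cfg, {m.label: m.trace for m in simulate_peristalsis(cfg)}
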