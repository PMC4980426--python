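"""Synapse-count connectome graph: input divergence metrics and screening.

The graph is a directed multigraph-free weighted digraph: one edge per
ordered (pre, post) pair carrying the number of synaptic contacts, with a
neuron annotation table (cell class, motor pool, transmitter, segment,
side). The metrics quantify how much presynaptic input two motor neurons
share — by partner identity (shared/union partner counts, the Venn-diagram
view) and by synapse weight (fraction of each neuron's input synapses that
shared partners contribute, and the Pearson correlation of per-shared-
partner contributions onto the two neurons).

The screening operation reproduces the candidate premotor-interneuron rule:
keep interneurons of a given transmitter that make strictly more than
``min_synapses`` synapses onto a target motor pool, contribute strictly more
than ``min_fraction`` of the pool's total input, and make zero synapses onto
an excluded pool.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "NeuronRecord",
    "SynapticEdge",
    "ConnectomeGraph",
    "SharedInputSummary",
    "ZeroInputError",
    "shared_input_summary",
    "divergent_synapse_fraction",
    "paired_contribution_correlation",
    "input_fraction",
    "screen_candidates",
    "identified_coverage",
    "percent",
]

CELL_CLASSES = {"motor_neuron", "interneuron", "sensory", "unknown"}
TRANSMITTERS = {"GABA", "ACh", "glutamate", "unknown"}
SIDES = {"left", "right", "unknown"}


class ZeroInputError(ValueError):
    """Raised when a metric needs presynaptic partners a neuron lacks."""


@dataclass(frozen=True)
class NeuronRecord:
    neuron_id: str
    cell_class: str = "unknown"
    pool: str | None = None
    transmitter: str = "unknown"
    segment: str = "unknown"
    side: str = "unknown"

    def __post_init__(self) -> None:
        if self.cell_class not in CELL_CLASSES:
            raise ValueError(f"unknown cell_class {self.cell_class!r}")
        if self.transmitter not in TRANSMITTERS:
            raise ValueError(f"unknown transmitter {self.transmitter!r}")
        if self.side not in SIDES:
            raise ValueError(f"unknown side {self.side!r}")


@dataclass(frozen=True)
class SynapticEdge:
    pre_id: str
    post_id: str
    synapse_count: int

    def __post_init__(self) -> None:
        if self.synapse_count < 1:
            raise ValueError(
                f"edge {self.pre_id}->{self.post_id}: synapse_count must be >= 1"
            )


class ConnectomeGraph:
    """Directed synapse-count graph with neuron annotations.

    Duplicate (pre, post) rows are aggregated by summing their counts, so
    the one-edge-per-ordered-pair invariant holds after construction.
    """

    def __init__(self, neurons: list[NeuronRecord], edges: list[SynapticEdge]):
        ids = [n.neuron_id for n in neurons]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate neuron ids: {dupes}")
        self._records = {n.neuron_id: n for n in neurons}
        g = nx.DiGraph()
        g.add_nodes_from(ids)
        for e in edges:
            for endpoint in (e.pre_id, e.post_id):
                if endpoint not in self._records:
                    raise ValueError(
                        f"edge {e.pre_id}->{e.post_id} references unknown neuron "
                        f"{endpoint!r}"
                    )
            if g.has_edge(e.pre_id, e.post_id):
                g[e.pre_id][e.post_id]["synapses"] += int(e.synapse_count)
            else:
                g.add_edge(e.pre_id, e.post_id, synapses=int(e.synapse_count))
        self._g = g

    # -- container API -------------------------------------------------
    @property
    def graph(self) -> nx.DiGraph:
        return self._g

    def __contains__(self, neuron_id: str) -> bool:
        return neuron_id in self._records

    def record(self, neuron_id: str) -> NeuronRecord:
        return self._records[neuron_id]

    def neuron_ids(self) -> list[str]:
        return list(self._records)

    def neurons_in_pool(self, pool: str) -> set[str]:
        return {i for i, r in self._records.items() if r.pool == pool}

    def presynaptic_weights(self, neuron_id: str) -> dict[str, int]:
        """Map presynaptic partner id -> synapse count onto ``neuron_id``."""
        if neuron_id not in self._records:
            raise KeyError(f"unknown neuron {neuron_id!r}")
        return {
            pre: data["synapses"] for pre, _, data in self._g.in_edges(neuron_id, data=True)
        }

    def total_input(self, neuron_id: str) -> int:
        return sum(self.presynaptic_weights(neuron_id).values())

    def synapse_count(self, pre_id: str, post_id: str) -> int:
        if self._g.has_edge(pre_id, post_id):
            return int(self._g[pre_id][post_id]["synapses"])
        return 0

    # -- I/O ------------------------------------------------------------
    @classmethod
    def from_csv(cls, neuron_table: str | Path, edge_list: str | Path) -> "ConnectomeGraph":
        """Load from neuron-table and edge-list CSVs.

        Neuron table columns: neuron_id, cell_class, pool, transmitter,
        segment, side (missing annotation columns default to unknown).
        Edge list columns: pre_id, post_id, synapse_count.
        """
        ndf = pd.read_csv(neuron_table, dtype={"neuron_id": str})
        if "neuron_id" not in ndf.columns:
            raise ValueError(f"{neuron_table}: missing column neuron_id")
        neurons = []
        for i, row in ndf.iterrows():
            try:
                pool = row.get("pool")
                neurons.append(
                    NeuronRecord(
                        neuron_id=str(row["neuron_id"]),
                        cell_class=str(row.get("cell_class", "unknown")),
                        pool=None if pd.isna(pool) else str(pool),
                        transmitter=str(row.get("transmitter", "unknown")),
                        segment=str(row.get("segment", "unknown")),
                        side=str(row.get("side", "unknown")),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{neuron_table}, row {i + 2}: {exc}") from exc
        edf = pd.read_csv(edge_list, dtype={"pre_id": str, "post_id": str})
        for col in ("pre_id", "post_id", "synapse_count"):
            if col not in edf.columns:
                raise ValueError(f"{edge_list}: missing column {col}")
        edges = []
        for i, row in edf.iterrows():
            try:
                edges.append(
                    SynapticEdge(str(row["pre_id"]), str(row["post_id"]), int(row["synapse_count"]))
                )
            except ValueError as exc:
                raise ValueError(f"{edge_list}, row {i + 2}: {exc}") from exc
        return cls(neurons, edges)

    def to_csv(self, neuron_table: str | Path, edge_list: str | Path) -> None:
        pd.DataFrame(
            [
                {
                    "neuron_id": r.neuron_id,
                    "cell_class": r.cell_class,
                    "pool": r.pool,
                    "transmitter": r.transmitter,
                    "segment": r.segment,
                    "side": r.side,
                }
                for r in self._records.values()
            ]
        ).to_csv(neuron_table, index=False)
        pd.DataFrame(
            [
                {"pre_id": u, "post_id": v, "synapse_count": d["synapses"]}
                for u, v, d in self._g.edges(data=True)
            ]
        ).to_csv(edge_list, index=False)

    def to_graphml(self, path: str | Path) -> None:
        """Export with neuron annotations on nodes and synapse_count on edges."""
        g = nx.DiGraph()
        for r in self._records.values():
            g.add_node(
                r.neuron_id,
                cell_class=r.cell_class,
                pool=r.pool or "",
                transmitter=r.transmitter,
                segment=r.segment,
                side=r.side,
            )
        for u, v, d in self._g.edges(data=True):
            g.add_edge(u, v, synapse_count=d["synapses"], weight=d["synapses"])
        nx.write_graphml(g, path)


@dataclass(frozen=True)
class SharedInputSummary:
    """Partner-level and synapse-level overlap of two neurons' inputs."""

    neuron_a: str
    neuron_b: str
    shared_partner_count: int
    union_partner_count: int
    shared_partner_fraction: float
    shared_synapse_fraction_a: float
    shared_synapse_fraction_b: float

    @property
    def shared_partner_percent(self) -> int:
        return percent(self.shared_partner_fraction)


def percent(fraction: float) -> int:
    """Round a fraction to the nearest integer percent (reporting convention)."""
    return int(round(100.0 * fraction))


def _input_weights_checked(graph: ConnectomeGraph, neuron_id: str) -> dict[str, int]:
    w = graph.presynaptic_weights(neuron_id)
    if not w:
        raise ZeroInputError(f"neuron {neuron_id!r} has no input synapses")
    return w


def shared_input_summary(
    graph: ConnectomeGraph, neuron_a: str, neuron_b: str
) -> SharedInputSummary:
    """Partner overlap of two neurons: shared over union of presynaptic
    partner sets, plus the fraction of each neuron's input synapses that
    the shared partners supply."""
    wa = _input_weights_checked(graph, neuron_a)
    wb = _input_weights_checked(graph, neuron_b)
    shared = set(wa) & set(wb)
    union = set(wa) | set(wb)
    total_a = sum(wa.values())
    total_b = sum(wb.values())
    return SharedInputSummary(
        neuron_a=neuron_a,
        neuron_b=neuron_b,
        shared_partner_count=len(shared),
        union_partner_count=len(union),
        shared_partner_fraction=len(shared) / len(union),
        shared_synapse_fraction_a=sum(wa[p] for p in shared) / total_a,
        shared_synapse_fraction_b=sum(wb[p] for p in shared) / total_b,
    )


def divergent_synapse_fraction(graph: ConnectomeGraph, neuron_a: str, neuron_b: str) -> float:
    """Mean fraction of the two neurons' input synapses coming from
    NON-shared partners: 1 - mean of the two shared synapse fractions."""
    s = shared_input_summary(graph, neuron_a, neuron_b)
    return 1.0 - 0.5 * (s.shared_synapse_fraction_a + s.shared_synapse_fraction_b)


def paired_contribution_correlation(
    graph: ConnectomeGraph, neuron_a: str, neuron_b: str
) -> tuple[float | None, int]:
    """Pearson correlation of shared partners' synapse counts onto the two
    neurons; (None, n_shared) when fewer than 3 partners are shared."""
    wa = _input_weights_checked(graph, neuron_a)
    wb = _input_weights_checked(graph, neuron_b)
    shared = sorted(set(wa) & set(wb))
    if len(shared) < 3:
        return None, len(shared)
    xs = np.array([wa[p] for p in shared], dtype=float)
    ys = np.array([wb[p] for p in shared], dtype=float)
    if xs.std() == 0 or ys.std() == 0:
        return None, len(shared)
    r = float(np.corrcoef(xs, ys)[0, 1])
    return r, len(shared)


def input_fraction(graph: ConnectomeGraph, interneuron: str, pool: set[str]) -> float:
    """Fraction of the pool's total input synapses supplied by one neuron."""
    if not pool:
        raise ValueError("pool must be nonempty")
    total = sum(graph.total_input(m) for m in pool)
    if total == 0:
        raise ZeroInputError(f"pool {sorted(pool)} has no input synapses")
    onto_pool = sum(graph.synapse_count(interneuron, m) for m in pool)
    return onto_pool / total


def screen_candidates(
    graph: ConnectomeGraph,
    target_pool: set[str],
    excluded_pool: set[str],
    transmitter: str | None = None,
    min_synapses: int = 35,
    min_fraction: float = 0.0275,
) -> list[str]:
    """Screen for candidate premotor interneurons.

    Returns interneurons (matching ``transmitter`` when given) whose summed
    synapses onto ``target_pool`` strictly exceed ``min_synapses``, whose
    share of the pool's total input strictly exceeds ``min_fraction``, and
    that make zero synapses onto ``excluded_pool``. Sorted by descending
    input fraction, ties by id.
    """
    if target_pool & excluded_pool:
        raise ValueError(
            f"pools overlap: {sorted(target_pool & excluded_pool)}"
        )
    if not target_pool:
        raise ValueError("target_pool must be nonempty")
    total = sum(graph.total_input(m) for m in target_pool)
    if total == 0:
        return []
    hits: list[tuple[float, str]] = []
    for nid in graph.neuron_ids():
        rec = graph.record(nid)
        if rec.cell_class != "interneuron":
            continue
        if transmitter is not None and rec.transmitter != transmitter:
            continue
        onto_target = sum(graph.synapse_count(nid, m) for m in target_pool)
        if onto_target <= min_synapses:
            continue
        frac = onto_target / total
        if frac <= min_fraction:
            continue
        if any(graph.synapse_count(nid, m) > 0 for m in excluded_pool):
            continue
        hits.append((frac, nid))
    hits.sort(key=lambda t: (-t[0], t[1]))
    return [nid for _, nid in hits]


def identified_coverage(
    graph: ConnectomeGraph, identified_ids: set[str], targets: set[str]
) -> tuple[int, float]:
    """(synapse count, fraction) of input onto ``targets`` that originates
    from ``identified_ids``."""
    if not targets:
        raise ValueError("targets must be nonempty")
    total = sum(graph.total_input(m) for m in targets)
    if total == 0:
        raise ZeroInputError(f"targets {sorted(targets)} have no input synapses")
    from_identified = sum(
        w
        for m in targets
        for pre, w in graph.presynaptic_weights(m).items()
        if pre in identified_ids
    )
    return from_identified, from_identified / total
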