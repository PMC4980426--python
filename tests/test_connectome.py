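"""Synapse-count graph metrics against enumerable fixtures and brute force."""

import numpy as np
import pytest

from motorpool import (
    ConnectomeGraph,
    NeuronRecord,
    SynapticEdge,
    divergent_synapse_fraction,
    identified_coverage,
    input_fraction,
    paired_contribution_correlation,
    screen_candidates,
    shared_input_summary,
)
from motorpool.connectome import ZeroInputError, percent

from conftest import make_graph, random_graph


class TestSharedInputSummary:
    def test_enumerable_overlap(self):
        g = make_graph(
            {("p1", "MN_A"): 1, ("p2", "MN_A"): 1, ("p3", "MN_A"): 1,
             ("p3", "MN_B"): 1, ("p4", "MN_B"): 1}
        )
        s = shared_input_summary(g, "MN_A", "MN_B")
        assert s.shared_partner_count == 1
        assert s.union_partner_count == 4
        assert s.shared_partner_fraction == pytest.approx(0.25)

    def test_identical_partner_sets(self):
        g = make_graph({("p1", "MN_A"): 3, ("p1", "MN_B"): 3,
                        ("p2", "MN_A"): 7, ("p2", "MN_B"): 7})
        s = shared_input_summary(g, "MN_A", "MN_B")
        assert s.shared_partner_fraction == 1.0
        assert s.shared_synapse_fraction_a == 1.0
        assert s.shared_synapse_fraction_b == 1.0

    def test_34_of_75_reports_45_percent(self):
        edges = {}
        for i in range(34):
            edges[(f"s{i}", "MN_A")] = 2
            edges[(f"s{i}", "MN_B")] = 2
        for i in range(21):
            edges[(f"a{i}", "MN_A")] = 1
        for i in range(20):
            edges[(f"b{i}", "MN_B")] = 1
        g = make_graph(edges)
        s = shared_input_summary(g, "MN_A", "MN_B")
        assert (s.shared_partner_count, s.union_partner_count) == (34, 75)
        assert s.shared_partner_percent == 45

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        g = random_graph(rng)
        ab = shared_input_summary(g, "MN0", "MN1")
        ba = shared_input_summary(g, "MN1", "MN0")
        assert ab.shared_partner_fraction == ba.shared_partner_fraction
        assert ab.shared_synapse_fraction_a == ba.shared_synapse_fraction_b
        assert ab.shared_synapse_fraction_b == ba.shared_synapse_fraction_a

    def test_zero_input_neuron_named_in_error(self):
        # MN_B exists (as a presynaptic node) but receives no input
        g = make_graph({("p1", "MN_A"): 1, ("MN_B", "MN_A"): 1})
        with pytest.raises(ZeroInputError, match="MN_B"):
            shared_input_summary(g, "MN_A", "MN_B")


class TestDivergentFraction:
    def test_disjoint_partners(self):
        g = make_graph({("p1", "MN_A"): 5, ("p2", "MN_B"): 5})
        assert divergent_synapse_fraction(g, "MN_A", "MN_B") == 1.0

    def test_identical_partners(self):
        g = make_graph({("p1", "MN_A"): 5, ("p1", "MN_B"): 2})
        assert divergent_synapse_fraction(g, "MN_A", "MN_B") == 0.0

    def test_shared_partners_supplying_18_percent(self):
        # shared partner supplies 18 of each neuron's 100 input synapses
        g = make_graph(
            {("s", "MN_A"): 18, ("s", "MN_B"): 18,
             ("a", "MN_A"): 82, ("b", "MN_B"): 82}
        )
        assert divergent_synapse_fraction(g, "MN_A", "MN_B") == pytest.approx(0.82)

    def test_conservation_with_shared_fraction(self):
        rng = np.random.default_rng(1)
        g = random_graph(rng)
        s = shared_input_summary(g, "MN0", "MN2")
        d = divergent_synapse_fraction(g, "MN0", "MN2")
        assert d + 0.5 * (s.shared_synapse_fraction_a + s.shared_synapse_fraction_b) == pytest.approx(1.0)


class TestContributionCorrelation:
    def test_identical_weight_vectors(self):
        g = make_graph(
            {(p, m): w for p, w in zip("xyz", (2, 5, 9)) for m in ("MN_A", "MN_B")}
        )
        r, n = paired_contribution_correlation(g, "MN_A", "MN_B")
        assert r == pytest.approx(1.0)
        assert n == 3

    def test_exact_anticorrelation(self):
        g = make_graph(
            {("x", "MN_A"): 1, ("y", "MN_A"): 2, ("z", "MN_A"): 3,
             ("x", "MN_B"): 3, ("y", "MN_B"): 2, ("z", "MN_B"): 1}
        )
        r, _ = paired_contribution_correlation(g, "MN_A", "MN_B")
        assert r == pytest.approx(-1.0)

    def test_too_few_shared_partners_undefined(self):
        g = make_graph({("x", "MN_A"): 1, ("x", "MN_B"): 1, ("y", "MN_A"): 1})
        r, n = paired_contribution_correlation(g, "MN_A", "MN_B")
        assert r is None
        assert n == 1

    def test_matches_brute_force_covariance(self):
        rng = np.random.default_rng(2)
        g = random_graph(rng, n_neurons=40, p_edge=0.3)
        r, n = paired_contribution_correlation(g, "MN0", "MN1")
        wa = g.presynaptic_weights("MN0")
        wb = g.presynaptic_weights("MN1")
        shared = sorted(set(wa) & set(wb))
        xs = np.array([wa[p] for p in shared], float)
        ys = np.array([wb[p] for p in shared], float)
        cov = np.mean((xs - xs.mean()) * (ys - ys.mean()))
        oracle = cov / (xs.std() * ys.std())
        assert n == len(shared) >= 3
        assert r == pytest.approx(oracle, abs=1e-12)


class TestInputFraction:
    def test_sole_provider(self):
        g = make_graph({("i", "MN_A"): 10})
        assert input_fraction(g, "i", {"MN_A"}) == 1.0

    def test_unconnected_interneuron(self):
        g = make_graph({("i", "MN_A"): 10, ("j", "MN_B"): 4})
        assert input_fraction(g, "j", {"MN_A"}) == 0.0

    def test_matches_exhaustive_edge_sum(self):
        rng = np.random.default_rng(3)
        g = random_graph(rng)
        pool = {"MN0", "MN1", "MN2", "MN3"}
        for nid in g.neuron_ids():
            if nid in pool:
                continue
            total = sum(
                d["synapses"] for _, post, d in g.graph.edges(data=True) if post in pool
            )
            onto = sum(
                d["synapses"]
                for pre, post, d in g.graph.edges(data=True)
                if pre == nid and post in pool
            )
            assert input_fraction(g, nid, pool) == pytest.approx(onto / total)

    def test_empty_pool_rejected(self):
        g = make_graph({("i", "MN_A"): 1})
        with pytest.raises(ValueError, match="nonempty"):
            input_fraction(g, "i", set())


class TestScreening:
    def _graph(self):
        edges = {("bulk", "MN_LT1"): 900}  # anonymous drive setting the denominator
        annotations = {"bulk": {"transmitter": "unknown"}}
        # qualifying GABA cell: 40 synapses, 4% of 1000-total pool input
        edges[("gaba_hit", "MN_LT2")] = 40
        annotations["gaba_hit"] = {"transmitter": "GABA"}
        # qualifying ACh cell
        edges[("ach_hit", "MN_LT2")] = 60
        annotations["ach_hit"] = {"transmitter": "ACh"}
        # exactly at the synapse threshold: excluded by strict inequality
        edges[("border", "MN_LT1")] = 35
        annotations["border"] = {"transmitter": "GABA"}
        # strong but touches the excluded pool
        edges[("leaky", "MN_LT1")] = 80
        edges[("leaky", "MN_LO1")] = 1
        annotations["leaky"] = {"transmitter": "GABA"}
        edges[("other", "MN_LO1")] = 50
        annotations["other"] = {"transmitter": "GABA"}
        g = make_graph(edges, annotations)
        return g, {"MN_LT1", "MN_LT2"}, {"MN_LO1"}

    def test_empty_graph_returns_empty(self):
        g = ConnectomeGraph([NeuronRecord("MN_A", cell_class="motor_neuron")], [])
        assert screen_candidates(g, {"MN_A"}, set()) == []

    def test_exactly_35_synapses_excluded(self):
        g, target, excluded = self._graph()
        hits = screen_candidates(g, target, excluded)
        assert "border" not in hits

    def test_transmitter_filter(self):
        g, target, excluded = self._graph()
        assert screen_candidates(g, target, excluded, transmitter="GABA") == ["gaba_hit"]
        assert screen_candidates(g, target, excluded, transmitter="ACh") == ["ach_hit"]
        # no filter: the unannotated bulk cell also qualifies; ordering is
        # by descending input fraction
        assert screen_candidates(g, target, excluded) == ["bulk", "ach_hit", "gaba_hit"]

    def test_excluded_pool_is_categorical(self):
        g, target, excluded = self._graph()
        assert "leaky" not in screen_candidates(g, target, excluded)
        # without the exclusion it qualifies
        assert "leaky" in screen_candidates(g, target, set())

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(4)
        g = random_graph(rng, n_neurons=40, p_edge=0.3)
        target, excluded = {"MN0", "MN1"}, {"MN2"}
        prev = set(screen_candidates(g, target, excluded, min_synapses=0, min_fraction=0.0))
        for ms, mf in [(5, 0.0), (5, 0.02), (10, 0.02), (10, 0.05)]:
            cur = set(screen_candidates(g, target, excluded, min_synapses=ms, min_fraction=mf))
            assert cur <= prev
            prev = cur

    def test_overlapping_pools_rejected(self):
        g, target, _ = self._graph()
        with pytest.raises(ValueError, match="overlap"):
            screen_candidates(g, target, {"MN_LT1"})


class TestIdentifiedCoverage:
    def test_all_and_none(self):
        g = make_graph({("i", "MN_A"): 5, ("j", "MN_A"): 5})
        assert identified_coverage(g, {"i", "j"}, {"MN_A"}) == (10, 1.0)
        assert identified_coverage(g, set(), {"MN_A"}) == (0, 0.0)

    def test_1300_of_1409_reports_92_percent(self):
        g = make_graph({("known", "MN_A"): 1300, ("unknown", "MN_A"): 109})
        count, fraction = identified_coverage(g, {"known"}, {"MN_A"})
        assert count == 1300
        assert percent(fraction) == 92


class TestGraphContainer:
    def test_duplicate_edges_aggregated(self):
        g = ConnectomeGraph(
            [NeuronRecord("a"), NeuronRecord("MN_B", cell_class="motor_neuron")],
            [SynapticEdge("a", "MN_B", 3), SynapticEdge("a", "MN_B", 4)],
        )
        assert g.synapse_count("a", "MN_B") == 7

    def test_unknown_endpoint_rejected(self):
        with pytest.raises(ValueError, match="unknown neuron"):
            ConnectomeGraph([NeuronRecord("a")], [SynapticEdge("a", "ghost", 1)])

    def test_nonpositive_count_rejected(self):
        with pytest.raises(ValueError, match="synapse_count"):
            SynapticEdge("a", "b", 0)

    def test_csv_and_graphml_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        g = random_graph(rng, n_neurons=15)
        g.to_csv(tmp_path / "neurons.csv", tmp_path / "edges.csv")
        g2 = ConnectomeGraph.from_csv(tmp_path / "neurons.csv", tmp_path / "edges.csv")
        assert set(g2.neuron_ids()) == set(g.neuron_ids())
        for u, v, d in g.graph.edges(data=True):
            assert g2.synapse_count(u, v) == d["synapses"]
        g.to_graphml(tmp_path / "g.graphml")
        import networkx as nx

        g3 = nx.read_graphml(tmp_path / "g.graphml")
        assert g3.number_of_edges() == g.graph.number_of_edges()

    def test_metrics_match_brute_force_on_random_graphs(self):
        # exhaustive recomputation from the raw edge list, graphs <= 50 neurons
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            g = random_graph(rng, n_neurons=int(rng.integers(10, 50)), p_edge=0.25)
            raw = [
                (u, v, d["synapses"]) for u, v, d in g.graph.edges(data=True)
            ]
            a, b = "MN0", "MN1"
            part_a = {u: w for u, v, w in raw if v == a}
            part_b = {u: w for u, v, w in raw if v == b}
            if not part_a or not part_b:
                continue
            shared = set(part_a) & set(part_b)
            union = set(part_a) | set(part_b)
            s = shared_input_summary(g, a, b)
            assert s.shared_partner_count == len(shared)
            assert s.union_partner_count == len(union)
            assert s.shared_synapse_fraction_a == pytest.approx(
                sum(part_a[p] for p in shared) / sum(part_a.values())
            )
            expected_div = 1 - 0.5 * (
                sum(part_a[p] for p in shared) / sum(part_a.values())
                + sum(part_b[p] for p in shared) / sum(part_b.values())
            )
            assert divergent_synapse_fraction(g, a, b) == pytest.approx(expected_div)
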