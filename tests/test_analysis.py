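"""Network statistics, motif census, enrichment and class distributions."""

import itertools
from collections import Counter

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from dissipnet import (
    average_neighbors,
    class_distribution,
    degree_distribution,
    enrichment_probability,
    find_superhubs,
    motif_census,
    network_stats,
    shortest_path_percentage,
)
from dissipnet.analysis import triad_name

from conftest import random_time_dag


class TestNetworkStats:
    def test_three_node_directed_path(self):
        stats = network_stats(nx.DiGraph([("s", "a"), ("a", "t")]))
        assert stats.n_shortest_paths == 3  # s->a, a->t, s->t
        assert stats.diameter == 2
        assert stats.radius == 1
        assert stats.char_path_length == pytest.approx(4 / 3)

    def test_reported_connected_pair_percentages(self):
        # printed count/percentage triples for the three network sizes
        assert round(shortest_path_percentage(38329, 447)) == 19
        assert round(shortest_path_percentage(6063, 150)) == 27
        assert round(shortest_path_percentage(916, 50)) == 37

    def test_percentage_identity_is_exact(self):
        for n_pairs, n in [(38329, 447), (6063, 150), (916, 50)]:
            pct = shortest_path_percentage(n_pairs, n)
            assert pct * n * (n - 1) == pytest.approx(100 * n_pairs, rel=1e-12)

    def test_average_neighbors_reproduces_reported_values(self):
        assert average_neighbors(447, 2944) == pytest.approx(13.172, abs=5e-4)
        assert average_neighbors(447, 2954) == pytest.approx(13.217, abs=5e-4)

    def test_stats_consistency_on_random_networks(self):
        g = random_time_dag(40, seed=9)
        stats = network_stats(g)
        assert stats.radius <= stats.diameter
        assert 0 <= stats.pct_shortest_paths <= 100
        und = nx.Graph(g)
        assert stats.avg_neighbors == pytest.approx(
            2 * und.number_of_edges() / und.number_of_nodes()
        )


class TestDegreesAndSuperhubs:
    def test_star_graph_degrees(self):
        hist = degree_distribution(nx.star_graph(5))
        assert hist == {5: 1, 1: 5}

    def test_edgeless_network_all_zero(self):
        g = nx.DiGraph()
        g.add_nodes_from("abc")
        assert degree_distribution(g) == {0: 3}

    def test_distribution_matches_neighbor_recount(self):
        g = random_time_dag(50, seed=31)
        hist = degree_distribution(g)
        recount = Counter(
            len(set(g.successors(u)) | set(g.predecessors(u))) for u in g
        )
        assert hist == dict(recount)

    def test_superhub_run_recovery(self):
        # hub block at sequence positions 10-13, isolated hub at 20
        g = nx.Graph()
        order = [f"R{i}" for i in range(30)]
        g.add_nodes_from(order)
        for pos in (10, 11, 12, 13, 20):
            for k in range(11):  # degree 11 > threshold 10
                g.add_edge(f"R{pos}", f"X{pos}_{k}")
        for i, extra in enumerate(order):
            g.add_node(extra)
        full_order = order + sorted(
            {n for n in g.nodes if n.startswith("X")}
        )
        runs, singletons = find_superhubs(g, structure_order=full_order)
        assert runs == [["R10", "R11", "R12", "R13"]]
        assert singletons == ["R20"]

    def test_no_hub_above_threshold(self):
        g = nx.path_graph(5)
        runs, singletons = find_superhubs(g, structure_order=list(g.nodes))
        assert runs == [] and singletons == []


def brute_force_census(g: nx.DiGraph, size: int):
    """Exhaustive subset enumeration grouped by directed isomorphism."""
    reps, counts = [], []
    for subset in itertools.combinations(g.nodes, size):
        sub = g.subgraph(subset)
        if not nx.is_weakly_connected(sub):
            continue
        for i, rep in enumerate(reps):
            if nx.is_isomorphic(sub, rep):
                counts[i] += 1
                break
        else:
            reps.append(nx.DiGraph(sub))
            counts.append(1)
    return reps, counts


class TestMotifCensus:
    def test_single_triangle(self):
        census = motif_census(nx.DiGraph([("a", "b"), ("b", "c"), ("a", "c")]), size=3)
        assert sum(census.counts.values()) == 1
        assert len(census.counts) == 1

    def test_feed_forward_and_cycle_are_distinct_classes(self):
        ffl = nx.DiGraph([("a", "b"), ("b", "c"), ("a", "c")])
        cyc = nx.DiGraph([("a", "b"), ("b", "c"), ("c", "a")])
        labels = set(motif_census(ffl, 3).counts) | set(motif_census(cyc, 3).counts)
        assert len(labels) == 2
        names = {triad_name(lb) for lb in labels}
        assert names == {"030T", "030C"}

    @pytest.mark.parametrize("size", [3, 4])
    def test_census_equals_exhaustive_enumeration(self, size):
        rng = np.random.default_rng(5)
        g = nx.gnp_random_graph(25, 0.12, seed=3, directed=True)
        census = motif_census(g, size=size)
        _, counts = brute_force_census(g, size)
        assert sorted(census.counts.values()) == sorted(counts)
        assert len(census.counts) == len(counts)
        if census.frequencies:
            assert sum(census.frequencies.values()) == pytest.approx(1.0)

    def test_three_node_counts_match_triadic_census(self):
        g = nx.gnp_random_graph(30, 0.1, seed=8, directed=True)
        census = motif_census(g, size=3)
        named = {triad_name(lb): c for lb, c in census.counts.items()}
        reference = nx.triadic_census(g)
        for name, count in named.items():
            assert reference[name] == count

    def test_counts_invariant_under_relabeling(self):
        g = nx.gnp_random_graph(15, 0.15, seed=2, directed=True)
        relabeled = nx.relabel_nodes(g, {u: f"z{u}" for u in g.nodes})
        assert motif_census(g, 3).counts == motif_census(relabeled, 3).counts

    def test_frame_ordering_by_edges_then_frequency(self):
        g = nx.gnp_random_graph(20, 0.15, seed=4, directed=True)
        frame = motif_census(g, 3).to_frame()
        assert list(frame["n_edges"]) == sorted(frame["n_edges"])


class TestEnrichment:
    def test_certain_event(self):
        assert enrichment_probability(10, 10, 4).p == pytest.approx(1.0)

    def test_half_by_enumeration(self):
        # 1 hit among 4; samples of size 2: C(2,1)/C(4,1) = 0.5
        assert enrichment_probability(4, 2, 1).p == pytest.approx(0.5)

    def test_tiny_case_matches_subset_enumeration(self):
        population, sample, hits = 5, 3, 2
        universe = range(population)
        hit_set = set(range(hits))
        subsets = list(itertools.combinations(universe, sample))
        frac = sum(hit_set <= set(s) for s in subsets) / len(subsets)
        assert enrichment_probability(population, sample, hits).p == pytest.approx(frac)

    def test_matches_scipy_hypergeom(self):
        for population, sample, hits in [(447, 150, 21), (60, 25, 7), (100, 40, 0)]:
            mine = enrichment_probability(population, sample, hits).p
            ref = hypergeom.pmf(hits, population, hits, sample)
            assert mine == pytest.approx(ref, rel=1e-9)

    def test_exhaustive_identity_small_populations(self):
        from scipy.special import comb

        for population in range(1, 25):
            for sample in range(population + 1):
                for hits in range(sample + 1):
                    p = enrichment_probability(population, sample, hits).p
                    direct = comb(sample, hits) / comb(population, hits)
                    assert p == pytest.approx(direct, rel=1e-9)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            enrichment_probability(10, 12, 3)


class TestClassDistribution:
    def annotations(self):
        uids = [f"A{i}" for i in range(10)]
        return pd.DataFrame(
            {
                "region": ["ACT1"] * 10,
                "sec_struct": ["Sheet"] * 6 + ["Helix"] * 4,
                "conservation": [0.95] * 9 + [0.65],
            },
            index=uids,
        )

    def test_uniform_region_gives_fraction_one(self):
        dist = class_distribution([f"A{i}" for i in range(10)], self.annotations())
        assert dist["region"]["ACT1"] == pytest.approx(1.0)

    def test_fractions_match_counting_oracle(self):
        dist = class_distribution([f"A{i}" for i in range(10)], self.annotations())
        assert dist["sec_struct"]["Sheet"] == pytest.approx(0.6)
        assert dist["sec_struct"]["Helix"] == pytest.approx(0.4)

    def test_high_conservation_lands_in_top_bin(self):
        dist = class_distribution([f"A{i}" for i in range(10)], self.annotations())
        top = [frac for label, frac in dist["conservation"].items()
               if label.endswith("1.0]")]
        assert top[0] == pytest.approx(0.9)

    def test_unannotated_nodes_fall_in_unknown(self):
        dist = class_distribution(["A0", "ZZ"], self.annotations())
        assert dist["region"]["unknown"] == pytest.approx(0.5)
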