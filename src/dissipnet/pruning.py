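"""Source→target pair networks by 3-step pruning, plus union/intersection.

Starting from the Initial network, a pair network for (source, target)
is obtained by:

1. deleting every node whose response time exceeds the target's;
2. repeatedly deleting nodes of in-degree zero (the source excepted),
   recomputing in-degrees each round, until stable;
3. repeatedly deleting nodes of out-degree zero (the target excepted),
   recomputing out-degrees each round, until stable.

On acyclic inputs the surviving node set equals the residues that lie
on some directed path from source to target within the time-filtered
network; the iterative form is the operational definition and also
covers graphs with cycles introduced by tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

__all__ = [
    "pair_network",
    "union_network",
    "intersection_network",
    "target_influence_counts",
    "influence_histogram",
    "PairNetworkSet",
]


def _time(g: nx.DiGraph, u: str) -> float:
    t = g.nodes[u].get("response_time")
    if t is None:
        raise ValueError(f"node {u} has no response_time attribute")
    return t


def pair_network(initial: nx.DiGraph, source: str, target: str) -> nx.DiGraph:
    """Prune the Initial network down to one source→target pair network."""
    for name, u in (("source", source), ("target", target)):
        if u not in initial:
            raise ValueError(f"{name} residue {u!r} not in network")
    if source == target:
        raise ValueError("source and target must differ")

    t_target = _time(initial, target)

    # Step 1: time filter (strictly-later nodes deleted), induced edges
    keep = [u for u in initial.nodes if _time(initial, u) <= t_target]
    g = initial.subgraph(keep).copy()

    # Step 2: iteratively delete in-degree-0 nodes except the source
    while True:
        doomed = [u for u in g.nodes if g.in_degree(u) == 0 and u != source]
        if not doomed:
            break
        g.remove_nodes_from(doomed)

    # Step 3: iteratively delete out-degree-0 nodes except the target
    while True:
        doomed = [u for u in g.nodes if g.out_degree(u) == 0 and u != target]
        if not doomed:
            break
        g.remove_nodes_from(doomed)

    g.graph.update(provenance="pair", source=source, target=target)
    return g


def _merged(pairs: dict, mode: str) -> nx.DiGraph:
    if not pairs:
        raise ValueError("need at least one pair network")
    nets = list(pairs.values())
    if mode == "union":
        nodes = set().union(*(set(g.nodes) for g in nets))
        edges = set().union(*(set(g.edges) for g in nets))
    else:
        nodes = set.intersection(*(set(g.nodes) for g in nets))
        edges = set.intersection(*(set(g.edges) for g in nets))
    out = nx.DiGraph(provenance=mode)
    for g in nets:  # first network providing a node/edge wins on attributes
        for u in g.nodes:
            if u in nodes and u not in out:
                out.add_node(u, **g.nodes[u])
        for e in g.edges:
            if e in edges and not out.has_edge(*e):
                out.add_edge(*e, **g.edges[e])
    return out


def union_network(pairs: dict) -> nx.DiGraph:
    """Set union of nodes and edges over all pair networks."""
    return _merged(pairs, "union")


def intersection_network(pairs: dict) -> nx.DiGraph:
    """Set intersection of nodes and edges over all pair networks.

    Edges are intersected as sets (not re-induced), so the result can be
    sparser than the induced subgraph on the common nodes.
    """
    return _merged(pairs, "intersection")


def target_influence_counts(pairs: dict) -> dict[str, int]:
    """For each residue in the union, the number of distinct target
    residues whose pair network contains it."""
    counts: dict[str, set] = {}
    for (_, target), g in pairs.items():
        for u in g.nodes:
            counts.setdefault(u, set()).add(target)
    return {u: len(ts) for u, ts in counts.items()}


def influence_histogram(pairs: dict) -> pd.DataFrame:
    """Per-pair histogram of influence counts.

    Row (source, target), column c: number of residues of that pair
    network that influence exactly c targets.
    """
    counts = target_influence_counts(pairs)
    n_targets = len({t for (_, t) in pairs})
    rows = {}
    for key, g in pairs.items():
        row = {c: 0 for c in range(1, n_targets + 1)}
        for u in g.nodes:
            row[counts[u]] += 1
        rows["-".join(key)] = row
    return pd.DataFrame.from_dict(rows, orient="index").sort_index(axis=1)


@dataclass
class PairNetworkSet:
    """All pair networks for given sources and targets, with derived views."""

    pairs: dict = field(default_factory=dict)
    union: nx.DiGraph | None = None
    intersection: nx.DiGraph | None = None
    influence_count: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_initial(cls, initial: nx.DiGraph, sources, targets) -> "PairNetworkSet":
        sources, targets = list(sources), list(targets)
        if not sources or not targets:
            raise ValueError("need at least one source and one target")
        pairs = {
            (s, t): pair_network(initial, s, t)
            for s in sources
            for t in targets
            if s != t
        }
        return cls(
            pairs=pairs,
            union=union_network(pairs),
            intersection=intersection_network(pairs),
            influence_count=target_influence_counts(pairs),
        )
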