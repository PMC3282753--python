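"""Hierarchical layering of signal-transduction networks and the
propagation coefficient.

A directed acyclic signal-transduction network is layered top-to-bottom
("deep-preference": each node sits as deep as its longest incoming
path forces it, so every edge points strictly downward).  Within a
layer N holding nodes j with in-degrees m_j and out-degrees n_j, and
with l edges passing straight through the layer, the propagation
coefficient of node i is

    PC(i) = m_i * n_i / (sum_j m_j * n_j + l),

the fraction of former-layer-to-later-layer pathway capacity carried by
node i.  Nodes of the first layer take m := 1 and nodes of the last
layer take n := 1, so a sole source node with no pass-through edges has
PC = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

__all__ = ["LayerAssignment", "assign_layers", "propagation_coefficient", "layer_summary"]


@dataclass
class LayerAssignment:
    """Node → layer mapping plus per-layer structure.

    Attributes
    ----------
    layer : dict
        Node uid → layer number (1 = top/source layer).
    layers : dict
        Layer number → ordered list of member uids.
    pass_through : dict
        Layer number N → number of edges (u, v) with
        ``layer[u] < N < layer[v]``.
    mode : str
        ``"deep"`` (longest-path) or ``"bfs"`` (shortest-path) layering.
    """

    layer: dict[str, int]
    layers: dict[int, list[str]] = field(default_factory=dict)
    pass_through: dict[int, int] = field(default_factory=dict)
    mode: str = "deep"

    @property
    def n_layers(self) -> int:
        return max(self.layers) if self.layers else 0


def assign_layers(network: nx.DiGraph, mode: str = "deep") -> LayerAssignment:
    """Layer an acyclic directed network.

    ``mode="deep"`` places each node on layer
    ``1 + (longest directed path from the in-degree-0 node set)``, the
    deep-preference layout: every edge then spans at least one layer
    downward and the layer count equals the longest source→sink path
    plus one.  ``mode="bfs"`` uses shortest paths instead (sensitivity
    analysis only; upward edges become possible and are excluded from
    pass-through counts).
    """
    if mode not in ("deep", "bfs"):
        raise ValueError(f"unknown layering mode {mode!r}")
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    try:
        cycle = nx.find_cycle(network)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        path = " -> ".join(u for u, _ in cycle) + f" -> {cycle[-1][1]}"
        raise ValueError(f"network has a cycle, cannot layer it: {path}")

    pick = max if mode == "deep" else min
    layer: dict[str, int] = {}
    for v in nx.topological_sort(network):
        preds = list(network.predecessors(v))
        layer[v] = 1 if not preds else pick(layer[u] for u in preds) + 1

    layers: dict[int, list[str]] = {}
    order = {
        u: (network.nodes[u].get("order", math.inf), u) for u in network.nodes
    }
    for u in sorted(network.nodes, key=order.get):
        layers.setdefault(layer[u], []).append(u)

    n_layers = max(layers)
    pass_through = {
        n: sum(1 for u, v in network.edges if layer[u] < n < layer[v])
        for n in range(1, n_layers + 1)
    }
    return LayerAssignment(layer=layer, layers=dict(sorted(layers.items())),
                           pass_through=pass_through, mode=mode)


def propagation_coefficient(
    network: nx.DiGraph,
    assignment: LayerAssignment | None = None,
    degree_scope: str = "network",
) -> pd.DataFrame:
    """Per-node propagation coefficients.

    Parameters
    ----------
    network : networkx.DiGraph
        Acyclic signal-transduction network.
    assignment : LayerAssignment, optional
        Deep-preference layering; computed if omitted.
    degree_scope : {"network", "adjacent"}
        ``"network"`` uses full in-/out-degrees (default);
        ``"adjacent"`` counts only edges from the immediately previous
        layer and to the immediately next layer.

    Returns
    -------
    pandas.DataFrame
        Indexed by node uid, columns ``layer``, ``m`` (in-degree),
        ``n`` (out-degree), ``pc``; within each layer
        ``sum(pc) + l / (sum(m*n) + l) == 1`` exactly.
    """
    if degree_scope not in ("network", "adjacent"):
        raise ValueError(f"unknown degree_scope {degree_scope!r}")
    if assignment is None:
        assignment = assign_layers(network)
    lay = assignment.layer
    missing = set(network.nodes) - set(lay)
    if missing:
        raise ValueError(f"assignment does not cover nodes: {sorted(missing)[:5]}")
    last = assignment.n_layers

    rows = []
    for n_layer, members in assignment.layers.items():
        mn = {}
        for u in members:
            if degree_scope == "network":
                m = network.in_degree(u)
                n = network.out_degree(u)
            else:
                m = sum(1 for p in network.predecessors(u) if lay[p] == n_layer - 1)
                n = sum(1 for s in network.successors(u) if lay[s] == n_layer + 1)
            if n_layer == 1:
                m = 1
            if n_layer == last:
                n = 1
            mn[u] = (m, n)
        denom = sum(m * n for m, n in mn.values()) + assignment.pass_through[n_layer]
        for u in members:
            m, n = mn[u]
            pc = (m * n / denom) if denom > 0 else 0.0
            rows.append({"uid": u, "layer": n_layer, "m": m, "n": n, "pc": pc})
    return pd.DataFrame(rows).set_index("uid")


def layer_summary(assignment: LayerAssignment) -> pd.DataFrame:
    """Per-layer node count k and pass-through edge count l."""
    return pd.DataFrame(
        {
            "layer": list(assignment.layers),
            "k": [len(v) for v in assignment.layers.values()],
            "l": [assignment.pass_through[n] for n in assignment.layers],
        }
    ).set_index("layer")
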