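"""Direction assignment: contact network + response times -> Initial network.

Every undirected contact becomes exactly one directed edge pointing from
the earlier-responding residue to the later-responding one, so the
Initial network has exactly as many edges as the contact network.
Unresponsive residues (infinite response time) are treated as later than
every finite time.  Exact ties are broken deterministically toward the
sequence-earlier residue and counted in the graph attribute
``tie_edges``.
"""

from __future__ import annotations

import math

import networkx as nx

from .response import ResponseTimeTable

__all__ = ["direct_network", "write_directed_edges", "read_directed_graphml", "write_graphml"]


def _order_key(g: nx.Graph, u: str):
    # sequence rank when available, else lexicographic uid
    order = g.nodes[u].get("order")
    return (0, order) if order is not None else (1, u)


def direct_network(contacts: nx.Graph, times: ResponseTimeTable) -> nx.DiGraph:
    """Orient every contact edge by response time.

    Parameters
    ----------
    contacts : networkx.Graph
        Undirected contact network from
        :func:`dissipnet.structure.contact_network`.
    times : ResponseTimeTable
        Must cover every contact-network node (the unresponsive
        sentinel is allowed).

    Returns
    -------
    networkx.DiGraph
        The Initial network.  Nodes keep their contact-network
        attributes plus ``response_time``; graph attributes carry
        ``provenance="initial"`` and ``tie_edges``.
    """
    missing = [u for u in contacts.nodes if u not in times.response_time]
    if missing:
        raise ValueError(f"nodes without response times: {missing[:10]}")

    g = nx.DiGraph(provenance="initial", tie_edges=0, energy_cutoff=times.energy_cutoff)
    for u, data in contacts.nodes(data=True):
        g.add_node(u, response_time=times[u], **data)

    ties = 0
    for u, v, data in contacts.edges(data=True):
        tu, tv = times[u], times[v]
        if tu < tv:
            src, dst = u, v
        elif tv < tu:
            src, dst = v, u
        else:
            ties += 1
            src, dst = sorted((u, v), key=lambda w: _order_key(contacts, w))
        g.add_edge(src, dst, **data)
    g.graph["tie_edges"] = ties
    return g


def write_directed_edges(g: nx.DiGraph, path) -> None:
    """TSV edge list: src, dst, t_src_fs, t_dst_fs."""

    def fmt(t: float) -> str:
        return "unresponsive" if t is None or math.isinf(t) else f"{t:.6g}"

    with open(path, "w") as fh:
        fh.write("src\tdst\tt_src_fs\tt_dst_fs\n")
        for u, v in sorted(g.edges):
            fh.write(
                f"{u}\t{v}\t{fmt(g.nodes[u].get('response_time'))}\t"
                f"{fmt(g.nodes[v].get('response_time'))}\n"
            )


def write_graphml(g, path) -> None:
    """GraphML export; infinite response times are serialized as strings."""
    out = g.copy()
    for _, data in out.nodes(data=True):
        t = data.get("response_time")
        if t is not None and math.isinf(t):
            data["response_time"] = "unresponsive"
    nx.write_graphml(out, path)


def read_directed_graphml(path) -> nx.DiGraph:
    g = nx.read_graphml(path)
    if not g.is_directed():
        raise ValueError("expected a directed GraphML graph")
    for _, data in g.nodes(data=True):
        if data.get("response_time") == "unresponsive":
            data["response_time"] = math.inf
        elif "response_time" in data:
            data["response_time"] = float(data["response_time"])
    return nx.DiGraph(g)
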