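"""Descriptive analyses of signal-transduction networks.

Covers the summary statistics reported for the Initial / Union /
Intersection networks (node and edge counts, radius, diameter,
characteristic path length, connected-pair percentage, average
neighbor count, clustering coefficient), degree distributions and
super-hub detection, a directed motif census for 3- and 4-node
connected subgraphs, hypergeometric enrichment of annotated sites, and
residue-class distribution tables.
"""

from __future__ import annotations

import itertools
import logging
import math
from collections import Counter
from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln

logger = logging.getLogger(__name__)

__all__ = [
    "NetStats",
    "network_stats",
    "degree_distribution",
    "find_superhubs",
    "MotifCensus",
    "motif_census",
    "triad_name",
    "EnrichmentResult",
    "enrichment_probability",
    "class_distribution",
    "average_neighbors",
    "shortest_path_percentage",
]


# ---------------------------------------------------------------------------
# Network statistics
# ---------------------------------------------------------------------------

@dataclass
class NetStats:
    """Summary statistics of a directed network.

    ``radius``/``diameter``/``char_path_length`` are computed on
    directed shortest paths over reachable ordered pairs only;
    ``avg_neighbors`` and ``clustering`` on the underlying undirected
    adjacency (the convention of the Cytoscape NetworkAnalyzer).
    """

    n_nodes: int
    n_edges: int
    radius: int
    diameter: int
    char_path_length: float
    n_shortest_paths: int
    pct_shortest_paths: float
    avg_neighbors: float
    clustering: float

    def as_dict(self) -> dict:
        return asdict(self)


def average_neighbors(n_nodes: int, n_undirected_edges: int) -> float:
    """Mean neighbor count of a simple graph: 2E/N."""
    if n_nodes <= 0:
        raise ValueError("need at least one node")
    return 2.0 * n_undirected_edges / n_nodes


def shortest_path_percentage(n_connected_pairs: int, n_nodes: int) -> float:
    """Connected ordered pairs as a percentage of all n(n-1) pairs."""
    if n_nodes < 2:
        raise ValueError("need at least two nodes")
    return 100.0 * n_connected_pairs / (n_nodes * (n_nodes - 1))


def network_stats(network: nx.DiGraph, directed_clustering: bool = False) -> NetStats:
    """Compute the standard summary statistics of a directed network.

    The eccentricity of a node is the maximum shortest-path length to
    the nodes it can reach; the radius is the minimum *positive*
    eccentricity (sink nodes, which reach nothing, do not drag it to
    zero) and the diameter the maximum.
    """
    n = network.number_of_nodes()
    if n == 0:
        raise ValueError("empty network")

    lengths = dict(nx.all_pairs_shortest_path_length(network))
    dists = [d for src, row in lengths.items() for dst, d in row.items() if dst != src]
    ecc = [max(row.values()) for row in lengths.values()]
    positive_ecc = [e for e in ecc if e > 0]

    n_pairs = len(dists)
    cpl = float(np.mean(dists)) if dists else float("nan")

    und = nx.Graph(network)
    clustering = nx.average_clustering(network if directed_clustering else und)

    return NetStats(
        n_nodes=n,
        n_edges=network.number_of_edges(),
        radius=min(positive_ecc) if positive_ecc else 0,
        diameter=max(ecc) if ecc else 0,
        char_path_length=cpl,
        n_shortest_paths=n_pairs,
        pct_shortest_paths=shortest_path_percentage(n_pairs, n) if n > 1 else 0.0,
        avg_neighbors=average_neighbors(n, und.number_of_edges()),
        clustering=float(clustering),
    )


def degree_distribution(network) -> dict[int, int]:
    """Histogram of undirected neighbor counts: degree → node count."""
    und = nx.Graph(network)
    return dict(Counter(d for _, d in und.degree()))


def find_superhubs(
    network,
    structure_order: list[str] | None = None,
    degree_threshold: int = 10,
) -> tuple[list[list[str]], list[str]]:
    """Runs of sequence-consecutive residues with neighbor count above
    the threshold.

    Parameters
    ----------
    network : graph
        Directed or undirected; neighbor counts use the undirected
        adjacency.
    structure_order : list of uid, optional
        Residue uids in chain/sequence order.  If omitted, the node
        attribute ``seq_index`` (or ``order``) is used.
    degree_threshold : int
        Strict lower bound on the neighbor count (default 10).

    Returns
    -------
    (runs, singletons)
        ``runs``: maximal runs of length >= 2, each a list of uids in
        sequence order; ``singletons``: high-degree residues with no
        high-degree sequence neighbor.
    """
    und = nx.Graph(network)
    if structure_order is not None:
        position = {u: i for i, u in enumerate(structure_order)}
    else:
        position = {}
        for u, data in network.nodes(data=True):
            pos = data.get("seq_index", data.get("order"))
            if pos is not None:
                position[u] = pos
    missing = [u for u in und.nodes if u not in position]
    if missing:
        raise ValueError(f"nodes without sequence positions: {missing[:10]}")

    hot = sorted(
        (u for u, d in und.degree() if d > degree_threshold),
        key=position.get,
    )
    runs: list[list[str]] = []
    current: list[str] = []
    for u in hot:
        if current and position[u] == position[current[-1]] + 1:
            current.append(u)
        else:
            if current:
                runs.append(current)
            current = [u]
    if current:
        runs.append(current)
    singletons = [r[0] for r in runs if len(r) == 1]
    return [r for r in runs if len(r) >= 2], singletons


# ---------------------------------------------------------------------------
# Motif census
# ---------------------------------------------------------------------------

@dataclass
class MotifCensus:
    """Occurrence counts of connected directed subgraph classes.

    ``counts`` maps a canonical class label (bit-serialization of the
    lexicographically smallest adjacency matrix over node
    permutations) to the number of induced occurrences; ``frequencies``
    normalizes by the total.
    """

    size: int
    counts: dict[str, int]
    frequencies: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        """Table ordered by edge count, then descending frequency."""
        rows = [
            {
                "motif": label,
                "n_edges": label.count("1"),
                "count": c,
                "frequency": self.frequencies[label],
                "triad": triad_name(label) if self.size == 3 else "",
            }
            for label, c in self.counts.items()
        ]
        df = pd.DataFrame(rows)
        return df.sort_values(
            ["n_edges", "frequency", "motif"], ascending=[True, False, True]
        ).reset_index(drop=True)


def _canonical_label(adj: np.ndarray) -> str:
    """Lexicographically smallest row-major bit string over all node
    permutations of a small directed adjacency matrix."""
    k = len(adj)
    best = None
    for perm in itertools.permutations(range(k)):
        bits = "".join(str(adj[i][j]) for i in perm for j in perm)
        if best is None or bits < best:
            best = bits
    return best


def _connected_subsets(und_neighbors: dict, nodes: list, size: int):
    """Enumerate connected induced node subsets of the given size (ESU)."""
    index = {u: i for i, u in enumerate(nodes)}

    def extend(sub: list, extension: set, v_idx: int):
        if len(sub) == size:
            yield tuple(sub)
            return
        ext = set(extension)
        sub_nbrs = set().union(*(und_neighbors[u] for u in sub))
        while ext:
            w = ext.pop()
            new_ext = ext | {
                u
                for u in und_neighbors[w]
                if index[u] > v_idx and u not in sub and u not in sub_nbrs
            }
            yield from extend(sub + [w], new_ext, v_idx)

    for v in nodes:
        ext = {u for u in und_neighbors[v] if index[u] > index[v]}
        yield from extend([v], ext, index[v])


def motif_census(network: nx.DiGraph, size: int = 3) -> MotifCensus:
    """Census of weakly connected induced directed subgraphs.

    Every connected ``size``-node induced subgraph is assigned to its
    directed-isomorphism class via a canonical adjacency-matrix label;
    counts and frequencies over classes are returned.
    """
    if size not in (3, 4):
        raise ValueError("motif size must be 3 or 4")
    nodes = list(network.nodes)
    und_neighbors = {
        u: set(network.successors(u)) | set(network.predecessors(u)) for u in nodes
    }
    counts: Counter = Counter()
    for subset in _connected_subsets(und_neighbors, nodes, size):
        adj = [
            [1 if network.has_edge(u, v) else 0 for v in subset] for u in subset
        ]
        counts[_canonical_label(np.asarray(adj))] += 1
    total = sum(counts.values())
    freqs = {label: c / total for label, c in counts.items()} if total else {}
    return MotifCensus(size=size, counts=dict(counts), frequencies=freqs)


def _build_triad_names() -> dict[str, str]:
    # the 13 weakly connected classes of the standard 16-triad taxonomy
    names = [
        "021D", "021U", "021C", "111D", "111U", "030T", "030C",
        "201", "120D", "120U", "120C", "210", "300",
    ]
    table = {}
    for name in names:
        g = nx.triad_graph(name)
        adj = nx.to_numpy_array(g, dtype=int)
        table[_canonical_label(adj)] = name
    return table


_TRIAD_NAMES: dict[str, str] | None = None


def triad_name(label: str) -> str:
    """Standard triad-census name for a canonical 3-node class label."""
    global _TRIAD_NAMES
    if _TRIAD_NAMES is None:
        _TRIAD_NAMES = _build_triad_names()
    return _TRIAD_NAMES.get(label, "?")


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    """Probability that `sample` residues drawn from `population`
    contain all `hits` annotated sites."""

    population: int
    sample: int
    hits: int
    p: float
    log10_p: float


def _log_comb(n: float, k: float) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def enrichment_probability(population: int, sample: int, hits: int) -> EnrichmentResult:
    """Chance of catching every annotated site in a random sample.

    Computed in log-space two algebraically identical ways —
    ``C(sample, hits) / C(population, hits)`` and the hypergeometric
    form ``C(hits, hits) * C(population - hits, sample - hits) /
    C(population, sample)`` — which must agree to 1e-12 relative
    tolerance; the common value is returned.
    """
    if not 0 <= hits <= sample <= population:
        raise ValueError(
            f"need 0 <= hits <= sample <= population, got {hits}, {sample}, {population}"
        )
    log_p_comb = _log_comb(sample, hits) - _log_comb(population, hits)
    log_p_hyper = _log_comb(population - hits, sample - hits) - _log_comb(population, sample)
    if not math.isclose(log_p_comb, log_p_hyper, rel_tol=1e-12, abs_tol=1e-12):
        raise AssertionError(
            f"combination and hypergeometric forms disagree: {log_p_comb} vs {log_p_hyper}"
        )
    log_p = 0.5 * (log_p_comb + log_p_hyper)
    return EnrichmentResult(
        population=population,
        sample=sample,
        hits=hits,
        p=float(math.exp(log_p)),
        log10_p=float(log_p / math.log(10)),
    )


# ---------------------------------------------------------------------------
# Residue-class distributions
# ---------------------------------------------------------------------------

def class_distribution(
    node_set,
    annotations: pd.DataFrame,
    conservation_bins=None,
) -> dict[str, pd.Series]:
    """Fraction of network residues per annotation category.

    Parameters
    ----------
    node_set : iterable of uid
        Residues of one network.
    annotations : pandas.DataFrame
        Indexed by residue uid; recognised columns are ``region``,
        ``sec_struct``, ``polarity_class`` (categorical) and
        ``conservation`` (numeric in [0, 1], binned).
    conservation_bins : array-like, optional
        Bin edges for conservation (default width 0.1 on [0, 1]).

    Returns
    -------
    dict of column name → Series of fractions (sums to 1 per column).
    Unannotated residues fall into an ``"unknown"`` bucket with a
    logged warning.
    """
    nodes = list(node_set)
    if not nodes:
        raise ValueError("empty node set")
    missing = [u for u in nodes if u not in annotations.index]
    if missing:
        logger.warning("%d residues lack annotations; binned as 'unknown'", len(missing))

    out: dict[str, pd.Series] = {}
    for col in annotations.columns:
        if col == "conservation":
            edges = np.asarray(
                conservation_bins if conservation_bins is not None else np.linspace(0, 1, 11)
            )
            values = annotations[col].reindex(nodes)
            binned = pd.cut(values, bins=edges, include_lowest=True).astype(str)
            binned[values.isna()] = "unknown"
            counts = binned.value_counts()
        else:
            values = annotations[col].reindex(nodes).fillna("unknown")
            counts = values.value_counts()
        out[col] = (counts / len(nodes)).sort_index()
    return out
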