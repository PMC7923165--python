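"""Topological diagnostics separating biological from random networks.

Scale-freeness is assessed the way the classical network analyzers do:
a least-squares line on the log-log degree histogram, reported as the
fitted exponent plus the correlation R^2. Small-world character is read
from the mean clustering coefficient (undirected projection) and the
characteristic path length (mean directed shortest-path hop count over
reachable ordered pairs). Focal-node metrics profile the kinase of
interest: degrees, neighborhood connectivity, harmonic closeness,
betweenness, and mean shortest-path lengths from/through the node.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import FitUndefinedError, P2NError
from .netbuild import SignalingNetwork


@dataclass
class PowerLawFit:
    exponent: float  # -slope of the log-log regression
    r_squared: float
    slope: float
    intercept: float


@dataclass
class FocalMetrics:
    node: str
    in_degree: int
    out_degree: int
    degree: int
    neighborhood_connectivity: float
    closeness: float
    betweenness: float
    mean_path_length_from: float | None
    mean_path_length_through: float | None


@dataclass
class TopologyReport:
    n_nodes: int
    n_edges: int
    degree_histogram: dict[int, int]
    in_degree_histogram: dict[int, int]
    out_degree_histogram: dict[int, int]
    power_law: PowerLawFit | None
    mean_clustering: float
    char_path_length: float | None
    path_length_distribution: dict[int, int]
    focal: FocalMetrics | None = None


def power_law_fit_from_histogram(
    degrees: np.ndarray, freqs: np.ndarray
) -> PowerLawFit:
    """Least-squares line on (log10 degree, log10 frequency).

    Only strictly positive degrees with nonzero frequency enter the fit;
    at least 3 distinct such degrees are required.
    """
    degrees = np.asarray(degrees, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    mask = (degrees > 0) & (freqs > 0)
    x = np.log10(degrees[mask])
    y = np.log10(freqs[mask])
    if len(np.unique(x)) < 3:
        raise FitUndefinedError(
            "power-law fit needs >=3 distinct positive degree values"
        )
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - float((resid**2).sum()) / ss_tot
    return PowerLawFit(
        exponent=-float(slope),
        r_squared=r2,
        slope=float(slope),
        intercept=float(intercept),
    )


def degree_power_law_fit(
    net: SignalingNetwork, mode: str = "total"
) -> PowerLawFit:
    """Fit the degree ('node connectivity') distribution to a power law.

    ``mode`` selects total degree of the undirected projection (default),
    or ``in``/``out`` degree of the directed graph.
    """
    g = net.graph
    if mode == "total":
        deg = [d for _, d in g.to_undirected(as_view=True).degree()]
    elif mode == "in":
        deg = [d for _, d in g.in_degree()]
    elif mode == "out":
        deg = [d for _, d in g.out_degree()]
    else:
        raise P2NError(f"unknown degree mode {mode!r}")
    counts = Counter(d for d in deg if d > 0)
    ds = np.array(sorted(counts))
    fs = np.array([counts[d] for d in ds])
    return power_law_fit_from_histogram(ds, fs)


def _path_length_distribution(g: nx.DiGraph) -> dict[int, int]:
    dist: Counter[int] = Counter()
    for src in g.nodes:
        lengths = nx.single_source_shortest_path_length(g, src)
        for tgt, d in lengths.items():
            if tgt != src:
                dist[d] += 1
    return dict(sorted(dist.items()))


def characteristic_path_length(g: nx.DiGraph) -> tuple[float | None, dict[int, int]]:
    """Mean directed hop distance over reachable ordered pairs."""
    dist = _path_length_distribution(g)
    total = sum(dist.values())
    if total == 0:
        return None, dist
    return sum(d * c for d, c in dist.items()) / total, dist


def global_topology(net: SignalingNetwork) -> TopologyReport:
    """Degree histograms, power-law fit, clustering and path lengths."""
    g = net.graph
    if g.number_of_nodes() == 0:
        raise P2NError("topology of an empty network is undefined")
    und = g.to_undirected(as_view=True)
    try:
        plfit = degree_power_law_fit(net)
    except FitUndefinedError:
        plfit = None
    cpl, dist = characteristic_path_length(g)
    return TopologyReport(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        degree_histogram=dict(sorted(Counter(d for _, d in und.degree()).items())),
        in_degree_histogram=dict(sorted(Counter(d for _, d in g.in_degree()).items())),
        out_degree_histogram=dict(sorted(Counter(d for _, d in g.out_degree()).items())),
        power_law=plfit,
        mean_clustering=nx.average_clustering(und),
        char_path_length=cpl,
        path_length_distribution=dist,
    )


def focal_node_metrics(net: SignalingNetwork, focal: str) -> FocalMetrics:
    """Per-node profile of the focal kinase.

    Closeness is harmonic: sum over reachable nodes of 1/d(focal, u),
    normalized by n-1, which stays defined on disconnected directed
    graphs. Betweenness is directed and normalized. The mean path length
    *through* the node averages d(s, t) over ordered pairs (s, t), both
    distinct from the node, for which it lies on at least one shortest
    path, i.e. d(s, v) + d(v, t) = d(s, t); the mean path length *from*
    it averages outgoing distances to reachable nodes.
    """
    g = net.graph
    if focal not in g:
        raise P2NError(f"focal node {focal} not in network")
    n = g.number_of_nodes()
    neighbors = set(g.predecessors(focal)) | set(g.successors(focal))
    und = g.to_undirected(as_view=True)
    neigh_conn = (
        float(np.mean([und.degree(u) for u in sorted(neighbors)])) if neighbors else 0.0
    )
    out_dist = nx.single_source_shortest_path_length(g, focal)
    reach_out = {u: d for u, d in out_dist.items() if u != focal}
    closeness = (
        sum(1.0 / d for d in reach_out.values()) / (n - 1) if n > 1 else 0.0
    )
    betweenness = nx.betweenness_centrality(g, normalized=True)[focal]
    mean_from = (
        sum(reach_out.values()) / len(reach_out) if reach_out else None
    )
    # distances into the focal node, for the through-node criterion
    in_dist = nx.single_source_shortest_path_length(g.reverse(copy=False), focal)
    through_lengths = []
    for s, d_sv in in_dist.items():
        if s == focal:
            continue
        s_dist = nx.single_source_shortest_path_length(g, s)
        for t, d_vt in reach_out.items():
            if t == s:
                continue
            d_st = s_dist.get(t)
            if d_st is not None and d_sv + d_vt == d_st:
                through_lengths.append(d_st)
    mean_through = (
        sum(through_lengths) / len(through_lengths) if through_lengths else None
    )
    return FocalMetrics(
        node=focal,
        in_degree=g.in_degree(focal),
        out_degree=g.out_degree(focal),
        degree=g.in_degree(focal) + g.out_degree(focal),
        neighborhood_connectivity=neigh_conn,
        closeness=closeness,
        betweenness=betweenness,
        mean_path_length_from=mean_from,
        mean_path_length_through=mean_through,
    )
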