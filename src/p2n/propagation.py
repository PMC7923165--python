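"""Random-walk-weighted shortest-path propagation from the focal kinase.

Edges are weighted w(u→v) = log2(outdeg(u)), so a path's total weight is
-log2 of the probability that an unbiased random walk starting at the
path's source follows exactly that edge sequence; the minimum-weight path
is therefore the maximum-probability walk. On top of the k best loopless
paths (Yen's algorithm), every path within ``epsilon`` weight of the
optimum — epsilon bits of walk probability — is kept as "near-shortest".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx

from .core import GoAnnotation, TargetDataset
from .errors import P2NError
from .netbuild import SignalingNetwork

logger = logging.getLogger(__name__)

_TOL = 1e-9

SCHEME_RANDOM_WALK = "random_walk"
SCHEME_UNIT = "unit"


@dataclass(frozen=True)
class WeightedPath:
    nodes: tuple[str, ...]
    weight: float


@dataclass
class EdgeWeighting:
    scheme: str
    weights: dict[tuple[str, str], float]

    def path_weight(self, nodes: tuple[str, ...]) -> float:
        return sum(self.weights[(u, v)] for u, v in zip(nodes, nodes[1:]))


@dataclass
class PathEnsemble:
    source: str
    paths: dict[str, dict[str, list[WeightedPath]]]  # condition -> target -> paths
    unreachable: dict[str, list[str]]
    subnetwork: SignalingNetwork
    params: dict


def weight_edges(net: SignalingNetwork, scheme: str = SCHEME_RANDOM_WALK) -> EdgeWeighting:
    """Assign per-edge weights.

    ``random_walk``: w(u→v) = log2(outdeg(u)) (0 for a forced step, so the
    weight of a path is the information content of the corresponding
    walk). ``unit``: w = 1, giving hop-shortest paths.
    """
    import math

    g = net.graph
    if g.number_of_nodes() == 0:
        raise P2NError("cannot weight an empty network")
    weights: dict[tuple[str, str], float] = {}
    for u, v in g.edges:
        if scheme == SCHEME_RANDOM_WALK:
            weights[(u, v)] = math.log2(g.out_degree(u))
        elif scheme == SCHEME_UNIT:
            weights[(u, v)] = 1.0
        else:
            raise P2NError(f"unknown weighting scheme {scheme!r}")
    return EdgeWeighting(scheme=scheme, weights=weights)


def k_shortest_paths(
    net: SignalingNetwork,
    weights: EdgeWeighting,
    source: str,
    target: str,
    k: int = 5,
    epsilon: float = 1.0,
) -> list[WeightedPath]:
    """Best loopless paths from source to target under the weighting.

    Keeps the k lowest-weight simple paths plus every path whose weight
    is within ``epsilon`` of the minimum (the near-shortest extension).
    Output is sorted by ascending weight, ties by lexicographic node
    sequence. An unreachable target yields an empty list.
    """
    if k < 1 or epsilon < 0:
        raise P2NError("k must be >=1 and epsilon >=0")
    g = net.graph
    if source not in g or target not in g:
        return []

    def wfunc(u, v, _data):
        return weights.weights[(u, v)]

    collected: list[WeightedPath] = []
    w_min: float | None = None
    try:
        for nodes in nx.shortest_simple_paths(g, source, target, weight=wfunc):
            path = WeightedPath(tuple(nodes), weights.path_weight(tuple(nodes)))
            if w_min is None:
                w_min = path.weight
            if len(collected) >= k and path.weight > w_min + epsilon + _TOL:
                # collect through the tie class at the k-th position so
                # equal-weight alternatives are broken lexicographically
                kth = sorted(p.weight for p in collected)[k - 1]
                if path.weight > kth + _TOL:
                    break
            collected.append(path)
    except nx.NetworkXNoPath:
        return []
    collected.sort(key=lambda p: (p.weight, p.nodes))
    return [
        p
        for i, p in enumerate(collected)
        if i < k or p.weight <= w_min + epsilon + _TOL
    ]


MODE_ALL_PATHWAYS = "all_pathways"
MODE_ENRICHED_ONLY = "enriched_only"


def propagation_subnetwork(
    net: SignalingNetwork,
    weights: EdgeWeighting,
    source: str,
    datasets: list[TargetDataset],
    k: int = 5,
    epsilon: float = 1.0,
    mode: str = MODE_ALL_PATHWAYS,
    condition_networks: dict[str, SignalingNetwork] | None = None,
    include_direct: bool = True,
    end_at_modifier: bool = False,
) -> PathEnsemble:
    """Paths from the focal kinase to every condition's targets, unioned.

    ``all_pathways`` mode runs every condition over the one shared
    prior-knowledge network ``net`` (removing reconstruction bias from the
    comparison); ``enriched_only`` uses each condition's own built network
    from ``condition_networks``. The union subnetwork labels each node and
    edge with the set of conditions whose paths use it. Targets that are
    direct successors of the source always contribute their one-edge path
    (``include_direct``). With ``end_at_modifier`` paths are kept only if
    their penultimate node is an annotated phospho-modifier — a
    plausibility filter for the terminal (de)phosphorylation step.
    """
    if mode not in (MODE_ALL_PATHWAYS, MODE_ENRICHED_ONLY):
        raise P2NError(f"unknown propagation mode {mode!r}")
    if mode == MODE_ENRICHED_ONLY and not condition_networks:
        raise P2NError("enriched_only mode needs per-condition networks")
    if source not in net.graph:
        raise P2NError(f"source {source} absent from the prior-knowledge network")

    all_paths: dict[str, dict[str, list[WeightedPath]]] = {}
    unreachable: dict[str, list[str]] = {}
    union = nx.DiGraph()
    for ds in datasets:
        if mode == MODE_ALL_PATHWAYS:
            cnet, cweights = net, weights
        else:
            cnet = condition_networks[ds.name]
            cweights = weight_edges(cnet, weights.scheme)
        cond_paths: dict[str, list[WeightedPath]] = {}
        cond_unreachable: list[str] = []
        for target in sorted(ds.accessions):
            if target == source:
                continue
            paths = k_shortest_paths(cnet, cweights, source, target, k, epsilon)
            if end_at_modifier:
                paths = [
                    p
                    for p in paths
                    if len(p.nodes) >= 2
                    and cnet.graph.nodes[p.nodes[-2]].get("is_modifier", False)
                ]
            if include_direct and cnet.graph.has_edge(source, target):
                direct = WeightedPath(
                    (source, target), cweights.weights[(source, target)]
                )
                if direct not in paths:
                    paths = sorted(paths + [direct], key=lambda p: (p.weight, p.nodes))
            if not paths:
                cond_unreachable.append(target)
                continue
            cond_paths[target] = paths
            for p in paths:
                for node in p.nodes:
                    if node not in union:
                        union.add_node(node, conditions=set())
                    union.nodes[node]["conditions"].add(ds.name)
                for u, v in zip(p.nodes, p.nodes[1:]):
                    if not union.has_edge(u, v):
                        union.add_edge(
                            u, v,
                            conditions=set(),
                            weight=cweights.weights[(u, v)],
                            sign=cnet.graph[u][v].get("sign", "unknown"),
                        )
                    union[u][v]["conditions"].add(ds.name)
        all_paths[ds.name] = cond_paths
        unreachable[ds.name] = cond_unreachable
        logger.info(
            "%s: %d targets reached, %d unreachable",
            ds.name, len(cond_paths), len(cond_unreachable),
        )
    for _, data in union.nodes(data=True):
        data["conditions"] = frozenset(data["conditions"])
    for _, _, data in union.edges(data=True):
        data["conditions"] = frozenset(data["conditions"])
    subnet = SignalingNetwork(
        graph=union,
        name=f"propagation-{source}",
        metadata={
            "source": source,
            "mode": mode,
            "k": k,
            "epsilon": epsilon,
            "scheme": weights.scheme,
            "reached": {c: len(p) for c, p in all_paths.items()},
            "unreachable": {c: len(u) for c, u in unreachable.items()},
        },
    )
    return PathEnsemble(
        source=source,
        paths=all_paths,
        unreachable=unreachable,
        subnetwork=subnet,
        params={"k": k, "epsilon": epsilon, "scheme": weights.scheme, "mode": mode},
    )


def restrict_targets_by_go(
    ds: TargetDataset, go: GoAnnotation, group: str
) -> TargetDataset:
    """Keep only targets directly annotated with a term of the GO group."""
    if group not in go.groups:
        raise P2NError(
            f"unknown GO group {group!r}; configured groups: {sorted(go.groups)}"
        )
    member_accs = go.accessions_for_terms(go.groups[group])
    kept = {acc: t for acc, t in ds.targets.items() if acc in member_accs}
    if not kept:
        logger.warning("%s: no targets in GO group %s", ds.name, group)
    return TargetDataset(
        name=f"{ds.name}[{group}]", targets=kept, direction_filtered=ds.direction_filtered
    )
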