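"""Multi-network alignment, presence labels and node rewiring.

Condition networks are aligned by identity: nodes correspond by
accession, edges by their ordered (source, target) pair with minimal edge
properties (sign and provenance are ignored so database origin never
splits a correspondence). Every element of the fused graph carries a
presence set — the input networks that contain it — from which the
common / exclusive / shared-by-subset labels derive. Rewiring of a node
between two sides of the fusion is the Jaccard distance of its incident
directed edge sets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .errors import P2NError
from .netbuild import SignalingNetwork

logger = logging.getLogger(__name__)


@dataclass
class FusionNetwork:
    """Union graph of aligned networks with per-element presence sets."""

    graph: nx.DiGraph
    origins: tuple[str, ...]

    def node_presence(self, node: str) -> frozenset[str]:
        return self.graph.nodes[node]["presence"]

    def edge_presence(self, u: str, v: str) -> frozenset[str]:
        return self.graph[u][v]["presence"]


def presence_label(
    presence: frozenset[str],
    origins: tuple[str, ...],
    sides: dict[str, set[str]] | None = None,
) -> str:
    """Map a presence set to common / exclusive-to-X / shared-by-subset.

    With ``sides`` given (e.g. breast-cancer = {MCF7, MDA231} vs lymphoma
    = {DG75}), presence confined to one side is exclusive to that side;
    otherwise single-origin presence is exclusive to that origin.
    """
    if not presence:
        raise P2NError("presence set must be nonempty")
    if presence == frozenset(origins):
        return "common"
    if sides:
        for label, members in sides.items():
            if presence <= members:
                return f"exclusive-to-{label}"
    if len(presence) == 1:
        return f"exclusive-to-{next(iter(presence))}"
    return "shared-by-subset"


def _net_origins(net: SignalingNetwork) -> frozenset[str]:
    """Origin labels of a network: its merge origins if it is a merge,
    otherwise its own name."""
    merged = net.metadata.get("merged_from")
    return frozenset(merged) if merged else frozenset({net.name})


def merge_condition_networks(
    nets: list[SignalingNetwork], label: str
) -> SignalingNetwork:
    """Node/edge union of condition networks, keeping element origins.

    Node attribute ``origins`` (and likewise per edge) records which input
    networks contained the element; target annotations are merged across
    inputs.
    """
    if not nets:
        raise P2NError("merge needs at least one network")
    g = nx.DiGraph()
    all_origins: set[str] = set()
    for net in nets:
        origins = _net_origins(net)
        all_origins |= origins
        for node, data in net.graph.nodes(data=True):
            node_origins = frozenset(data.get("origins", origins))
            if node in g:
                g.nodes[node]["origins"] = g.nodes[node]["origins"] | node_origins
                merged_targets = dict(g.nodes[node].get("targets", {}))
                merged_targets.update(data.get("targets", {}))
                g.nodes[node]["targets"] = merged_targets
            else:
                g.add_node(
                    node,
                    origins=node_origins,
                    targets=dict(data.get("targets", {})),
                    symbol=data.get("symbol", ""),
                    is_modifier=data.get("is_modifier", False),
                    is_focal=data.get("is_focal", False),
                )
        for u, v, data in net.graph.edges(data=True):
            edge_origins = frozenset(data.get("origins", origins))
            if g.has_edge(u, v):
                g[u][v]["origins"] = g[u][v]["origins"] | edge_origins
            else:
                g.add_edge(
                    u, v,
                    origins=edge_origins,
                    sign=data.get("sign", "unknown"),
                    provenance=data.get("provenance", frozenset()),
                    dbs=data.get("dbs", frozenset()),
                )
    return SignalingNetwork(
        graph=g, name=label, metadata={"merged_from": sorted(all_origins)}
    )


def align_networks(a: SignalingNetwork, b: SignalingNetwork) -> FusionNetwork:
    """Identity alignment of two (possibly merged) networks.

    Nodes correspond by accession, edges by ordered endpoint pair.
    Presence sets are expressed in origin labels (for merged inputs, the
    per-element origins recorded by the merge), and per-node rewiring
    between the two sides is stored as a node attribute.
    """
    side_a, side_b = _net_origins(a), _net_origins(b)
    fused = merge_condition_networks([a, b], label=f"{a.name}+{b.name}")
    g = fused.graph
    origins = tuple(sorted(side_a | side_b))
    for _, data in g.nodes(data=True):
        data["presence"] = data.pop("origins")
    for _, _, data in g.edges(data=True):
        data["presence"] = data.pop("origins")
    fn = FusionNetwork(graph=g, origins=origins)
    if side_a & side_b:
        # self-alignment (or overlapping origins): no two-sided contrast
        scores: dict[str, float] = {}
    else:
        report = rewiring_scores(fn, set(side_a), set(side_b))
        scores = dict(zip(report["accession"], report["rewiring"]))
    sides = {a.name: set(side_a), b.name: set(side_b)}
    for node, data in g.nodes(data=True):
        data["rewiring"] = scores.get(node, 0.0)
        data["label"] = presence_label(data["presence"], origins, sides)
    for u, v, data in g.edges(data=True):
        data["label"] = presence_label(data["presence"], origins, sides)
    return fn


def rewiring_scores(
    fn: FusionNetwork,
    side_a: set[str],
    side_b: set[str],
    degree_corrected: bool = False,
) -> pd.DataFrame:
    """Per-node rewiring between two sides of a fusion network.

    For node v let E_a(v), E_b(v) be its incident directed edges present
    on each side. The score is the Jaccard distance
    1 - |E_a ∩ E_b| / |E_a ∪ E_b|; nodes with no incident edge on either
    side are excluded (noted in the log). ``degree_corrected`` multiplies
    by sqrt(min(|E_a|, |E_b|)) to de-emphasize low-degree nodes.

    Returns a frame sorted by descending score, ties by accession, with
    the incident / shared / union edge counts.
    """
    overlap = side_a & side_b
    if overlap:
        raise P2NError(f"sides must be disjoint, both contain {sorted(overlap)}")
    g = fn.graph
    rows = []
    skipped = 0
    for node in sorted(g.nodes):
        incident = [(u, v) for u, v in g.in_edges(node)] + [
            (u, v) for u, v in g.out_edges(node)
        ]
        e_a = {e for e in incident if g[e[0]][e[1]]["presence"] & side_a}
        e_b = {e for e in incident if g[e[0]][e[1]]["presence"] & side_b}
        union = e_a | e_b
        if not union:
            skipped += 1
            continue
        score = 1.0 - len(e_a & e_b) / len(union)
        if degree_corrected:
            score *= math.sqrt(min(len(e_a), len(e_b)))
        rows.append(
            {
                "accession": node,
                "rewiring": score,
                "n_side_a": len(e_a),
                "n_side_b": len(e_b),
                "n_shared": len(e_a & e_b),
                "n_union": len(union),
            }
        )
    if skipped:
        logger.info("%d nodes with no incident edges on either side excluded", skipped)
    df = pd.DataFrame(
        rows,
        columns=["accession", "rewiring", "n_side_a", "n_side_b", "n_shared", "n_union"],
    )
    return df.sort_values(
        ["rewiring", "accession"], ascending=[False, True]
    ).reset_index(drop=True)


def proximal_subnetwork(
    net: SignalingNetwork | FusionNetwork, seeds: set[str]
) -> SignalingNetwork | FusionNetwork:
    """First-neighbor subnetwork of the seed proteins.

    Induced subgraph on the seeds, their in- and out-neighbors, and every
    interaction among them; all annotations are preserved.
    """
    g = net.graph
    missing = sorted(set(seeds) - set(g.nodes))
    if missing:
        raise P2NError(f"seed accessions not in graph: {missing}")
    nodes = set(seeds)
    for s in seeds:
        nodes |= set(g.predecessors(s)) | set(g.successors(s))
    sub = g.subgraph(nodes).copy()
    if isinstance(net, FusionNetwork):
        return FusionNetwork(graph=sub, origins=net.origins)
    return SignalingNetwork(
        graph=sub, name=f"{net.name}-proximal", metadata=dict(net.metadata)
    )
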