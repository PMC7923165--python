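"""Ground-truth-bearing synthetic inputs for every pipeline stage.

The generator emulates the shape of the real inputs: a scale-free
directed interactome (preferential attachment, so the degree histogram
shows the power-law/small-world structure typical of curated signaling
databases), pathways as overlapping connected node subsets (snowball
samples), per-condition target lists with planted enrichment in chosen
pathways, and condition pairs with planted edge rewiring around chosen
nodes. Everything is deterministic under (spec, seed); independent
sub-streams are derived by hashing the master seed with a purpose label.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .core import (
    SIGNS,
    Interaction,
    Pathway,
    PathwayDB,
    PhosphoTarget,
    Protein,
    TargetDataset,
)
from .errors import ValidationError
from .netbuild import SignalingNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters; defaults define the reference study conditions.

    ``p_in`` is the probability a target is drawn from an enriched
    pathway's members, ``p_out`` the complementary background draw
    probability (spread uniformly over the universe).
    """

    n_proteins: int = 2000
    m: int = 3  # preferential-attachment edges per new node
    n_pathways: int = 40
    pathway_size_range: tuple[int, int] = (20, 60)
    n_enriched: int = 3
    p_in: float = 0.7
    p_out: float = 0.3
    n_targets: int = 150
    n_conditions: int = 3
    rewire_fraction: float = 0.5
    n_rewired_nodes: int = 10
    sign_ratios: tuple[float, float, float] = (0.45, 0.25, 0.30)
    reciprocal_prob: float = 0.1
    n_sites_range: tuple[int, int] = (1, 2)
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.p_out < self.p_in <= 1):
            raise ValidationError("need 0 <= p_out < p_in <= 1")
        if abs(self.p_in + self.p_out - 1) > 1e-9:
            raise ValidationError("p_in + p_out must sum to 1")
        if not (0 <= self.rewire_fraction <= 1):
            raise ValidationError("rewire fraction must be in [0, 1]")
        for name in (
            "n_proteins", "m", "n_pathways", "n_enriched", "n_targets",
            "n_conditions", "n_rewired_nodes",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.n_proteins < self.m + 1:
            raise ValidationError("n_proteins must exceed the attachment parameter")
        lo, hi = self.pathway_size_range
        if not (1 <= lo <= hi <= self.n_proteins):
            raise ValidationError("unsatisfiable pathway size range")


@dataclass
class GroundTruth:
    enriched: set[str] = field(default_factory=set)
    rewired: set[str] = field(default_factory=set)
    target_origin: dict[str, dict[str, str]] = field(default_factory=dict)
    focal: str | None = None


def subseed(master: int, label: str, index: int = 0) -> int:
    """Independent reproducible sub-stream seed from (master, label, index)."""
    digest = hashlib.blake2b(
        f"{master}:{label}:{index}".encode(), digest_size=4
    ).digest()
    return int.from_bytes(digest, "big")


def _accession(i: int) -> str:
    return f"SP{i:05d}"


def gen_interactome(spec: SyntheticSpec) -> SignalingNetwork:
    """Directed scale-free interactome via preferential attachment.

    An undirected Barabási–Albert graph is generated, each edge is given
    a random orientation (made reciprocal with probability
    ``reciprocal_prob``) and a sign drawn at the configured
    activate/inhibit/unknown ratios.
    """
    spec.validate()
    rng = np.random.default_rng(subseed(spec.seed, "interactome"))
    und = nx.barabasi_albert_graph(spec.n_proteins, spec.m, seed=int(rng.integers(2**31)))
    g = nx.DiGraph()
    g.add_nodes_from(_accession(i) for i in und.nodes)
    for u, v in sorted(und.edges):
        a, b = _accession(u), _accession(v)
        if rng.random() < 0.5:
            a, b = b, a
        sign = SIGNS[rng.choice(3, p=spec.sign_ratios)]
        g.add_edge(a, b, sign=sign)
        if rng.random() < spec.reciprocal_prob:
            sign2 = SIGNS[rng.choice(3, p=spec.sign_ratios)]
            g.add_edge(b, a, sign=sign2)
    return SignalingNetwork(
        graph=g, name="interactome", metadata={"synthetic": True, "seed": spec.seed}
    )


def _snowball(und: nx.Graph, start, size: int, rng: np.random.Generator) -> set:
    """Randomized breadth-limited snowball sample of ``size`` nodes."""
    members = {start}
    frontier = [start]
    while frontier and len(members) < size:
        nxt = []
        for node in frontier:
            neigh = [n for n in und.neighbors(node) if n not in members]
            rng.shuffle(neigh)
            for n in neigh:
                if len(members) >= size:
                    break
                members.add(n)
                nxt.append(n)
        frontier = nxt
    return members


def gen_pathway_db(
    net: SignalingNetwork, spec: SyntheticSpec
) -> tuple[PathwayDB, GroundTruth]:
    """Pathways as overlapping snowball node subsets of the interactome.

    Interactions are the interactome's edges; each carries as provenance
    the pathways containing both endpoints. ``n_enriched`` pathways are
    marked ground-truth enriched; they are the focal kinase's own
    pathways, snowballed from the focal node (the highest-degree hub), so
    they overlap around its signaling core the way one kinase's enriched
    pathways share components in curated databases. Background pathways
    snowball from uniformly chosen start nodes.
    """
    spec.validate()
    rng = np.random.default_rng(subseed(spec.seed, "pathways"))
    und = net.graph.to_undirected(as_view=True)
    nodes = sorted(net.graph.nodes)
    focal = max(nodes, key=lambda n: (und.degree(n), n))
    enriched_idx = set(
        int(i) for i in rng.choice(spec.n_pathways, size=spec.n_enriched, replace=False)
    )
    lo, hi = spec.pathway_size_range
    pathways: dict[str, Pathway] = {}
    for i in range(spec.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        if i in enriched_idx:
            start = focal
        else:
            start = nodes[int(rng.integers(len(nodes)))]
        members = _snowball(und, start, size, rng)
        if len(members) < lo:
            raise ValidationError(
                f"snowball from {start} exhausted its component below size {lo}"
            )
        pw_id = f"sim:PW{i:03d}"
        pathways[pw_id] = Pathway(
            id=pw_id, name=f"synthetic pathway {i}", source="sim",
            members=frozenset(members),
        )
    interactions = []
    for u, v, data in sorted(net.graph.edges(data=True)):
        prov = frozenset(
            pw.id for pw in pathways.values() if u in pw.members and v in pw.members
        )
        interactions.append(
            Interaction(u, v, sign=data.get("sign", "unknown"),
                        provenance=prov, dbs=frozenset({"sim"}))
        )
    db = PathwayDB(pathways=pathways, interactions=interactions)
    enriched = {f"sim:PW{i:03d}" for i in enriched_idx}
    return db, GroundTruth(enriched=enriched, focal=focal)


def gen_target_lists(
    db: PathwayDB,
    truth: GroundTruth,
    spec: SyntheticSpec,
    n_conditions: int | None = None,
) -> list[TargetDataset]:
    """Per-condition target lists with planted enrichment.

    Each target is drawn from the enriched pathways' member union with
    probability ``p_in``, otherwise uniformly from the universe; draws
    colliding with already-chosen targets are repeated. Phosphosites are
    random residue positions; per-condition streams derive from the
    master seed, so conditions differ under the same seed.
    """
    spec.validate()
    if not truth.enriched:
        raise ValidationError("ground truth has no enriched pathways")
    n_conditions = n_conditions or spec.n_conditions
    universe = sorted(db.universe)
    if spec.n_targets > len(universe):
        raise ValidationError("more targets requested than universe members")
    enriched_members = sorted(
        set().union(*(db.pathways[p].members for p in truth.enriched))
    )
    member_of = {
        acc: p
        for p in sorted(truth.enriched)
        for acc in db.pathways[p].members
    }
    datasets = []
    for c in range(n_conditions):
        name = f"cond{c}"
        rng = np.random.default_rng(subseed(spec.seed, "targets", c))
        ds = TargetDataset(name=name, direction_filtered=True)
        origin: dict[str, str] = {}
        misses = 0
        while len(ds) < spec.n_targets:
            if misses > 1000 * spec.n_targets:
                raise ValidationError(
                    "target draw pool exhausted (enriched membership smaller "
                    "than the requested list under p_in)"
                )
            if rng.random() < spec.p_in:
                acc = enriched_members[int(rng.integers(len(enriched_members)))]
                src = member_of[acc]
            else:
                acc = universe[int(rng.integers(len(universe)))]
                src = "background"
            if acc in ds:
                misses += 1
                continue
            lo, hi = spec.n_sites_range
            n_sites = int(rng.integers(lo, hi + 1))
            sites = frozenset(int(s) for s in rng.integers(1, 1200, size=n_sites))
            ds.add(
                PhosphoTarget(
                    protein=Protein(acc), sites=sites, direction="up",
                )
            )
            origin[acc] = src
        truth.target_origin[name] = origin
        datasets.append(ds)
    return datasets


def gen_rewired_pair(
    net: SignalingNetwork, spec: SyntheticSpec
) -> tuple[SignalingNetwork, SignalingNetwork, GroundTruth]:
    """A condition pair with planted rewiring around chosen nodes.

    The second network is a copy of the first in which, for each planted
    node, a fraction ``rewire_fraction`` of its incident edges is deleted
    and replaced by edges to uniformly chosen new endpoints (no
    self-loops, no duplicates). Nodes whose degree is too small for at
    least one rewired edge are skipped with a warning.
    """
    spec.validate()
    rng = np.random.default_rng(subseed(spec.seed, "rewire"))
    if spec.n_rewired_nodes > net.n_nodes:
        raise ValidationError("more planted nodes requested than nodes available")
    g_b = net.graph.copy()
    nodes = sorted(g_b.nodes)
    degrees = dict(g_b.degree())  # in+out
    candidates = [n for n in nodes if degrees[n] >= 2]
    planted = [
        str(x)
        for x in rng.choice(candidates, size=spec.n_rewired_nodes, replace=False)
    ]
    rewired: set[str] = set()
    for node in planted:
        incident = sorted(g_b.in_edges(node)) + sorted(g_b.out_edges(node))
        n_rewire = int(round(spec.rewire_fraction * len(incident)))
        if n_rewire < 1:
            logger.warning("planted node %s degree too small to rewire; skipped", node)
            continue
        chosen = [
            incident[i]
            for i in rng.choice(len(incident), size=n_rewire, replace=False)
        ]
        for u, v in chosen:
            g_b.remove_edge(u, v)
            for _ in range(100):
                new_end = nodes[int(rng.integers(len(nodes)))]
                if u == node:  # outgoing edge: replace the head
                    cand = (node, new_end)
                else:  # incoming edge: replace the tail
                    cand = (new_end, node)
                if cand[0] != cand[1] and not g_b.has_edge(*cand):
                    g_b.add_edge(*cand, sign=SIGNS[rng.choice(3, p=spec.sign_ratios)])
                    break
        rewired.add(node)
    net_a = net
    net_b = SignalingNetwork(
        graph=g_b, name=f"{net.name}-rewired",
        metadata={**net.metadata, "rewired_nodes": sorted(rewired)},
    )
    return net_a, net_b, GroundTruth(rewired=rewired)
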