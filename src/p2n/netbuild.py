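"""Prior-knowledge network construction from selected pathways.

The per-condition network is the union of the selected pathways' members,
wired with every database interaction whose endpoints both fall in that
node set (cross-pathway edges included). Cleanup removes self-loops,
merges duplicate directed edges (provenance unioned, conflicting signs
demoted to unknown) and drops isolated nodes. A size-matched random
baseline runs the identical enrichment -> selection -> build pipeline on
uniformly sampled pseudo-targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .core import SIGN_UNKNOWN, PathwayDB, TargetDataset
from .enrichment import fisher_enrichment, select_pathways
from .errors import P2NError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class SignalingNetwork:
    """A directed protein signaling graph with node/edge annotations.

    Node attributes: ``targets`` (dataset label -> sorted site list),
    ``is_modifier``, ``is_focal``, ``symbol``. Edge attributes: ``sign``,
    ``provenance`` (pathway ids), ``dbs`` (source database labels).
    """

    graph: nx.DiGraph
    name: str = "network"
    metadata: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def copy(self) -> "SignalingNetwork":
        return SignalingNetwork(self.graph.copy(), self.name, dict(self.metadata))

    def assert_clean(self) -> None:
        if any(u == v for u, v in self.graph.edges):
            raise ValidationError(f"{self.name}: self-loop survived cleanup")
        if any(d == 0 for _, d in self.graph.degree()):
            raise ValidationError(f"{self.name}: isolated node survived cleanup")


def build_network(
    selected: set[str],
    db: PathwayDB,
    datasets: list[TargetDataset] | None = None,
    focal: str | None = None,
    modifiers: dict[str, bool] | None = None,
    name: str = "network",
) -> SignalingNetwork:
    """Embed the selected pathways into one cleaned signaling network."""
    unknown = selected - set(db.pathways)
    if unknown:
        raise P2NError(f"selected pathways not in database: {sorted(unknown)[:5]}")
    nodes: set[str] = set()
    for pw_id in selected:
        nodes |= db.pathways[pw_id].members

    g = nx.DiGraph()
    n_self_loops = 0
    for ia in db.interactions:
        if ia.source not in nodes or ia.target not in nodes:
            continue
        if ia.source == ia.target:
            n_self_loops += 1
            continue
        prov = frozenset(ia.provenance & selected)
        if g.has_edge(ia.source, ia.target):
            data = g[ia.source][ia.target]
            if data["sign"] != ia.sign:
                logger.info(
                    "sign conflict on %s->%s (%s vs %s): set to unknown",
                    ia.source, ia.target, data["sign"], ia.sign,
                )
                data["sign"] = SIGN_UNKNOWN
            data["provenance"] = data["provenance"] | prov
            data["dbs"] = data["dbs"] | ia.dbs
        else:
            g.add_edge(ia.source, ia.target, sign=ia.sign, provenance=prov, dbs=ia.dbs)

    isolated = nodes - set(g.nodes)
    logger.info(
        "%s: %d pathway members, %d isolated dropped, %d self-loops removed",
        name, len(nodes), len(isolated), n_self_loops,
    )

    datasets = datasets or []
    for node in g.nodes:
        targets = {}
        symbol = ""
        for ds in datasets:
            t = ds.targets.get(node)
            if t is not None:
                targets[ds.name] = sorted(t.sites)
                symbol = symbol or (t.protein.symbol or "")
        g.nodes[node]["targets"] = targets
        g.nodes[node]["symbol"] = symbol
        g.nodes[node]["is_modifier"] = bool(modifiers.get(node)) if modifiers else False
        g.nodes[node]["is_focal"] = node == focal

    net = SignalingNetwork(
        graph=g,
        name=name,
        metadata={"selected_pathways": sorted(selected), "random": False},
    )
    net.assert_clean()
    if focal is not None and focal not in g:
        raise P2NError(
            f"focal protein {focal} absent from the built network; "
            "propagation from it is impossible"
        )
    return net


def build_random_network(
    db: PathwayDB,
    size: int,
    seed: int,
    alpha: float = 0.05,
    name: str = "random",
) -> SignalingNetwork:
    """Random-protein baseline through the identical pipeline.

    Samples ``size`` accessions uniformly without replacement from the
    database universe, treats them as pseudo-targets and runs enrichment,
    selection and network construction on them. An empty selection (the
    random proteins hit no pathway) yields an empty network with a
    warning, not an error.
    """
    universe = sorted(db.universe)
    if size > len(universe):
        raise ValidationError(f"requested {size} random proteins from {len(universe)}")
    rng = np.random.default_rng(seed)
    sample = rng.choice(universe, size=size, replace=False) if size else []
    from .core import PhosphoTarget, Protein

    ds = TargetDataset(name=f"{name}-targets", direction_filtered=True)
    for acc in sample:
        ds.add(PhosphoTarget(protein=Protein(str(acc)), direction="up"))
    results = fisher_enrichment(ds, db, alpha=alpha)
    selection = select_pathways(results, ds, db, alpha=alpha)
    if not selection.selected:
        logger.warning("%s: random proteins hit no pathway; empty network", name)
        return SignalingNetwork(
            graph=nx.DiGraph(), name=name, metadata={"random": True, "seed": seed}
        )
    net = build_network(selection.selected, db, datasets=[ds], name=name)
    net.metadata.update({"random": True, "seed": seed, "sample_size": size})
    return net
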