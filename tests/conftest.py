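import networkx as nx
import pytest

from p2n.core import (
    Interaction,
    Pathway,
    PathwayDB,
    PhosphoTarget,
    Protein,
    TargetDataset,
)
from p2n.netbuild import SignalingNetwork


def make_dataset(name, accessions, direction="up", filtered=True):
    ds = TargetDataset(name=name, direction_filtered=filtered)
    for acc in accessions:
        ds.add(PhosphoTarget(protein=Protein(acc), direction=direction))
    return ds


def make_db(pathways, edges=(), source="kegg"):
    """pathways: {id: members}; edges: [(src, tgt)] or [(src, tgt, sign)]."""
    pw = {}
    for pid, members in pathways.items():
        full_id = pid if ":" in pid else f"{source}:{pid}"
        pw[full_id] = Pathway(
            id=full_id, name=pid, source=source, members=frozenset(members)
        )
    interactions = []
    for e in edges:
        src, tgt = e[0], e[1]
        sign = e[2] if len(e) > 2 else "unknown"
        prov = frozenset(
            p.id for p in pw.values() if src in p.members and tgt in p.members
        )
        interactions.append(
            Interaction(src, tgt, sign=sign, provenance=prov,
                        dbs=frozenset({source}))
        )
    return PathwayDB(pathways=pw, interactions=interactions)


def make_net(edges, name="net", nodes=()):
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return SignalingNetwork(graph=g, name=name)


@pytest.fixture
def bidirectional_star():
    """Center C connected both ways to four leaves."""
    edges = []
    for leaf in "ABDE":
        edges += [("C", leaf), (leaf, "C")]
    return make_net(edges, name="star")
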