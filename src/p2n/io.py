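"""Readers and writers for the plain-text formats the pipeline consumes.

Targets arrive as TSV, pathway membership as GMT, interactions as SIF,
GO annotations as GAF 2.x, and annotated networks leave as GraphML or SIF.
All readers key proteins by accession and strip isoform suffixes by
default.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from .core import (
    DEFAULT_SIGN_MAP,
    EVIDENCE_PHOSPHOSITE,
    EVIDENCE_PRESENCE,
    SIGN_UNKNOWN,
    GoAnnotation,
    Interaction,
    Pathway,
    PathwayDB,
    PhosphoTarget,
    Protein,
    TargetDataset,
    strip_isoform,
)
from .errors import FormatError

logger = logging.getLogger(__name__)

_TARGET_COLUMNS = ["accession", "symbol", "sites", "evidence", "direction"]


def _parse_sites(token: str, row_label: str) -> tuple[frozenset[int], frozenset[int]]:
    """Parse ``"551;759*"`` into (sites, direct sites). ``*`` marks a residue
    the focal kinase can phosphorylate directly."""
    sites: set[int] = set()
    direct: set[int] = set()
    if not token or not str(token).strip():
        return frozenset(), frozenset()
    for raw in str(token).split(";"):
        part = raw.strip()
        if not part:
            continue
        is_direct = part.endswith("*")
        if is_direct:
            part = part[:-1].strip()
        try:
            pos = int(part)
        except ValueError as exc:
            raise FormatError(
                f"{row_label}: non-integer phosphosite token {raw!r}"
            ) from exc
        sites.add(pos)
        if is_direct:
            direct.add(pos)
    return frozenset(sites), frozenset(direct)


def read_target_table(
    path: str | Path, name: str, strip_isoforms: bool = True
) -> TargetDataset:
    """Read one condition's target list from a TSV file.

    Expected header: ``accession  symbol  sites  evidence  direction`` where
    ``sites`` is semicolon-separated residue positions (``*`` suffix =
    direct phosphorylation by the focal kinase) and ``direction`` is
    ``up``/``down``. Duplicate accessions are merged by site-set union.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("accession",) if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    ds = TargetDataset(name=name)
    for i, row in df.iterrows():
        acc = str(row["accession"]).strip()
        if not acc:
            raise FormatError(f"{path} row {i + 2}: empty accession")
        if strip_isoforms:
            stripped = strip_isoform(acc)
            if stripped != acc:
                logger.info("%s: isoform suffix stripped %s -> %s", path, acc, stripped)
            acc = stripped
        sites, direct = _parse_sites(row.get("sites", ""), f"{path} row {i + 2}")
        evidence = str(row.get("evidence", "")).strip() or (
            EVIDENCE_PHOSPHOSITE if sites else EVIDENCE_PRESENCE
        )
        direction = str(row.get("direction", "")).strip() or None
        symbol = str(row.get("symbol", "")).strip() or None
        ds.add(
            PhosphoTarget(
                protein=Protein(acc, symbol),
                sites=sites,
                evidence=evidence,
                direction=direction,
                direct_sites=direct,
            )
        )
    logger.info("read %d targets for %s from %s", len(ds), name, path)
    return ds


def write_target_table(ds: TargetDataset, path: str | Path) -> None:
    rows = []
    for acc in sorted(ds.targets):
        t = ds.targets[acc]
        rows.append(
            {
                "accession": acc,
                "symbol": t.protein.symbol or "",
                "sites": ";".join(
                    f"{s}*" if s in t.direct_sites else str(s)
                    for s in sorted(t.sites)
                ),
                "evidence": t.evidence,
                "direction": t.direction or "",
            }
        )
    pd.DataFrame(rows, columns=_TARGET_COLUMNS).to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path, source: str) -> dict[str, Pathway]:
    """Read pathway membership (``id <TAB> name <TAB> members...``).

    Pathway ids are prefixed with the source label (``kegg:...``) so that
    ids from different databases can never collide.
    """
    pathways: dict[str, Pathway] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path} line {lineno}: GMT needs >=3 tab-separated fields"
                )
            raw_id, name, *members = fields
            pw_id = raw_id if raw_id.startswith(f"{source}:") else f"{source}:{raw_id}"
            members = [m.strip() for m in members if m.strip()]
            pathways[pw_id] = Pathway(
                id=pw_id, name=name, source=source, members=frozenset(members)
            )
    return pathways


def read_sif(
    path: str | Path,
    source: str,
    sign_map: dict[str, str] | None = None,
) -> list[tuple[str, str, str]]:
    """Read directed interactions (``source <TAB> relation <TAB> target``).

    Relation tokens are mapped to signs through ``sign_map``; unknown tokens
    map to ``unknown`` with a warning.
    """
    sign_map = DEFAULT_SIGN_MAP if sign_map is None else sign_map
    edges: list[tuple[str, str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(
                    f"{path} line {lineno}: SIF needs 3 tab-separated fields"
                )
            src, relation, tgt = (f.strip() for f in fields)
            sign = sign_map.get(relation)
            if sign is None:
                logger.warning(
                    "%s line %d: unknown relation %r mapped to sign=unknown",
                    path,
                    lineno,
                    relation,
                )
                sign = SIGN_UNKNOWN
            edges.append((src, tgt, sign))
    return edges


def read_pathway_db(
    gmt: str | Path,
    sif: str | Path,
    source: str,
    sign_map: dict[str, str] | None = None,
) -> PathwayDB:
    """Assemble a PathwayDB from one source database's GMT + SIF exports.

    Each interaction's provenance is the set of pathways whose member set
    contains both endpoints (possibly empty for cross-pathway edges).
    """
    pathways = read_gmt(gmt, source)
    interactions = []
    for src, tgt, sign in read_sif(sif, source, sign_map):
        prov = frozenset(
            pw.id
            for pw in pathways.values()
            if src in pw.members and tgt in pw.members
        )
        interactions.append(
            Interaction(src, tgt, sign=sign, provenance=prov, dbs=frozenset({source}))
        )
    db = PathwayDB(pathways=pathways, interactions=interactions)
    db.validate()
    return db


def write_pathway_db(db: PathwayDB, gmt: str | Path, sif: str | Path) -> None:
    """Write a PathwayDB back to GMT + SIF (sign used as relation token)."""
    with open(gmt, "w") as fh:
        for pw_id in sorted(db.pathways):
            pw = db.pathways[pw_id]
            fh.write("\t".join([pw.id, pw.name, *sorted(pw.members)]) + "\n")
    relation = {"activate": "activates", "inhibit": "inhibits", "unknown": "interacts"}
    with open(sif, "w") as fh:
        for ia in sorted(db.interactions, key=lambda i: (i.source, i.target, i.sign)):
            fh.write(f"{ia.source}\t{relation[ia.sign]}\t{ia.target}\n")


def read_gaf(path: str | Path, strip_isoforms: bool = True) -> GoAnnotation:
    """Read GO annotations from a GAF 2.x file (comment lines start with ``!``).

    Only the object id (column 2), qualifier (column 4) and GO id (column 5)
    are used; NOT-qualified annotations are skipped.
    """
    term_to_acc: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("!"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise FormatError(f"{path} line {lineno}: GAF needs >=5 columns")
            acc, qualifier, go_id = fields[1], fields[3], fields[4]
            if "NOT" in qualifier.split("|"):
                continue
            if strip_isoforms:
                acc = strip_isoform(acc)
            term_to_acc.setdefault(go_id, set()).add(acc)
    return GoAnnotation(term_to_accessions=term_to_acc)


# ---------------------------------------------------------------------------
# GraphML round-trip for annotated networks
# ---------------------------------------------------------------------------

_JSON_PREFIX = "json:"


def _encode_attrs(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, (str, int, float, bool)):
            out[k] = v
        elif isinstance(v, (set, frozenset)):
            out[k] = _JSON_PREFIX + json.dumps(sorted(v))
        else:
            out[k] = _JSON_PREFIX + json.dumps(v, sort_keys=True, default=sorted)
    return out


def _decode_attrs(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, str) and v.startswith(_JSON_PREFIX):
            out[k] = json.loads(v[len(_JSON_PREFIX):])
        else:
            out[k] = v
    return out


def write_graphml(net, path: str | Path) -> None:
    """Write a SignalingNetwork with set/dict annotations JSON-encoded."""
    g = nx.DiGraph(**_encode_attrs({"name": net.name, **net.metadata}))
    for n, data in net.graph.nodes(data=True):
        g.add_node(n, **_encode_attrs(data))
    for u, v, data in net.graph.edges(data=True):
        g.add_edge(u, v, **_encode_attrs(data))
    nx.write_graphml(g, path)


def read_graphml(path: str | Path):
    from .netbuild import SignalingNetwork

    g = nx.read_graphml(path)
    meta = _decode_attrs(dict(g.graph))
    name = meta.pop("name", "network")
    out = nx.DiGraph()
    for n, data in g.nodes(data=True):
        out.add_node(n, **_decode_attrs(data))
    for u, v, data in g.edges(data=True):
        out.add_edge(u, v, **_decode_attrs(data))
    return SignalingNetwork(graph=out, name=name, metadata=meta)


def write_network_sif(net, path: str | Path) -> None:
    """Topology-only SIF export of a network (sign as relation token)."""
    relation = {"activate": "activates", "inhibit": "inhibits", "unknown": "interacts"}
    with open(path, "w") as fh:
        for u, v, data in sorted(net.graph.edges(data=True)):
            fh.write(f"{u}\t{relation.get(data.get('sign', 'unknown'))}\t{v}\n")
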