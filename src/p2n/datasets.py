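"""Packaged worked-example fixtures.

Small published per-pathway target summaries for the focal spleen
tyrosine kinase (SYK, P43405) in three cell lines — MCF7 and MDA-MB-231
breast carcinoma (SYK tumor-suppressive) and DG75 Burkitt lymphoma (SYK
pro-oncogenic) — re-encoded as TSV: the B-cell receptor signaling and
regulation-of-actin-cytoskeleton pathway target tables, plus the list of
most-rewired targets between the breast cancer and lymphoma networks.
These are excerpts, not the complete per-condition target lists.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .core import (
    EVIDENCE_PHOSPHOSITE,
    EVIDENCE_PRESENCE,
    Pathway,
    PathwayDB,
    PhosphoTarget,
    Protein,
    TargetDataset,
)

SYK = "P43405"
CONDITIONS = ("MCF7", "MDA231", "DG75")

BCR_PATHWAY = "kegg:hsa04662"  # B-cell receptor signaling
ACTIN_PATHWAY = "kegg:hsa04810"  # regulation of actin cytoskeleton


def _read(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(f"data/{name}").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)


def load_pathway_tables() -> dict[str, pd.DataFrame]:
    """The published per-pathway target tables, as raw frames."""
    return {
        BCR_PATHWAY: _read("bcr_pathway_targets.tsv"),
        ACTIN_PATHWAY: _read("actin_pathway_targets.tsv"),
    }


def load_rewired_table() -> pd.DataFrame:
    """The published most-rewired target list (raw frame)."""
    return _read("rewired_targets.tsv")


def _cell_to_target(acc: str, symbol: str, cell: str) -> PhosphoTarget | None:
    cell = cell.strip()
    if not cell:
        return None
    protein = Protein(acc, symbol)
    if cell == "X":
        return PhosphoTarget(protein, evidence=EVIDENCE_PRESENCE, direction="up")
    sites: set[int] = set()
    direct: set[int] = set()
    for token in cell.split(";"):
        token = token.strip()
        is_direct = token.endswith("*")
        pos = int(token.rstrip("* ").strip())
        sites.add(pos)
        if is_direct:
            direct.add(pos)
    return PhosphoTarget(
        protein, sites=frozenset(sites), evidence=EVIDENCE_PHOSPHOSITE,
        direction="up", direct_sites=frozenset(direct),
    )


def load_example_targets() -> dict[str, TargetDataset]:
    """Per-condition target datasets from the union of all fixture tables.

    Note these cover only the targets the published excerpts print, not
    the complete experimental lists.
    """
    datasets = {
        c: TargetDataset(name=c, direction_filtered=True) for c in CONDITIONS
    }
    frames = list(load_pathway_tables().values()) + [load_rewired_table()]
    for df in frames:
        for _, row in df.iterrows():
            for cond in CONDITIONS:
                t = _cell_to_target(row["accession"], row["symbol"], row.get(cond, ""))
                if t is not None:
                    datasets[cond].add(t)
    return datasets


def load_example_db() -> PathwayDB:
    """A two-pathway database whose members are the fixture-table rows."""
    tables = load_pathway_tables()
    pathways = {}
    names = {
        BCR_PATHWAY: "B cell receptor signaling pathway",
        ACTIN_PATHWAY: "Regulation of actin cytoskeleton",
    }
    for pw_id, df in tables.items():
        pathways[pw_id] = Pathway(
            id=pw_id, name=names[pw_id], source="kegg",
            members=frozenset(df["accession"]),
        )
    return PathwayDB(pathways=pathways, interactions=[])
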