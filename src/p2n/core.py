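"""Domain types and target-list operations.

The whole pipeline identifies proteins by their UniProt-style accession;
gene symbols are carried for display only and are never used for joins.
A *target* is a protein whose (tyrosine) phosphorylation responded to
perturbation of the focal kinase, optionally with the responding residue
positions; proteins pulled down through interaction with phosphorylated
partners (no site resolved) carry the ``presence`` evidence class and are
treated identically to site-resolved targets downstream.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

from .errors import ValidationError

logger = logging.getLogger(__name__)

EVIDENCE_PHOSPHOSITE = "phosphosite"
EVIDENCE_PRESENCE = "presence"

SIGN_ACTIVATE = "activate"
SIGN_INHIBIT = "inhibit"
SIGN_UNKNOWN = "unknown"
SIGNS = (SIGN_ACTIVATE, SIGN_INHIBIT, SIGN_UNKNOWN)

#: Default mapping of SIF relation tokens to interaction signs. Tokens not
#: listed here map to ``unknown`` (with a warning at read time).
DEFAULT_SIGN_MAP = {
    "activates": SIGN_ACTIVATE,
    "activate": SIGN_ACTIVATE,
    "phosphorylates": SIGN_ACTIVATE,
    "stimulates": SIGN_ACTIVATE,
    "inhibits": SIGN_INHIBIT,
    "inhibit": SIGN_INHIBIT,
    "dephosphorylates": SIGN_INHIBIT,
}

_ISOFORM_RE = re.compile(r"-\d+$")
_GO_TERM_RE = re.compile(r"^GO:\d{7}$")


def strip_isoform(accession: str) -> str:
    """Drop a ``-N`` isoform suffix from a UniProt-style accession."""
    return _ISOFORM_RE.sub("", accession)


@dataclass(frozen=True)
class Protein:
    """A protein keyed by accession; the symbol is display-only."""

    accession: str
    symbol: str | None = None

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValidationError("protein accession must be non-empty")


@dataclass(frozen=True)
class PhosphoTarget:
    """One target protein with its responding phosphosites.

    ``sites`` are 1-based residue positions and may be empty for the
    ``presence`` evidence class. ``direct_sites`` is the subset of sites
    that the focal kinase can phosphorylate directly.
    """

    protein: Protein
    sites: frozenset[int] = frozenset()
    evidence: str = EVIDENCE_PHOSPHOSITE
    direction: str | None = None
    direct_sites: frozenset[int] = frozenset()
    manual: bool = False

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sites):
            raise ValidationError(
                f"{self.protein.accession}: phosphosite positions must be positive"
            )
        if not self.direct_sites <= self.sites:
            raise ValidationError(
                f"{self.protein.accession}: direct sites must be a subset of sites"
            )

    @property
    def accession(self) -> str:
        return self.protein.accession

    def merged_with(self, other: "PhosphoTarget") -> "PhosphoTarget":
        """Union two records for the same accession (site sets merged)."""
        if other.accession != self.accession:
            raise ValidationError("cannot merge targets with different accessions")
        return replace(
            self,
            sites=self.sites | other.sites,
            direct_sites=self.direct_sites | other.direct_sites,
            manual=self.manual or other.manual,
            evidence=(
                EVIDENCE_PHOSPHOSITE
                if EVIDENCE_PHOSPHOSITE in (self.evidence, other.evidence)
                else self.evidence
            ),
        )


@dataclass
class TargetDataset:
    """One condition's (cell line's) target list, keyed by accession."""

    name: str
    targets: dict[str, PhosphoTarget] = field(default_factory=dict)
    direction_filtered: bool = False

    @property
    def accessions(self) -> set[str]:
        return set(self.targets)

    def __len__(self) -> int:
        return len(self.targets)

    def __contains__(self, accession: str) -> bool:
        return accession in self.targets

    def add(self, target: PhosphoTarget) -> None:
        existing = self.targets.get(target.accession)
        self.targets[target.accession] = (
            existing.merged_with(target) if existing is not None else target
        )


@dataclass(frozen=True)
class Pathway:
    """A named set of member proteins from one source database."""

    id: str
    name: str
    source: str
    members: frozenset[str]


@dataclass(frozen=True)
class Interaction:
    """A directed signed interaction with pathway provenance."""

    source: str
    target: str
    sign: str = SIGN_UNKNOWN
    provenance: frozenset[str] = frozenset()
    dbs: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.sign not in SIGNS:
            raise ValidationError(f"unknown interaction sign: {self.sign!r}")


@dataclass
class PathwayDB:
    """Pathway membership plus directed interactions over a protein universe."""

    pathways: dict[str, Pathway] = field(default_factory=dict)
    interactions: list[Interaction] = field(default_factory=list)

    @property
    def universe(self) -> set[str]:
        acc: set[str] = set()
        for pw in self.pathways.values():
            acc |= pw.members
        for ia in self.interactions:
            acc.add(ia.source)
            acc.add(ia.target)
        return acc

    @property
    def sources(self) -> set[str]:
        return {pw.source for pw in self.pathways.values()}

    def source_universe(self, source: str) -> set[str]:
        """Universe restricted to one source database's pathways/interactions."""
        acc: set[str] = set()
        for pw in self.pathways.values():
            if pw.source == source:
                acc |= pw.members
        for ia in self.interactions:
            if source in ia.dbs:
                acc.add(ia.source)
                acc.add(ia.target)
        return acc

    def validate(self) -> None:
        uni = self.universe
        for pw in self.pathways.values():
            if not pw.members <= uni:
                raise ValidationError(f"pathway {pw.id} has members outside universe")
        for ia in self.interactions:
            if ia.source not in uni or ia.target not in uni:
                raise ValidationError(
                    f"interaction {ia.source}->{ia.target} endpoint outside universe"
                )

    def combined_with(self, other: "PathwayDB") -> "PathwayDB":
        """Union of two databases; pathway ids must not collide."""
        overlap = set(self.pathways) & set(other.pathways)
        if overlap:
            raise ValidationError(f"pathway id collision: {sorted(overlap)[:5]}")
        return PathwayDB(
            pathways={**self.pathways, **other.pathways},
            interactions=list(self.interactions) + list(other.interactions),
        )


@dataclass
class GoAnnotation:
    """GO term -> annotated accessions, plus named groups of terms.

    Groups bundle the process/function terms used to slice target lists,
    e.g. a cell-adhesion-and-motility group holding GO:0048870, GO:0007155...
    """

    term_to_accessions: dict[str, set[str]] = field(default_factory=dict)
    groups: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [t for t in self.term_to_accessions if not _GO_TERM_RE.match(t)]
        bad += [t for ts in self.groups.values() for t in ts if not _GO_TERM_RE.match(t)]
        if bad:
            raise ValidationError(f"malformed GO term ids: {sorted(set(bad))[:5]}")

    def accessions_for_terms(self, terms: set[str]) -> set[str]:
        acc: set[str] = set()
        for t in terms:
            acc |= self.term_to_accessions.get(t, set())
        return acc


# ---------------------------------------------------------------------------
# target-list operations
# ---------------------------------------------------------------------------

def normalize_targets(ds: TargetDataset) -> TargetDataset:
    """Keep only targets whose phosphorylation increased with active kinase.

    Returns a new dataset containing the ``direction == "up"`` targets
    (manually added entries are kept regardless). Idempotent: a dataset
    already filtered is returned unchanged, with a warning.
    """
    if ds.direction_filtered:
        logger.warning("dataset %s already direction-filtered; no-op", ds.name)
        return TargetDataset(ds.name, dict(ds.targets), direction_filtered=True)
    kept = {
        acc: t for acc, t in ds.targets.items() if t.direction == "up" or t.manual
    }
    dropped = len(ds.targets) - len(kept)
    logger.info("normalize %s: retained %d, dropped %d", ds.name, len(kept), dropped)
    if not kept:
        logger.warning("dataset %s empty after direction filtering", ds.name)
    return TargetDataset(ds.name, kept, direction_filtered=True)


def add_manual_targets(
    ds: TargetDataset, additions: list[PhosphoTarget]
) -> TargetDataset:
    """Add curated a-posteriori targets (flagged ``manual``), merging by accession."""
    out = TargetDataset(ds.name, dict(ds.targets), ds.direction_filtered)
    for t in additions:
        out.add(replace(t, manual=True))
    return out


def annotate_modifiers(
    db: PathwayDB,
    go: GoAnnotation,
    extension: list[str] | set[str] = (),
    kinase_term: str = "GO:0004713",
    phosphatase_term: str = "GO:0004725",
) -> dict[str, bool]:
    """Flag phospho-tyrosine modifiers in the database universe.

    A protein is a modifier iff it carries the protein-tyrosine-kinase or
    protein-tyrosine-phosphatase GO term, or appears in the curated
    ``extension`` list (supplied as configuration, not recomputed).
    """
    annotated = go.accessions_for_terms({kinase_term, phosphatase_term})
    ext = set(extension)
    return {acc: (acc in annotated or acc in ext) for acc in sorted(db.universe)}


def dataset_intersection(a: TargetDataset, b: TargetDataset) -> set[str]:
    """Accessions shared by two condition target lists."""
    return a.accessions & b.accessions
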