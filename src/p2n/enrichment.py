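"""Pathway over-representation scoring and selection.

For each pathway the over-representation of a condition's targets among
the pathway members is scored with the one-sided Fisher exact test, i.e.
the hypergeometric upper tail

    p = P(X >= k),  X ~ Hypergeom(N, K, n)

with N the source database's universe size, K the number of targets found
in that universe, n the pathway size and k the overlap. The enrichment
score is ES = -log10(p). Pathway selection keeps every significant pathway
and then adds, greedily by ascending p, pathways needed to cover targets
that no significant pathway contains.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import false_discovery_control, hypergeom

from .core import EVIDENCE_PRESENCE, PathwayDB, TargetDataset
from .errors import P2NError, ValidationError

logger = logging.getLogger(__name__)

_TINY_P = 5e-324  # smallest positive float; guards -log10 against underflow


@dataclass
class EnrichmentResult:
    pathway_id: str
    source: str
    N: int
    K: int
    n: int
    k: int
    p: float
    score: float
    significant: bool
    selected_reason: str = "none"  # significant | coverage | none


@dataclass
class SelectionResult:
    selected: set[str]
    reasons: dict[str, str]
    uncovered: set[str]


@dataclass
class DifferentialEnrichment:
    pathway_id: str
    scores: dict[str, float]
    mean: float
    deviations: dict[str, float]


@dataclass
class ClusterResult:
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: list
    col_order: list


def fisher_enrichment(
    ds: TargetDataset,
    db: PathwayDB,
    alpha: float = 0.05,
    log_base: float = 10.0,
    two_sided: bool = False,
    bh_correction: bool = False,
) -> list[EnrichmentResult]:
    """Score every pathway's target over-representation.

    The universe is per source database; targets outside a source's
    universe are dropped (and counted) for that source. Results are sorted
    by ascending p, ties broken by descending overlap then pathway id.
    With ``bh_correction`` the significance flag uses Benjamini-Hochberg
    adjusted p-values (raw p is still reported).
    """
    results: list[EnrichmentResult] = []
    if not ds.targets:
        logger.warning("empty target set for %s: all p=1", ds.name)
    for source in sorted(db.sources):
        universe = db.source_universe(source)
        N = len(universe)
        targets_in = ds.accessions & universe
        dropped = len(ds.accessions) - len(targets_in)
        if dropped:
            logger.info(
                "%s/%s: %d targets outside universe dropped", ds.name, source, dropped
            )
        K = len(targets_in)
        for pw_id in sorted(db.pathways):
            pw = db.pathways[pw_id]
            if pw.source != source:
                continue
            n = len(pw.members)
            if n > N:
                raise ValidationError(f"pathway {pw_id} larger than universe")
            k = len(pw.members & targets_in)
            if k == 0:
                p = 1.0
            elif two_sided:
                # sum of all tables at most as probable as the observed one
                probs = hypergeom.pmf(np.arange(0, min(K, n) + 1), N, K, n)
                p = float(min(1.0, probs[probs <= probs[k] * (1 + 1e-9)].sum()))
            else:
                p = float(hypergeom.sf(k - 1, N, K, n))
            p = min(max(p, _TINY_P), 1.0)
            score = -math.log(p, log_base) if p < 1.0 else 0.0
            results.append(
                EnrichmentResult(
                    pathway_id=pw_id,
                    source=source,
                    N=N,
                    K=K,
                    n=n,
                    k=k,
                    p=p,
                    score=max(score, 0.0),
                    significant=p < alpha,
                )
            )
    if bh_correction and results:
        adjusted = false_discovery_control([r.p for r in results], method="bh")
        for r, q in zip(results, adjusted):
            r.significant = q < alpha
    results.sort(key=lambda r: (r.p, -r.k, r.pathway_id))
    return results


def select_pathways(
    results: list[EnrichmentResult],
    ds: TargetDataset,
    db: PathwayDB,
    alpha: float = 0.05,
) -> SelectionResult:
    """Significance-plus-coverage pathway selection.

    Within each source database: step 1 keeps pathways with p < alpha;
    step 2 walks the remaining pathways by ascending p (ties: larger
    overlap, then id) and adds any pathway containing a target not yet
    covered, until no further target can be covered. Selections from the
    source databases are unioned.
    """
    selected: set[str] = set()
    reasons: dict[str, str] = {}
    covered_any: set[str] = set()
    for source in sorted(db.sources):
        src_results = [r for r in results if r.source == source]
        targets = ds.accessions & db.source_universe(source)
        in_any = set()
        for r in src_results:
            in_any |= db.pathways[r.pathway_id].members & targets
        covered = set()
        for r in (r for r in src_results if r.significant):
            selected.add(r.pathway_id)
            reasons[r.pathway_id] = "significant"
            r.selected_reason = "significant"
            covered |= db.pathways[r.pathway_id].members & targets
        uncovered = in_any - covered
        for r in sorted(src_results, key=lambda r: (r.p, -r.k, r.pathway_id)):
            if not uncovered:
                break
            if r.pathway_id in selected:
                continue
            gain = db.pathways[r.pathway_id].members & uncovered
            if gain:
                selected.add(r.pathway_id)
                reasons[r.pathway_id] = "coverage"
                r.selected_reason = "coverage"
                covered |= gain
                uncovered -= gain
        covered_any |= covered
    never_covered = ds.accessions - covered_any
    if never_covered:
        logger.info(
            "%d targets coverable by no pathway: %s...",
            len(never_covered),
            sorted(never_covered)[:5],
        )
    return SelectionResult(selected=selected, reasons=reasons, uncovered=never_covered)


def differential_enrichment(
    per_condition: dict[str, list[EnrichmentResult]],
) -> list[DifferentialEnrichment]:
    """Mean enrichment score per pathway across conditions, with deviations.

    Pathways missing from a condition score ES=0 there. Output is sorted
    by descending mean ES (ties by pathway id); per-condition deviations
    (ES - mean) sum to zero for every pathway.
    """
    if len(per_condition) < 2:
        raise P2NError("differential enrichment needs at least 2 conditions")
    score_maps = {
        cond: {r.pathway_id: r.score for r in results}
        for cond, results in per_condition.items()
    }
    all_pathways = sorted(set().union(*(m.keys() for m in score_maps.values())))
    out = []
    for pw_id in all_pathways:
        scores = {cond: score_maps[cond].get(pw_id, 0.0) for cond in score_maps}
        mean = sum(scores.values()) / len(scores)
        out.append(
            DifferentialEnrichment(
                pathway_id=pw_id,
                scores=scores,
                mean=mean,
                deviations={c: s - mean for c, s in scores.items()},
            )
        )
    out.sort(key=lambda d: (-d.mean, d.pathway_id))
    return out


def enrichment_matrix(
    per_condition: dict[str, list[EnrichmentResult]],
) -> pd.DataFrame:
    """Dense pathways x conditions ES matrix (fill-zero)."""
    diffs = differential_enrichment(per_condition)
    conditions = sorted(per_condition)
    return pd.DataFrame(
        [[d.scores[c] for c in conditions] for d in diffs],
        index=[d.pathway_id for d in diffs],
        columns=conditions,
    )


def cluster_enrichment(
    matrix: pd.DataFrame,
    metric: str = "euclidean",
    method: str = "complete",
) -> ClusterResult:
    """Bidirectional (rows and columns) agglomerative clustering of the
    ES matrix. Ties in merge distance are resolved by scipy's
    deterministic observation-order rule, so results are reproducible.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValidationError("clustering needs at least a 2x2 matrix")
    row_link = linkage(matrix.values, method=method, metric=metric)
    col_link = linkage(matrix.values.T, method=method, metric=metric)
    return ClusterResult(
        row_linkage=row_link,
        col_linkage=col_link,
        row_order=[matrix.index[i] for i in leaves_list(row_link)],
        col_order=[matrix.columns[i] for i in leaves_list(col_link)],
    )


def render_sites(target, dataset_uses_presence: bool = False) -> str:
    """Render a target's sites for a per-pathway table cell.

    Site-resolved targets list positions ascending, with ``*`` marking
    residues the focal kinase can phosphorylate directly; presence-only
    targets render as ``X``.
    """
    if target.sites:
        return " ; ".join(
            f"{s} *" if s in target.direct_sites else str(s)
            for s in sorted(target.sites)
        )
    if target.evidence == EVIDENCE_PRESENCE or dataset_uses_presence:
        return "X"
    return "X"


def pathway_target_table(
    pathway_id: str,
    datasets: list[TargetDataset],
    db: PathwayDB,
) -> pd.DataFrame:
    """Per-pathway target summary (one row per member hit in >=1 dataset).

    Columns: gene symbol, accession, then one column per dataset holding
    the rendered sites (``X`` for presence-only evidence, ``*`` for direct
    phosphorylation), empty if the member is not a target there.
    """
    if pathway_id not in db.pathways:
        raise P2NError(f"unknown pathway id: {pathway_id}")
    pw = db.pathways[pathway_id]
    rows = []
    for acc in sorted(pw.members):
        cells = {}
        symbol = ""
        hit = False
        for ds in datasets:
            t = ds.targets.get(acc)
            if t is None:
                cells[ds.name] = ""
            else:
                hit = True
                cells[ds.name] = render_sites(t)
                symbol = symbol or (t.protein.symbol or "")
        if hit:
            rows.append({"symbol": symbol, "accession": acc, **cells})
    cols = ["symbol", "accession"] + [ds.name for ds in datasets]
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values(["symbol", "accession"]).reset_index(drop=True)
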