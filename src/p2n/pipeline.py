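"""End-to-end orchestration of the comparative network analysis.

The pipeline sequences the library stages — normalize targets, score and
select pathways, build per-condition prior-knowledge networks plus a
random baseline, profile topology, fuse and score rewiring, and extract
shortest-path propagation subnetworks — writing every output file and a
run manifest with checksums. Stages do no hidden computation here; each
is individually callable from the library.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import enrichment, fusion, io, netbuild, propagation, topology
from .core import PhosphoTarget, Protein, add_manual_targets, normalize_targets
from .errors import P2NError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration for a full comparative run."""

    targets: dict[str, str]  # condition label -> TSV path
    databases: list[dict]  # [{source, gmt, sif}]
    focal: str
    outdir: str = "p2n-out"
    alpha: float = 0.05
    log_base: float = 10.0
    clustering: dict = field(default_factory=lambda: {"metric": "euclidean", "method": "complete"})
    fusion_sides: dict = field(default_factory=dict)  # {side_a: [...], side_b: [...]}
    propagation: dict = field(default_factory=lambda: {"k": 5, "epsilon": 1.0, "scheme": "random_walk", "mode": "all_pathways"})
    manual_additions: dict = field(default_factory=dict)  # condition -> [{accession, symbol, sites}]
    random_baseline_size: int | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            cfg = cls(**raw)
        except TypeError as exc:
            raise ValidationError(f"bad config keys: {exc}") from exc
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.focal:
            raise ValidationError("config must name a focal kinase accession")
        if not self.targets:
            raise ValidationError("config must list at least one target table")
        if not self.databases:
            raise ValidationError("config must list at least one pathway database")
        for entry in self.databases:
            for key in ("source", "gmt", "sif"):
                if key not in entry:
                    raise ValidationError(f"database entry missing {key!r}: {entry}")
        for p in list(self.targets.values()) + [
            e[k] for e in self.databases for k in ("gmt", "sif")
        ]:
            if not Path(p).exists():
                raise ValidationError(f"input file not found: {p}")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must be in (0, 1)")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(manifest: dict, name: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.time()
            logger.info("stage %s started", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise P2NError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"].append(
                {"name": name, "seconds": round(time.time() - self.t0, 3)}
            )
            return False

    return _Ctx()


def run_compare(cfg: RunConfig) -> dict:
    """Execute the full comparative analysis; returns the run manifest."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(cfg),
        "stages": [],
        "outputs": {},
    }

    def record(path: Path) -> None:
        manifest["outputs"][str(path)] = _sha256(path)

    # stage 1: targets
    with _stage(manifest, "normalize"):
        datasets = {}
        for cond, path in sorted(cfg.targets.items()):
            ds = io.read_target_table(path, cond)
            ds = normalize_targets(ds)
            additions = [
                PhosphoTarget(
                    protein=Protein(a["accession"], a.get("symbol")),
                    sites=frozenset(a.get("sites", [])),
                    direct_sites=frozenset(a.get("direct_sites", [])),
                    direction="up",
                )
                for a in cfg.manual_additions.get(cond, [])
            ]
            if additions:
                ds = add_manual_targets(ds, additions)
            datasets[cond] = ds

    with _stage(manifest, "load-databases"):
        db = None
        for entry in cfg.databases:
            part = io.read_pathway_db(entry["gmt"], entry["sif"], entry["source"])
            db = part if db is None else db.combined_with(part)

    # stage 2: enrichment and selection
    with _stage(manifest, "enrich-select"):
        per_condition = {}
        selections = {}
        for cond, ds in datasets.items():
            results = enrichment.fisher_enrichment(
                ds, db, alpha=cfg.alpha, log_base=cfg.log_base
            )
            per_condition[cond] = results
            selections[cond] = enrichment.select_pathways(
                results, ds, db, alpha=cfg.alpha
            )
            path = outdir / f"enrich_{cond}.tsv"
            pd.DataFrame([dataclasses.asdict(r) for r in results]).to_csv(
                path, sep="\t", index=False
            )
            record(path)
        if len(datasets) >= 2:
            diff = enrichment.differential_enrichment(per_condition)
            path = outdir / "diff_enrich.tsv"
            pd.DataFrame(
                [
                    {"pathway_id": d.pathway_id, "mean": d.mean, **d.deviations}
                    for d in diff
                ]
            ).to_csv(path, sep="\t", index=False)
            record(path)
            matrix = enrichment.enrichment_matrix(per_condition)
            if matrix.shape[0] >= 2 and matrix.shape[1] >= 2:
                clust = enrichment.cluster_enrichment(matrix, **cfg.clustering)
                path = outdir / "cluster.json"
                path.write_text(
                    json.dumps(
                        {
                            "row_order": list(clust.row_order),
                            "col_order": list(clust.col_order),
                            "row_linkage": clust.row_linkage.tolist(),
                            "col_linkage": clust.col_linkage.tolist(),
                        },
                        indent=1,
                    )
                )
                record(path)

    # stage 3: network construction + random baseline + topology
    with _stage(manifest, "build"):
        nets = {}
        for cond, ds in datasets.items():
            nets[cond] = netbuild.build_network(
                selections[cond].selected, db, list(datasets.values()),
                focal=cfg.focal, name=cond,
            )
            path = outdir / f"net_{cond}.graphml"
            io.write_graphml(nets[cond], path)
            record(path)
        size = cfg.random_baseline_size or round(
            sum(len(d) for d in datasets.values()) / len(datasets)
        )
        random_net = netbuild.build_random_network(
            db, size=size, seed=cfg.seed, alpha=cfg.alpha
        )
        if random_net.n_nodes:
            path = outdir / "net_random.graphml"
            io.write_graphml(random_net, path)
            record(path)

    with _stage(manifest, "topology"):
        topo = {}
        for name, net in {**nets, "random": random_net}.items():
            if net.n_nodes == 0:
                continue
            report = topology.global_topology(net)
            entry = {
                "n_nodes": report.n_nodes,
                "n_edges": report.n_edges,
                "mean_clustering": report.mean_clustering,
                "char_path_length": report.char_path_length,
                "power_law_r2": report.power_law.r_squared if report.power_law else None,
                "power_law_exponent": report.power_law.exponent if report.power_law else None,
            }
            if cfg.focal in net.graph:
                fm = topology.focal_node_metrics(net, cfg.focal)
                entry["focal"] = dataclasses.asdict(fm)
            topo[name] = entry
        path = outdir / "topology.json"
        path.write_text(json.dumps(topo, indent=1))
        record(path)

    # stage 4: fusion + rewiring
    with _stage(manifest, "fuse"):
        sides = cfg.fusion_sides or _default_sides(list(datasets))
        side_a, side_b = sides["side_a"], sides["side_b"]
        merged_a = fusion.merge_condition_networks(
            [nets[c] for c in side_a], label="+".join(side_a)
        )
        merged_b = fusion.merge_condition_networks(
            [nets[c] for c in side_b], label="+".join(side_b)
        )
        fused = fusion.align_networks(merged_a, merged_b)
        report = fusion.rewiring_scores(fused, set(side_a), set(side_b))
        path = outdir / "rewiring.tsv"
        report.to_csv(path, sep="\t", index=False)
        record(path)
        path = outdir / "fusion.graphml"
        io.write_graphml(
            netbuild.SignalingNetwork(fused.graph, "fusion", {"origins": list(fused.origins)}),
            path,
        )
        record(path)

    # stage 5: propagation over the full prior-knowledge network
    with _stage(manifest, "propagate"):
        full_net = netbuild.build_network(
            set(db.pathways), db, list(datasets.values()),
            focal=cfg.focal, name="full-db",
        )
        prop_cfg = cfg.propagation
        weights = propagation.weight_edges(full_net, prop_cfg.get("scheme", "random_walk"))
        ensemble = propagation.propagation_subnetwork(
            full_net, weights, cfg.focal, list(datasets.values()),
            k=prop_cfg.get("k", 5), epsilon=prop_cfg.get("epsilon", 1.0),
            mode=prop_cfg.get("mode", "all_pathways"),
            condition_networks=nets,
        )
        path = outdir / "paths.json"
        path.write_text(
            json.dumps(
                {
                    cond: {
                        tgt: [
                            {"nodes": list(p.nodes), "weight": p.weight}
                            for p in paths
                        ]
                        for tgt, paths in targets.items()
                    }
                    for cond, targets in ensemble.paths.items()
                },
                indent=1,
            )
        )
        record(path)
        path = outdir / "propagation.graphml"
        io.write_graphml(ensemble.subnetwork, path)
        record(path)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("run complete: %s", manifest_path)
    return manifest


def _default_sides(conditions: list[str]) -> dict:
    """First n-1 conditions vs the last, when no sides are configured."""
    if len(conditions) < 2:
        raise ValidationError("fusion needs at least two conditions")
    ordered = sorted(conditions)
    return {"side_a": ordered[:-1], "side_b": ordered[-1:]}
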