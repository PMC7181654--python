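"""End-to-end orchestration: annotation -> biotypes -> expression prep ->
stage clustering -> co-expression modules -> MI networks -> coding
potential -> enrichment, under one declarative config.

Every intermediate is persisted as TSV next to the report, the resolved
config is written alongside, and the run is deterministic given the
config + seed (the report contains no timestamps, so identical runs are
byte-identical).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from . import __version__
from .annotation import classify_all, read_annotation
from .aracne import (
    apply_dpi,
    hub_rank,
    infer_network,
    network_delta,
    write_edges,
)
from .expression import (
    annotation_table,
    associated_gene_sets,
    filter_expressed,
    fraction_expressed_by_biotype,
    load_matrix,
    standardize_time,
)
from .fickett import score_transcripts
from .fuzzy import (
    FCMConfig,
    assign_stages,
    fcm_cluster,
    read_markers,
    stage_gene_counts,
)
from .wgcna import DEFAULT_BETA, stratified_module_counts

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


@dataclass
class PipelineConfig:
    annotation: str
    expression: str
    markers: str
    outdir: str
    gene_set: str | None = None
    fasta: str | None = None
    #: biotype -> {"t0": path, "t1": path} of sample x gene TSVs
    networks: Mapping[str, Mapping[str, str]] = field(default_factory=dict)
    network_hub: str | None = None
    genic_window: int = 5000
    rpkm_threshold: float = 1.0
    min_timepoints: int = 1
    log_transform: bool = True
    fcm_c: int = 9
    fcm_m: float = 1.25
    min_acore: float = 0.5
    fcm_tol: float = 1e-6
    fcm_max_iter: int = 1000
    fcm_n_init: int = 5
    beta: float = DEFAULT_BETA
    cut_height: float = 0.97
    min_module_size: int = 10
    alpha: float = 0.001
    n_perm: int = 4000
    mi_bins: int = 10
    dpi_tolerance: float = 0.15
    fickett_cutoff: float = 0.74
    coverage_cutoff: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        required = {
            "annotation": self.annotation,
            "expression": self.expression,
            "markers": self.markers,
        }
        for name, p in required.items():
            if not p or not Path(p).exists():
                raise ConfigError(f"required input {name!r} missing: {p}")
        for name, p in (("gene_set", self.gene_set), ("fasta", self.fasta),
                        ("network_hub", self.network_hub)):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"configured input {name!r} missing: {p}")
        for biotype, stages in self.networks.items():
            for key, p in stages.items():
                if not Path(p).exists():
                    raise ConfigError(
                        f"network input {biotype}/{key} missing: {p}"
                    )


def config_from_bundle(
    manifest: Mapping, outdir: str | Path, seed: int | None = None
) -> PipelineConfig:
    """Pipeline config wired to a simulate_bundle manifest."""
    return PipelineConfig(
        annotation=manifest["annotation"],
        expression=manifest["expression"],
        markers=manifest["markers"],
        gene_set=manifest.get("gene_set"),
        fasta=manifest.get("fasta"),
        networks=manifest.get("networks", {}),
        network_hub=manifest.get("network_hub"),
        outdir=str(outdir),
        seed=manifest["seed"] if seed is None else seed,
    )


def enrichment_percent(
    biotype_sets: Mapping[str, list[str]],
    target_set: set[str] | list[str],
    background: set[str] | list[str],
) -> pd.DataFrame:
    """Per biotype: percent of its genes in the target set plus a one-sided
    hypergeometric over-representation p-value against the background."""
    target = set(target_set)
    universe = set(background)
    if not target <= universe:
        raise ValueError("target_set must be a subset of background")
    rows = []
    for biotype, ids in biotype_sets.items():
        ids = [g for g in ids if g in universe]
        k = sum(g in target for g in ids)
        if len(ids) == 0:
            rows.append(
                {"biotype": biotype, "n_genes": 0, "n_in_target": 0,
                 "percent": np.nan, "p_hypergeom": np.nan}
            )
            continue
        p = float(
            hypergeom.sf(k - 1, len(universe), len(target), len(ids))
        )
        rows.append(
            {
                "biotype": biotype,
                "n_genes": len(ids),
                "n_in_target": k,
                "percent": 100.0 * k / len(ids),
                "p_hypergeom": p,
            }
        )
    return pd.DataFrame(rows).set_index("biotype")


def rank_genes_by_stage_signal(
    z: pd.DataFrame, stage_timepoint: str
) -> tuple[pd.DataFrame, np.ndarray]:
    """Rank genes of one biotype by their z-score at the stage timepoint
    and return the average-linkage (correlation distance) tree for the
    heatmap ordering.  Ties break lexicographically; deterministic."""
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import pdist

    if z.shape[0] < 2:
        raise ValueError("ranking needs at least 2 genes")
    if stage_timepoint not in z.columns:
        raise ValueError(f"unknown timepoint {stage_timepoint!r}")
    order = sorted(
        z.index, key=lambda g: (-z.loc[g, stage_timepoint], g)
    )
    ranked = pd.DataFrame(
        {
            "gene_id": order,
            "z_at_stage": [float(z.loc[g, stage_timepoint]) for g in order],
            "rank": np.arange(1, len(order) + 1),
        }
    ).set_index("gene_id")
    dist = pdist(z.to_numpy(), metric="correlation")
    tree = linkage(np.clip(dist, 0, None), method="average")
    return ranked, tree


def _load_network(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages in dependency order and write the run report.

    Any stage failure aborts with the stage name in the exception message;
    intermediates written so far are retained.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    resolved = dataclasses.asdict(cfg)
    (outdir / "resolved_config.json").write_text(
        json.dumps(resolved, indent=1, sort_keys=True)
    )
    report: dict = {}
    stage = "annotation"
    try:
        genes = read_annotation(cfg.annotation)
        assignments = classify_all(genes, cfg.genic_window)
        from .annotation import assignments_to_frame

        aframe = assignments_to_frame(assignments)
        aframe.to_csv(outdir / "biotype_assignments.tsv", sep="\t", index=False)
        ann = annotation_table(genes, assignments)
        ann.to_csv(outdir / "gene_annotations.tsv", sep="\t")
        report["annotation"] = {
            "n_genes": len(genes),
            "n_lncRNA": int((aframe.shape[0])),
            "biotype_counts": aframe["biotype"].value_counts().to_dict(),
        }
        logger.info("annotation: %d genes, %d lncRNAs", len(genes), len(aframe))

        stage = "expression_prep"
        m = load_matrix(cfg.expression, ann)
        fractions = fraction_expressed_by_biotype(m, cfg.rpkm_threshold,
                                                  cfg.min_timepoints)
        fractions.to_csv(outdir / "fraction_expressed.tsv", sep="\t")
        filtered = filter_expressed(m, cfg.rpkm_threshold, cfg.min_timepoints)
        z = standardize_time(filtered, log_transform=cfg.log_transform)
        z.to_csv(outdir / "standardized_matrix.tsv", sep="\t")
        report["expression"] = {
            "n_genes": m.data.shape[0],
            "n_expressed": filtered.data.shape[0],
            "fraction_expressed": {
                k: (None if pd.isna(v) else round(float(v), 6))
                for k, v in fractions.items()
            },
        }
        logger.info(
            "expression: %d/%d genes pass the %.2f RPKM filter",
            filtered.data.shape[0], m.data.shape[0], cfg.rpkm_threshold,
        )

        stage = "stage_clustering"
        fcm_cfg = FCMConfig(
            c=cfg.fcm_c, m=cfg.fcm_m, min_acore=cfg.min_acore,
            tol=cfg.fcm_tol, max_iter=cfg.fcm_max_iter, seed=cfg.seed,
            n_init=cfg.fcm_n_init,
        )
        res = fcm_cluster(z, fcm_cfg)
        res.memberships.to_csv(outdir / "memberships.tsv", sep="\t")
        pd.DataFrame(
            res.centroids,
            index=[f"C{j}" for j in range(cfg.fcm_c)],
            columns=z.columns,
        ).to_csv(outdir / "centroids.tsv", sep="\t")
        markers = read_markers(cfg.markers)
        stages = assign_stages(res, markers, cfg.min_acore)
        stages.evidence.assign(
            stage=[stages.mapping[j] for j in range(len(stages.evidence))]
        ).to_csv(outdir / "stage_assignments.tsv", sep="\t")
        counts = stage_gene_counts(res, stages, ann, cfg.min_acore)
        counts.to_csv(outdir / "stage_counts.tsv", sep="\t")
        report["stages"] = {
            "cluster_stages": {f"C{j}": s for j, s in stages.mapping.items()},
            "stage_counts": {
                s: {b: int(c) for b, c in row.items() if c}
                for s, row in counts.iterrows()
            },
            "fcm_iterations": res.iterations,
        }
        logger.info("stages: %s", report["stages"]["cluster_stages"])

        stage = "coexpression_modules"
        strata = associated_gene_sets(ann)
        module_counts, module_labels = stratified_module_counts(
            z, strata, beta=cfg.beta, cut_height=cfg.cut_height,
            min_module_size=cfg.min_module_size,
        )
        pd.concat(
            [
                lab.to_frame().assign(biotype=b)
                for b, lab in module_labels.items()
                if len(lab)
            ]
        ).to_csv(outdir / "module_labels.tsv", sep="\t")
        report["module_counts"] = module_counts
        logger.info("module counts: %s", module_counts)

        stage = "mi_network"
        if cfg.networks:
            deltas = []
            for biotype, paths in cfg.networks.items():
                nets = {}
                for key in ("t0", "t1"):
                    data = _load_network(paths[key])
                    net = infer_network(
                        data, alpha=cfg.alpha, n_perm=cfg.n_perm,
                        bins=cfg.mi_bins, seed=cfg.seed,
                    )
                    net = apply_dpi(net, cfg.dpi_tolerance)
                    write_edges(net, outdir / f"edges_{biotype}_{key}.tsv")
                    nets[key] = net
                d = network_delta(
                    nets["t0"], nets["t1"], {biotype: list(data.columns)}
                )
                deltas.append(d)
            delta = pd.concat(deltas)
            delta.to_csv(outdir / "network_delta.tsv", sep="\t")
            report["network_delta"] = {
                b: {k: int(v) for k, v in row.items()}
                for b, row in delta.iterrows()
            }
            logger.info("network delta:\n%s", delta)
        if cfg.network_hub:
            data = _load_network(cfg.network_hub)
            net = apply_dpi(
                infer_network(
                    data, alpha=cfg.alpha, n_perm=cfg.n_perm,
                    bins=cfg.mi_bins, seed=cfg.seed,
                ),
                cfg.dpi_tolerance,
            )
            ranking = hub_rank(net)
            pd.DataFrame(ranking, columns=["gene_id", "degree"]).to_csv(
                outdir / "hub_ranking.tsv", sep="\t", index=False
            )
            report["hub"] = {
                "top": ranking[0][0] if ranking else None,
                "degree": int(ranking[0][1]) if ranking else 0,
            }
            logger.info("hub gene: %s", report["hub"]["top"])

        stage = "coding_potential"
        if cfg.fasta:
            cp = score_transcripts(
                cfg.fasta, cfg.fickett_cutoff, cfg.coverage_cutoff
            )
            cp.to_csv(outdir / "coding_potential.tsv", sep="\t", index=False)
            report["coding_potential"] = {
                "n_transcripts": int(cp.shape[0]),
                "verdicts": cp["verdict"].value_counts().to_dict(),
                "mean_fickett": round(float(cp["fickett_score"].mean()), 6),
            }

        stage = "enrichment"
        if cfg.gene_set:
            target = [
                line.strip()
                for line in Path(cfg.gene_set).read_text().splitlines()
                if line.strip()
            ]
            background = sorted({g for ids in strata.values() for g in ids})
            enr = enrichment_percent(strata, target, background)
            enr.to_csv(outdir / "enrichment.tsv", sep="\t")
            report["enrichment"] = {
                b: {
                    "percent": None if pd.isna(row["percent"])
                    else round(float(row["percent"]), 4),
                    "p": None if pd.isna(row["p_hypergeom"])
                    else round(float(row["p_hypergeom"]), 6),
                }
                for b, row in enr.iterrows()
            }
        else:
            report["enrichment"] = "skipped: no gene_set input"

    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report["provenance"] = {
        "seed": cfg.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(resolved, sort_keys=True).encode()
        ).hexdigest(),
        "package_version": __version__,
    }
    body = json.dumps(report, indent=1, sort_keys=True)
    (outdir / "report.json").write_text(body)
    (outdir / "report.txt").write_text(_human_report(report))
    return report


def _human_report(report: dict) -> str:
    lines = ["lncstage run report", "=" * 40]
    for section in sorted(report):
        lines.append(f"\n[{section}]")
        lines.append(json.dumps(report[section], indent=2, sort_keys=True))
    return "\n".join(lines) + "\n"
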