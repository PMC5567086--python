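"""End-to-end orchestration: read inputs, filter, collapse + burden test,
gene-set enrichment + clustering, network degrees, and a run report.

Every stage writes its table with a provenance header (tool version +
config hash) so a re-run with the same inputs and configuration is
byte-identical.  A failure in any stage aborts with a stage-named error.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from .burden import GeneBurden, summarize_variants
from .enrichment import TermEnrichmentAnalysis
from .filters import FilterConfig, apply_cascade
from .io import (
    InputError,
    read_annotations,
    read_edge_list,
    read_gene_sets,
    read_panel,
    read_vcf,
    write_table,
)
from .network import build_network, degrees

logger = logging.getLogger("rvburden")

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage."""


@dataclass
class RunConfig:
    vcf: str
    annotations: str
    phenotypes: str
    out_dir: str
    panel: str | None = None
    gene_sets: str | None = None
    background: str | None = None
    edges: str | None = None
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    burden_alternative: str = "greater"  # or "two-sided"
    carrier_coding: str = "dominant"  # or "allelic"
    enrichment_method: str = "ease"  # or "fisher"
    kappa_threshold: float = 0.35
    seed_min_size: int = 3
    merge_overlap: float = 0.5

    def as_dict(self) -> dict:
        d = {
            "burden_alternative": self.burden_alternative,
            "carrier_coding": self.carrier_coding,
            "enrichment_method": self.enrichment_method,
            "kappa_threshold": self.kappa_threshold,
            "seed_min_size": self.seed_min_size,
            "merge_overlap": self.merge_overlap,
        }
        d.update(self.filter_config.as_dict())
        return d


def _read_phenotypes(path: str) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("SAMPLE", "PHENOTYPE"):
        if col not in df.columns:
            raise InputError(f"phenotype file {path} lacks column {col}")
    return dict(zip(df["SAMPLE"], df["PHENOTYPE"]))


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name}: {exc}") from exc

        return inner

    return wrap


@_stage("variant_io")
def _load_inputs(cfg: RunConfig):
    phenotype = _read_phenotypes(cfg.phenotypes)
    cohort = read_vcf(cfg.vcf, phenotype=phenotype)
    annotations = read_annotations(cfg.annotations)
    panel = read_panel(cfg.panel) if cfg.panel else set()
    return cohort, annotations, panel


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages; returns a report dict and writes tables to out_dir."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    conf = cfg.as_dict()
    report: dict = {}

    cohort, annotations, panel = _load_inputs(cfg)
    logger.info(
        "loaded %d samples (%d cases / %d controls), %d variants",
        len(cohort.samples), cohort.n_cases, cohort.n_controls, len(cohort.variants),
    )

    # --- filter cascade -------------------------------------------------
    try:
        qualifying, trace = apply_cascade(
            cohort.variants, annotations, panel, cfg.filter_config
        )
    except Exception as exc:
        raise PipelineError(f"stage filter_engine: {exc}") from exc
    trace_df = pd.DataFrame(trace.stages, columns=["STAGE", "N_SURVIVING"])
    write_table(trace_df, os.path.join(cfg.out_dir, "filter_trace.tsv"), conf)
    n_snv, n_indel, n_genes = summarize_variants(qualifying)
    report["filter_trace"] = trace.counts()
    report["qualifying"] = {"snvs": n_snv, "indels": n_indel, "genes": n_genes}
    logger.info(
        "qualifying set: %d SNVs + %d indels covering %d genes",
        n_snv, n_indel, n_genes,
    )

    # --- gene burden ----------------------------------------------------
    try:
        if qualifying:
            results = GeneBurden.from_cohort(
                qualifying, cohort, coding=cfg.carrier_coding
            ).fit(alternative=cfg.burden_alternative)
            burden_df = results.frame
        else:
            burden_df = pd.DataFrame(
                columns=[
                    "GENE", "CASES_CARRIER", "CASES_NONCARRIER",
                    "CONTROLS_CARRIER", "CONTROLS_NONCARRIER", "P", "Q",
                ]
            )
    except Exception as exc:
        raise PipelineError(f"stage gene_burden: {exc}") from exc
    write_table(burden_df, os.path.join(cfg.out_dir, "burden.tsv"), conf)
    report["top_burden"] = burden_df.head(10).to_dict("records")

    mutated_genes = sorted({v.gene for v in qualifying})

    # --- pathway enrichment ---------------------------------------------
    if cfg.gene_sets and cfg.background and mutated_genes:
        try:
            collection = read_gene_sets(cfg.gene_sets, cfg.background)
            enr = TermEnrichmentAnalysis(
                mutated_genes, collection, method=cfg.enrichment_method
            ).fit()
            clusters = enr.cluster(
                kappa_threshold=cfg.kappa_threshold,
                seed_min_size=cfg.seed_min_size,
                merge_overlap=cfg.merge_overlap,
            )
        except Exception as exc:
            raise PipelineError(f"stage pathway_enrichment: {exc}") from exc
        write_table(enr.frame, os.path.join(cfg.out_dir, "enrichment.tsv"), conf)
        write_table(
            enr.cluster_frame(clusters),
            os.path.join(cfg.out_dir, "clusters.tsv"),
            conf,
        )
        report["top_terms"] = enr.frame.head(5).to_dict("records")
        report["top_clusters"] = [
            {"cluster_id": c.cluster_id, "score": c.enrichment_score,
             "members": list(c.member_terms)}
            for c in clusters[:5]
        ]

    # --- network degrees -------------------------------------------------
    if cfg.edges and mutated_genes:
        try:
            edge_list = read_edge_list(cfg.edges)
            net = build_network(mutated_genes, edge_list)
            deg_df = degrees(net)
        except Exception as exc:
            raise PipelineError(f"stage network_degree: {exc}") from exc
        write_table(deg_df, os.path.join(cfg.out_dir, "degrees.tsv"), conf)
        report["top_degree"] = deg_df.head(10).to_dict("records")

    _write_report(report, os.path.join(cfg.out_dir, "report.txt"))
    return report


def _write_report(report: dict, path: str) -> None:
    lines = ["rvburden run report", "=" * 40]
    if "filter_trace" in report:
        lines.append("Filter cascade (variants surviving each stage):")
        for stage, n in report["filter_trace"].items():
            lines.append(f"  {stage:<16} {n}")
    if "qualifying" in report:
        q = report["qualifying"]
        lines.append(
            f"Qualifying set: {q['snvs']} SNVs + {q['indels']} indels "
            f"covering {q['genes']} genes"
        )
    if report.get("top_burden"):
        lines.append("Top burden genes (gene, a/b vs c/d, p, q):")
        for r in report["top_burden"][:5]:
            lines.append(
                f"  {r['GENE']:<10} {r['CASES_CARRIER']}/{r['CASES_NONCARRIER']} "
                f"vs {r['CONTROLS_CARRIER']}/{r['CONTROLS_NONCARRIER']} "
                f"p={r['P']:.3f} q={r['Q']:.3f}"
            )
    if report.get("top_terms"):
        lines.append("Top enriched terms (term, fold, p_ease):")
        for r in report["top_terms"]:
            lines.append(
                f"  {r['TERM_ID']:<10} fold={r['FOLD']:.2f} p={r['P_EASE']:.3g}"
            )
    if report.get("top_clusters"):
        lines.append("Top term clusters (score = -log10 geometric mean p):")
        for c in report["top_clusters"]:
            lines.append(
                f"  cluster {c['cluster_id']}: score={c['score']:.2f} "
                f"members={','.join(c['members'])}"
            )
    if report.get("top_degree"):
        lines.append("Highest-degree network genes:")
        for r in report["top_degree"][:5]:
            lines.append(
                f"  {r['GENE']:<10} ({r['ORIGIN']}) in={r['IN_DEGREE']} "
                f"out={r['OUT_DEGREE']} deg={r['DEGREE']}"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
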