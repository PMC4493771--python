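"""End-to-end orchestration: simulate/load -> test -> screen -> classify.

Every stage's output is materialized to the output directory as TSV or
JSON, so any stage can be re-run or audited in isolation, and the run
ends in a consolidated ``RunReport`` whose counts are all recomputable
from the files on disk.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .detest import (DEFAULT_FDR, DEFAULT_FOLD_CHANGE, STANDARD_PAIRS,
                     call_all_pairs)
from .enrichment import (DEFAULT_ALPHA, AnnotationMap, hypergeom_enrich,
                         select_candidates)
from .formatting import percentage, thousands
from .kinetics import (classify_profiles, sign_profiles, subcluster,
                       summarize_classification)
from .qpcr import concordance, delta_delta_ct, load_ct_table
from .quantify import CountMatrix, compute_rpkm, library_stats, load_counts
from .responsive import build_responsive
from .synthetic import (SimConfig, config_to_dict, generate_annotation,
                        generate_ct_table, generate_experiment)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""


@dataclass
class PipelineConfig:
    """Inputs, thresholds and mode flags of one pipeline run.

    Exactly one of ``sim`` (a synthetic experiment) or ``counts_path``
    (a real count table plus annotation TSVs) must be supplied.
    """

    outdir: str | Path = "dtapipe_out"
    sim: SimConfig | None = None
    counts_path: str | Path | None = None
    go_annotation_path: str | Path | None = None
    kegg_annotation_path: str | Path | None = None
    ct_table_path: str | Path | None = None
    accounting_path: str | Path | None = None
    fdr_deg: float = DEFAULT_FDR
    fc: float = DEFAULT_FOLD_CHANGE
    go_fdr: float = DEFAULT_ALPHA
    kegg_q: float = DEFAULT_ALPHA
    direction_aware_subtraction: bool = False
    subcluster_mode: str = "sign"
    concordance_metric: str = "day1"
    qpcr_targets: int = 41
    qpcr_noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.counts_path is None):
            raise PipelineError(
                "supply exactly one of a SimConfig or a counts path")
        if not (0 < self.fdr_deg <= 1) or self.fc < 1:
            raise PipelineError("invalid DEG thresholds")
        if not (0 < self.go_fdr <= 1) or not (0 < self.kegg_q <= 1):
            raise PipelineError("invalid enrichment thresholds")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        sim_payload = payload.pop("sim", None)
        sim = None
        if sim_payload is not None:
            from .synthetic import AnnotationConfig
            ann = sim_payload.pop("annotation", None)
            if ann is not None:
                for key in ("term_size_range",):
                    if key in ann:
                        ann[key] = tuple(ann[key])
                sim_payload["annotation"] = AnnotationConfig(**ann)
            for key in ("gene_length_range", "abundance_range"):
                if key in sim_payload:
                    sim_payload[key] = tuple(sim_payload[key])
            sim = SimConfig(**sim_payload)
        return cls(sim=sim, **payload)


@dataclass
class RunReport:
    """Consolidated accounting of one pipeline run."""

    seed: int
    version: str
    config: dict
    library_totals: dict[str, int]
    library_stats: list[dict] | None
    pair_deg_counts: dict[str, int]
    timepoint_sizes: dict[str, int]
    responsive_total: int
    enrichment: dict
    candidate_total: int
    classification: dict
    qpcr_concordance: dict | None = None
    truth_recovery: dict | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")


def _pair_key(pair: tuple[str, str]) -> str:
    return f"{pair[0]}_vs_{pair[1]}"


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run every stage, writing each output under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = None

    # --- inputs -----------------------------------------------------------
    if config.sim is not None:
        logger.info("simulating experiment (seed=%d)", config.sim.seed)
        counts, truth = generate_experiment(config.sim)
        annot_go = generate_annotation(config.sim, truth, "GO-like")
        annot_kegg = generate_annotation(config.sim, truth, "KEGG-like")
        ct_table = None
        if config.qpcr_targets:
            n_targets = min(config.qpcr_targets, len(truth.non_null))
            if n_targets:
                ct_table = generate_ct_table(
                    truth, n_targets, noise_sd=config.qpcr_noise_sd,
                    seed=config.sim.seed)
        counts.to_tsv(outdir / "counts.tsv")
        truth.to_json(outdir / "truth.json")
        annot_go.to_tsv(outdir / "annotation_go.tsv")
        annot_kegg.to_tsv(outdir / "annotation_kegg.tsv")
        if ct_table is not None:
            ct_table.to_csv(outdir / "ct_table.tsv", sep="\t", index=False)
    else:
        counts = load_counts(config.counts_path)
        if not (config.go_annotation_path and config.kegg_annotation_path):
            raise PipelineError("annotation TSVs required with a counts path")
        annot_go = AnnotationMap.from_tsv(config.go_annotation_path)
        annot_kegg = AnnotationMap.from_tsv(config.kegg_annotation_path)
        ct_table = (load_ct_table(config.ct_table_path)
                    if config.ct_table_path else None)

    stats_records = None
    if config.accounting_path:
        stats = library_stats(
            pd.read_csv(config.accounting_path, sep="\t", index_col=0))
        stats.to_csv(outdir / "library_stats.tsv", sep="\t")
        stats_records = stats.reset_index().to_dict(orient="records")

    # --- quantification ---------------------------------------------------
    expr = compute_rpkm(counts)
    expr.to_tsv(outdir / "rpkm.tsv")
    library_totals = {k: int(v) for k, v in counts.totals().items()}
    logger.info("assigned totals: %s", library_totals)

    # --- differential expression ------------------------------------------
    deg_tables = call_all_pairs(counts, fdr_threshold=config.fdr_deg,
                                fc_threshold=config.fc)
    pair_deg_counts = {}
    for pair, table in deg_tables.items():
        table.to_csv(outdir / f"deg_{_pair_key(pair)}.tsv",
                     sep="\t", index=False)
        pair_deg_counts[_pair_key(pair)] = int(
            (table["direction"] != "none").sum())
    logger.info("DEG counts at FDR<=%g, fold>=%g: %s",
                config.fdr_deg, config.fc, pair_deg_counts)

    # --- background subtraction and union ---------------------------------
    responsive = build_responsive(
        deg_tables, direction_aware=config.direction_aware_subtraction)
    responsive.write(outdir)
    timepoint_sizes = {
        f"ETH{t}/CK{t}": len(tab) for t, tab in responsive.per_timepoint.items()
    }
    logger.info("responsive sizes: %s, union=%d",
                timepoint_sizes, len(responsive.union))

    # --- enrichment screen --------------------------------------------------
    background = set(counts.expressed_genes())
    study = responsive.genes & background
    enrichment_report: dict = {"go": {}, "kegg": {}}
    if study:
        go_res = hypergeom_enrich(study, background, annot_go,
                                  alpha=config.go_fdr)
        kegg_res = hypergeom_enrich(study, background, annot_kegg,
                                    alpha=config.kegg_q)
        go_res.to_csv(outdir / "enrichment_go.tsv", sep="\t", index=False)
        kegg_res.to_csv(outdir / "enrichment_kegg.tsv", sep="\t", index=False)
        cand = select_candidates(go_res, kegg_res, annot_go, annot_kegg,
                                 responsive.genes)
        enrichment_report = {
            "go": {"terms": len(go_res),
                   "significant": int(go_res["significant"].sum())},
            "kegg": {"terms": len(kegg_res),
                     "significant": int(kegg_res["significant"].sum())},
            "branches": cand.sizes,
        }
        candidates = cand.candidates
    else:
        candidates = frozenset()
    pd.DataFrame({"gene_id": sorted(candidates)}).to_csv(
        outdir / "candidates.tsv", sep="\t", index=False)
    logger.info("candidates: %d of %d responsive", len(candidates), len(study))

    # --- temporal classification -------------------------------------------
    classification: dict = {"total": 0}
    if candidates:
        profiles = sign_profiles(responsive, candidates)
        assignments = classify_profiles(profiles)
        assignments["subcluster"] = subcluster(
            assignments, profiles, mode=config.subcluster_mode)
        assignments_out = assignments.merge(
            profiles[["gene_id", "s1", "s2", "s3"]], on="gene_id")
        assignments_out.to_csv(outdir / "assignments.tsv", sep="\t",
                               index=False)
        summary = summarize_classification(assignments, profiles)
        summary.to_json(outdir / "classification_summary.json")
        summary.heatmap.to_csv(outdir / "heatmap_matrix.tsv", sep="\t",
                               index=False)
        classification = summary.to_dict()

    # --- qPCR validation ----------------------------------------------------
    qpcr_summary = None
    if ct_table is not None and len(ct_table):
        re_table = delta_delta_ct(ct_table)
        re_table.to_csv(outdir / "qpcr_re.tsv", sep="\t", index=False)
        conc_table, qpcr_summary = concordance(
            re_table, expr, method=config.concordance_metric)
        conc_table.to_csv(outdir / "qpcr_concordance.tsv", sep="\t",
                          index=False)
        Path(outdir / "qpcr_concordance.json").write_text(
            json.dumps(qpcr_summary, indent=2) + "\n")
        logger.info("qPCR concordance: %d/%d", qpcr_summary["concordant"],
                    qpcr_summary["total"])

    # --- truth recovery (synthetic runs only) --------------------------------
    truth_recovery = None
    if truth is not None:
        planted = set(truth.non_null["gene_id"])
        recovered = responsive.genes & planted
        truth_recovery = {
            "planted": len(planted),
            "recovered_responsive": len(recovered),
            "false_responsive": len(responsive.genes - planted),
        }

    config_echo = {
        k: v for k, v in dataclasses.asdict(config).items() if k != "sim"
    }
    config_echo = {k: (str(v) if isinstance(v, Path) else v)
                   for k, v in config_echo.items()}
    if config.sim is not None:
        config_echo["sim"] = config_to_dict(config.sim)

    report = RunReport(
        seed=config.seed,
        version=__version__,
        config=config_echo,
        library_totals=library_totals,
        library_stats=stats_records,
        pair_deg_counts=pair_deg_counts,
        timepoint_sizes=timepoint_sizes,
        responsive_total=len(responsive.union),
        enrichment=enrichment_report,
        candidate_total=len(candidates),
        classification=classification,
        qpcr_concordance=qpcr_summary,
        truth_recovery=truth_recovery,
    )
    report.to_json(outdir / "report.json")
    return report


def render_report(report: RunReport) -> str:
    """Human-readable summary with two-decimal percentages and
    thousands-separated integers."""
    lines = [f"dtapipe {report.version} run (seed={report.seed})", ""]
    if report.library_stats:
        lines.append("Library sequencing statistics")
        for row in report.library_stats:
            lines.append(
                f"  {row.get('library', row.get('index', '?'))}\t"
                f"{thousands(row['total_reads'])}\t"
                f"{thousands(row['mapped_reads'])} ({row['mapped_pct']:.2f}%)\t"
                f"{thousands(row['unique_match_reads'])} "
                f"({row['unique_pct']:.2f}%)")
        lines.append("")
    lines.append("Assigned counts per library")
    for lib, total in report.library_totals.items():
        lines.append(f"  {lib}\t{thousands(total)}")
    lines.append("")
    lines.append("DEG calls per comparison (dual gate)")
    for pair, n in report.pair_deg_counts.items():
        lines.append(f"  {pair}\t{thousands(n)}")
    lines.append("")
    for label, n in report.timepoint_sizes.items():
        lines.append(f"  {label}\t{thousands(n)}")
    lines.append(f"Ethephon-responsive genes (union): "
                 f"{thousands(report.responsive_total)}")
    if report.enrichment.get("branches"):
        b = report.enrichment["branches"]
        lines.append(
            f"Candidate screen: GO branch {thousands(b['go_branch'])}, "
            f"KEGG branch {thousands(b['kegg_branch'])}, "
            f"union {thousands(b['union'])}")
    lines.append(f"Candidate genes: {thousands(report.candidate_total)}")
    cls = report.classification
    if cls.get("total"):
        lines.append("")
        lines.append("Temporal classification")
        for group, n in cls["group_counts"].items():
            pct = cls["group_pct"][group]
            lines.append(f"  Group {group}\t{thousands(n)} ({pct:.2f}%)")
        lines.append(
            f"  day-1 responders: {cls['day1_responder_pct']:.2f}%  "
            f"up: {cls['up_pct']:.2f}%  down: {cls['down_pct']:.2f}%")
    if report.qpcr_concordance:
        q = report.qpcr_concordance
        pct = percentage(q["concordant"], q["total"])
        lines.append("")
        lines.append(
            f"qPCR concordance ({q['method']}): "
            f"{q['concordant']}/{q['total']} ({pct:.2f}%)")
    return "\n".join(lines) + "\n"
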