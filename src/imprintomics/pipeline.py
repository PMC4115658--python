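"""End-to-end orchestration of the synthetic-scenario pipeline.

``run_pipeline`` executes simulate -> imprinting calls -> allele-specific
detection -> DMR calling -> variability classification -> gene/DMR
association, writing all tables plus a JSON manifest.  Given the same
config it is deterministic and idempotent.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .association import associate_genes_dmrs, enrichment_test
from .imprinting import ImprintingParams, call_imprinting, detect_allele_specific
from .io import write_dmr_bed, write_tsv
from .methylation import compare_windows, merge_dmrs
from .synthetic import (
    AS_PEG,
    Cross,
    PlantedDMR,
    PopulationPlan,
    TruthConfig,
    default_crosses,
    make_expression_table,
    make_gene_classes,
    simulate_allele_counts,
    simulate_methylome_pair,
    simulate_population_matrix,
)
from .variability import classify_matrix

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Synthetic-scenario pipeline configuration."""

    seed: int = 0
    out_dir: str = "pipeline_out"
    n_biallelic: int = 300
    n_meg: int = 20
    n_peg: int = 10
    n_seedcoat: int = 5
    allele_specific: list[tuple[str, str, str]] = field(
        default_factory=lambda: [(AS_PEG, "colC", "father")]
    )
    strains: tuple[str, ...] = ("colA", "colB", "colC")
    n_replicates: int = 3
    depth_mean: float = 300.0
    chrom_length: int = 200_000
    n_planted_dmrs: int = 8
    dmr_magnitude: float = 0.5
    n_population_strains: int = 140
    imprinting: ImprintingParams = field(default_factory=ImprintingParams)
    dmr_q_threshold: float = 0.01

    def __post_init__(self):
        if not 0 < self.dmr_q_threshold < 1:
            raise ValueError("q threshold outside (0, 1)")


def build_truth_config(cfg: PipelineConfig) -> tuple[TruthConfig, pd.DataFrame]:
    """TruthConfig plus a gene/TE annotation laid out along one chromosome.

    Genes occupy 2 kb intervals every 5 kb; a planted CG DMR (paired with a
    strongly-bimodal population class) is placed in the upstream flank of
    the first allele-specific gene, the remaining planted DMRs upstream of
    the first ordinary genes.
    """
    classes = make_gene_classes(
        n_biallelic=cfg.n_biallelic,
        n_meg=cfg.n_meg,
        n_peg=cfg.n_peg,
        allele_specific=cfg.allele_specific,
        n_seedcoat=cfg.n_seedcoat,
    )
    genes = sorted(classes)
    spacing, gene_len = 5000, 2000
    chrom_length = max(cfg.chrom_length, len(genes) * spacing + 10_000)
    rows = []
    for i, g in enumerate(genes):
        start = i * spacing
        rows.append(
            {"feature_id": g, "gene_id": g, "chrom": "chr1", "start": start,
             "end": start + gene_len, "strand": "+" if i % 2 == 0 else "-",
             "feature_class": "gene"}
        )
    annotation = pd.DataFrame(rows)

    as_genes = [g for g in genes if classes[g].name.startswith("allele_specific")]
    plan = []
    hosts = as_genes + [g for g in genes if g not in as_genes]
    hi = 0.5 + cfg.dmr_magnitude / 2
    lo = 0.5 - cfg.dmr_magnitude / 2
    for k in range(cfg.n_planted_dmrs):
        host = annotation[annotation["gene_id"] == hosts[k % len(hosts)]].iloc[0]
        start = int(host["start"]) - 1500
        if start < 0:
            start = int(host["end"]) + 500
        plan.append(PlantedDMR("chr1", start, start + 900, "CG", hi, lo))

    config = TruthConfig(
        seed=cfg.seed,
        gene_classes=classes,
        strains=cfg.strains,
        crosses=default_crosses(cfg.strains, "endosperm", cfg.n_replicates),
        depth_mean=cfg.depth_mean,
        chrom_length=chrom_length,
        methylome_plan=plan,
        n_population_strains=cfg.n_population_strains,
    )
    return config, annotation


def _file_digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages; returns the manifest (also written to manifest.json)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": cfg.seed, "stages": {},
                "thresholds": {"alpha": cfg.imprinting.alpha,
                               "dmr_q": cfg.dmr_q_threshold}}

    def record(stage: str, df: pd.DataFrame, path: Path):
        manifest["stages"][stage] = {
            "records": int(len(df)), "file": path.name, "sha256": _file_digest(path),
        }

    try:
        truth_config, annotation = build_truth_config(cfg)
        counts, truth = simulate_allele_counts(truth_config)
        expression = make_expression_table(truth_config)
        write_tsv(counts, out / "allele_counts.tsv")
        write_tsv(truth, out / "gene_truth.tsv")
        write_tsv(expression.reset_index(), out / "expression.tsv")
        record("simulate_counts", counts, out / "allele_counts.tsv")
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-tagged for the caller
        raise PipelineError("simulate_counts", str(exc)) from exc

    try:
        calls = call_imprinting(counts, expression, "endosperm", cfg.imprinting)
        write_tsv(calls, out / "imprinting_calls.tsv")
        record("call_imprinting", calls, out / "imprinting_calls.tsv")
    except Exception as exc:
        raise PipelineError("call_imprinting", str(exc)) from exc

    try:
        patterns = detect_allele_specific(counts, calls, expression)
        write_tsv(patterns, out / "allele_specific_patterns.tsv")
        record("allele_specific", patterns, out / "allele_specific_patterns.tsv")
    except Exception as exc:
        raise PipelineError("allele_specific", str(exc)) from exc

    try:
        samples, dmr_truth = simulate_methylome_pair(truth_config, annotation)
        names = list(samples)
        windows = compare_windows(
            samples[names[0]], samples[names[1]], "CG", q_threshold=cfg.dmr_q_threshold
        )
        dmrs = merge_dmrs(windows)
        write_tsv(windows, out / "dmr_windows.tsv")
        write_tsv(dmrs, out / "dmrs_merged.tsv")
        if not dmrs.empty:
            write_dmr_bed(dmrs, out / "dmrs_merged.bed")
        record("call_dmrs", dmrs, out / "dmrs_merged.tsv")
    except Exception as exc:
        raise PipelineError("call_dmrs", str(exc)) from exc

    try:
        # planted population classes: DMRs matching a planted interval get
        # strongly_bimodal scores, background calls (if any) very_low
        plans = []
        for d in dmrs.itertuples():
            planted = not dmr_truth.empty and bool(
                ((dmr_truth["start"] < d.end) & (dmr_truth["end"] > d.start)).any()
            )
            plans.append(
                PopulationPlan(d.dmr_id, "strongly_bimodal" if planted else "very_low")
            )
        truth_config.population_plan = plans
        matrix, pop_truth = simulate_population_matrix(truth_config)
        classes_df, summary = classify_matrix(matrix)
        write_tsv(matrix.reset_index(), out / "population_matrix.tsv")
        write_tsv(classes_df, out / "variability_classes.tsv")
        record("classify_variability", classes_df, out / "variability_classes.tsv")
    except Exception as exc:
        raise PipelineError("classify_variability", str(exc)) from exc

    try:
        assoc = associate_genes_dmrs(annotation, dmrs) if not dmrs.empty else pd.DataFrame(
            columns=["gene_id", "dmr_id", "relation", "distance"]
        )
        write_tsv(assoc, out / "gene_dmr_associations.tsv")
        joined = (
            patterns.merge(assoc, on="gene_id", how="inner")
            .merge(classes_df[["dmr_id", "variability_class"]], on="dmr_id", how="left")
            if not patterns.empty
            else pd.DataFrame(columns=["gene_id", "dmr_id", "variability_class"])
        )
        write_tsv(joined, out / "allele_specific_dmr_join.tsv")
        record("associate", assoc, out / "gene_dmr_associations.tsv")

        megs = set(calls.loc[calls["status"] == "MEG", "gene_id"])
        assessable = set(calls.loc[calls["status"] != "not_assessable", "gene_id"])
        flagged = set(assoc["gene_id"])
        if megs and assessable:
            enr = enrichment_test(megs, flagged, assessable)
            manifest["enrichment"] = {
                "pvalue": enr["pvalue"], "fold": enr["fold"], "table": enr["table"],
            }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("associate", str(exc)) from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %d stages", len(manifest["stages"]))
    return manifest
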