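"""End-to-end pipeline: events -> quantify -> test -> features -> link.

All interchange is TSV/JSON so intermediate results are inspectable and
diffable; a MANIFEST.json records the config echo, seed, package version
and a checksum per output file. Stages can be run individually through
the CLI and compose to the same outputs as a single ``run``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .events import build_all_events, write_event_catalog, write_ri_bed
from .expression import (
    gene_log2fc,
    mw_link_test,
    partition_genes,
    read_gene_counts,
)
from .features import GenomeSequence, compute_features, ks_compare, select_background
from .gtf import parse_gtf, write_gtf
from .quantify import (
    apply_coverage_filter,
    build_inclusion_table,
    read_counts,
    read_inclusion_table,
    write_counts,
    write_inclusion_table,
)
from .rankprod import Contrast, summarize_results, analyze_contrast
from .simulate import (
    SimConfig,
    affected_gene_set,
    sample_sheet,
    simulate_annotation,
    simulate_counts,
    simulate_gene_counts,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Paths, thresholds and test parameters for one analysis run."""

    annotation: str = ""
    genome: str = ""
    counts: str = ""
    gene_counts: str = ""
    sample_sheet: str = ""
    out_dir: str = "splicerank_out"
    group_a: str = "A"
    group_b: str = "B"
    p_max: float = 0.001
    fdr_max: float = 0.05
    delta_min: float = 0.1
    background_delta_max: float = 0.05
    background_p_min: float = 0.05
    min_overhang: int = 8
    min_coverage: float = 10
    min_mapq: int = 10
    n_perm: int = 100
    null_model: str = "ranks"
    seed: int = 0
    features: list = field(default_factory=list)  # empty = full registry

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"sample_id", "group"} - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns {sorted(missing)}")
    return sheet


def _groups(sheet: pd.DataFrame) -> dict[str, list[str]]:
    return {g: list(sub["sample_id"]) for g, sub in sheet.groupby("group", sort=True)}


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def write_fasta(genome: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def simulate_dataset(config: SimConfig, out_dir) -> dict[str, Path]:
    """Emit a complete synthetic dataset (annotation, genome, counts,
    gene counts, sample sheet, truth table, provenance echo)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    sim = simulate_annotation(config, rng)
    events = build_all_events(sim.models)
    counts, truth = simulate_counts(events, sim, config, rng)
    genes = sorted({m.gene_id for m in sim.models})
    gene_counts = simulate_gene_counts(genes, affected_gene_set(sim), config, rng)

    paths = {
        "annotation": out / "annotation.gtf",
        "genome": out / "genome.fa",
        "counts": out / "counts.tsv",
        "gene_counts": out / "gene_counts.tsv",
        "sample_sheet": out / "samples.tsv",
        "truth": out / "truth.tsv",
        "provenance": out / "provenance.json",
    }
    write_gtf(sim.models, paths["annotation"])
    write_fasta(sim.genome, paths["genome"])
    write_counts(counts, paths["counts"])
    gene_counts.to_csv(paths["gene_counts"], sep="\t")
    sample_sheet(config).to_csv(paths["sample_sheet"], sep="\t", index=False)
    truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.8g")
    _write_json({"config": json.loads(config.to_json()), "version": __version__},
                paths["provenance"])
    return paths


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the summary dictionary.

    Outputs: catalog.tsv, ri.bed, inclusion.tsv, results.tsv,
    features_retained.tsv / features_background.tsv, ks_report.tsv,
    gene_log2fc.tsv, gene_assignment.tsv, link_test.json, summary.json
    and MANIFEST.json. Any stage failure raises :class:`StageError`; a
    MANIFEST marking the completed stages is still written.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    completed: list[str] = []
    outputs: dict[str, Path] = {}
    summary: dict = {"config": config.to_dict(), "version": __version__}

    def finish_stage(stage: str, files: dict[str, Path]) -> None:
        completed.append(stage)
        outputs.update(files)

    try:
        stage = "build-events"
        models = parse_gtf(config.annotation)
        events = build_all_events(models)
        catalog_path = out / "catalog.tsv"
        bed_path = out / "ri.bed"
        write_event_catalog(events, catalog_path)
        write_ri_bed(events, bed_path)
        finish_stage(stage, {"catalog": catalog_path, "ri_bed": bed_path})

        stage = "quantify"
        sheet = read_sample_sheet(config.sample_sheet)
        groups = _groups(sheet)
        for g in (config.group_a, config.group_b):
            if g not in groups:
                raise ValueError(f"group {g!r} absent from sample sheet")
        counts = read_counts(config.counts)
        table = build_inclusion_table(counts, events)
        table = apply_coverage_filter(table, groups, min_coverage=config.min_coverage)
        incl_path = out / "inclusion.tsv"
        write_inclusion_table(table, incl_path)
        # re-read so staged and single-shot runs are byte-identical
        table = read_inclusion_table(incl_path)
        finish_stage(stage, {"inclusion": incl_path})

        stage = "test"
        contrast = Contrast(groups[config.group_a], groups[config.group_b])
        results = analyze_contrast(
            table[table["passed_filter"]],
            contrast,
            n_perm=config.n_perm,
            seed=config.seed,
            null_model=config.null_model,
            p_max=config.p_max,
            fdr_max=config.fdr_max,
            delta_min=config.delta_min,
        )
        results_path = out / "results.tsv"
        results.to_csv(results_path, sep="\t", index=False, float_format="%.8g")
        results = pd.read_csv(results_path, sep="\t", dtype={"event_id": str})
        summary["significant"] = summarize_results(results)
        finish_stage(stage, {"results": results_path})

        stage = "features"
        feature_files = {}
        try:
            retained_ids, background_ids = select_background(
                results,
                delta_max=config.background_delta_max,
                p_min=config.background_p_min,
            )
        except ValueError as exc:
            logger.warning("feature stage skipped: %s", exc)
            retained_ids = []
        if retained_ids:
            import pyfaidx

            genome = GenomeSequence(pyfaidx.Fasta(config.genome))
            by_id = {e.event_id: e for e in events}
            registry = None
            if config.features:
                from .features import FEATURE_REGISTRY

                registry = {k: FEATURE_REGISTRY[k] for k in config.features}
            ret_df = compute_features(
                [by_id[i].core for i in retained_ids], genome, models, registry
            )
            bg_df = compute_features(
                [by_id[i].core for i in background_ids], genome, models, registry
            )
            report = ks_compare(ret_df, bg_df)
            feature_files = {
                "features_retained": out / "features_retained.tsv",
                "features_background": out / "features_background.tsv",
                "ks_report": out / "ks_report.tsv",
            }
            ret_df.to_csv(feature_files["features_retained"], sep="\t",
                          float_format="%.8g")
            bg_df.to_csv(feature_files["features_background"], sep="\t",
                         float_format="%.8g")
            report.to_csv(feature_files["ks_report"], sep="\t", index=False,
                          float_format="%.8g")
            summary["top_feature"] = report.iloc[0]["feature"] if len(report) else None
        finish_stage(stage, feature_files)

        stage = "link"
        link_files = {}
        if config.gene_counts:
            gene_counts = read_gene_counts(config.gene_counts)
            records = gene_log2fc(
                gene_counts, groups[config.group_a], groups[config.group_b]
            )
            ir_genes, background_genes = partition_genes(results, events, records)
            if ir_genes and background_genes:
                link = mw_link_test(records, ir_genes, background_genes)
                summary["link_test"] = link.to_dict()
                assignment = pd.DataFrame(
                    {
                        "gene_id": list(records.index),
                        "set": [
                            "ir"
                            if g in set(ir_genes)
                            else ("background" if g in set(background_genes) else "excluded")
                            for g in records.index
                        ],
                        "log2fc": records["log2fc"].to_numpy(),
                    }
                ).sort_values("gene_id", ignore_index=True)
                link_files = {
                    "gene_log2fc": out / "gene_log2fc.tsv",
                    "gene_assignment": out / "gene_assignment.tsv",
                    "link_test": out / "link_test.json",
                }
                records.to_csv(link_files["gene_log2fc"], sep="\t",
                               float_format="%.8g")
                assignment.to_csv(link_files["gene_assignment"], sep="\t",
                                  index=False, float_format="%.8g")
                _write_json(link.to_dict(), link_files["link_test"])
            else:
                logger.warning("link stage skipped: empty gene set")
        finish_stage(stage, link_files)
    except Exception as exc:
        manifest = {
            "completed_stages": completed,
            "incomplete": True,
            "failed_stage": stage,
            "files": {k: _checksum(v) for k, v in sorted(outputs.items())},
        }
        _write_json(manifest, out / "MANIFEST.json")
        raise StageError(stage, str(exc)) from exc

    summary_path = out / "summary.json"
    _write_json(summary, summary_path)
    outputs["summary"] = summary_path
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "completed_stages": completed,
        "incomplete": False,
        "files": {k: _checksum(v) for k, v in sorted(outputs.items())},
    }
    _write_json(manifest, out / "MANIFEST.json")
    return summary
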