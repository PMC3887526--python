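"""End-to-end pipeline orchestration with a flat-key config and run report.

Stages: simulate -> (reads -> demux) -> counts -> test -> variance ->
enrich -> design-eval. Every output file carries a header with the tool
version, a hash of the configuration, and the seed; the run report records
per-stage record counts so conservation across stages is auditable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import DesignSpec
from .counts import (
    collapse_tags,
    collapse_tags_and_technical,
    filter_low_count,
    remove_control,
    tag_divergence_report,
)
from .demux import demultiplex
from .design_eval import make_fraction_grid, run_design_evaluation
from .diffabund import NBExactModel
from .enrich import filter_gene_sets, read_gmt, wilcoxon_enrichment
from .simulate import ReadSimParams, SimParams, simulate_experiment, simulate_reads
from .variance import partition_variance, preprocess_for_variance


@dataclass
class RunConfig:
    """Flat configuration for a pipeline run (YAML round-trippable)."""

    out_dir: str = "barseq_run"
    seed: int = 0
    # simulate
    n_mutants: int = 4295
    dispersion: float = 0.1
    frac_affected: float = 0.1
    effect_sdlog2: float = 1.0
    tag_dropout_prob: float = 0.13
    depth_per_sample: float = 1e6
    design: str = "2x4x2"
    simulate_reads_flag: bool = False
    per_base_error: float = 0.001
    # inputs (used instead of simulation when given)
    reads_path: str | None = None
    catalog_path: str | None = None
    samplesheet_path: str | None = None
    gene_sets_path: str | None = None
    # analysis constants
    max_barcode_dist: int = 2
    max_index_dist: int = 1
    min_total: int = 100
    control_ids: tuple = ()
    bottom_filter: float = 0.10
    prior_df: float = 10.0
    fdr: float = 0.05
    # design evaluation
    run_design_eval: bool = False
    eval_designs: tuple = ("2x4x2", "2x4x1", "2x3x2", "2x3x1", "2x2x2", "2x2x1")
    grid_step: float = 0.0025
    spline_df: int = 20
    spline_df_gene_sets: int = 15
    max_combinations: int | None = None

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("control_ids", "eval_designs"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order; returns the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = [
        f"barseqtools {__version__}",
        f"config {config.config_hash()}",
        f"seed {config.seed}",
    ]
    report: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }

    for path_attr in ("reads_path", "catalog_path", "samplesheet_path", "gene_sets_path"):
        p = getattr(config, path_attr)
        if p is not None and not Path(p).exists():
            raise StageError("inputs", f"missing input file: {p}")

    # -- simulate -------------------------------------------------------
    design = DesignSpec.parse(config.design)
    params = SimParams(
        n_mutants=config.n_mutants,
        dispersion=config.dispersion,
        frac_affected=config.frac_affected,
        effect_sdlog2=config.effect_sdlog2,
        tag_dropout_prob=config.tag_dropout_prob,
        control_id=config.control_ids[0] if config.control_ids else None,
        seed=config.seed,
    )
    catalog, sheet, effects, matrix = simulate_experiment(
        params, design, config.depth_per_sample
    )
    catalog.to_tsv(out / "catalog.tsv", header)
    sheet.to_tsv(out / "samplesheet.tsv", header)
    eff_frame = effects.to_frame().reset_index()
    _write(eff_frame, out / "true_effects.tsv", header)
    report["stages"]["simulate"] = {
        "n_mutants": params.n_mutants,
        "n_samples": len(sheet),
        "total_counts": matrix.grand_total,
    }

    # -- reads + demux (optional round trip through FASTQ) ---------------
    if config.simulate_reads_flag:
        rp = ReadSimParams(per_base_error=config.per_base_error)
        fastq = out / "reads.fastq"
        simulate_reads(matrix, catalog, sheet, rp, seed=config.seed + 7, path=fastq)
        matrix, stats = demultiplex(
            fastq, sheet, catalog,
            max_barcode_dist=config.max_barcode_dist,
            max_index_dist=config.max_index_dist,
        )
        _write(stats.as_series().rename_axis("category").reset_index(),
               out / "mapping_stats.tsv", header)
        report["stages"]["demux"] = {
            "reads_total": stats.n_total,
            "reads_mapped": stats.n_mapped,
            "reads_unassigned": stats.n_unassigned,
        }

    matrix.to_tsv(out / "counts_raw.tsv", header)

    # -- counts -----------------------------------------------------------
    filtered, removed = filter_low_count(matrix, config.min_total)
    if config.control_ids:
        filtered = remove_control(filtered, list(config.control_ids))
    div_table, div_summary = tag_divergence_report(filtered)
    _write(div_table.reset_index(), out / "tag_divergence.tsv", header)
    collapsed = collapse_tags_and_technical(filtered)
    collapsed.to_tsv(out / "counts_collapsed.tsv", header)
    report["stages"]["counts"] = {
        "rows_in": int(matrix.counts.shape[0]),
        "rows_removed_low_count": len(removed),
        "mutants_out": int(collapsed.counts.shape[0]),
        "total_in": matrix.grand_total,
        "total_after_filters": filtered.grand_total,
        "total_collapsed": collapsed.grand_total,
        "tag_divergence": {k: int(v) for k, v in div_summary.items()},
    }
    if collapsed.grand_total != filtered.grand_total:
        raise StageError("counts", "collapse failed to conserve the grand total")

    # -- differential test -----------------------------------------------
    res = NBExactModel(collapsed, groups="treatment").fit(prior_df=config.prior_df)
    _write(res.table.reset_index(), out / "test_results.tsv", header)
    n_sig = len(res.significant(config.fdr))
    report["stages"]["test"] = {
        "mutants_tested": len(res.table),
        "common_dispersion": res.dispersion_common,
        "n_significant": n_sig,
    }

    # -- variance ----------------------------------------------------------
    tag_summed = collapse_tags(filtered)
    x = preprocess_for_variance(tag_summed, config.bottom_filter)
    vd = partition_variance(x, tag_summed.samples)
    _write(vd.as_series().rename_axis("component").reset_index(),
           out / "variance_components.tsv", header)
    report["stages"]["variance"] = {
        k: float(v) for k, v in vd.as_series().items()
    }

    # -- enrichment ---------------------------------------------------------
    if config.gene_sets_path:
        sets = read_gmt(config.gene_sets_path)
        usable = filter_gene_sets(sets, set(res.table.index))
        enr = wilcoxon_enrichment(res.table["logFC"], usable, fdr=config.fdr)
        _write(enr.reset_index(), out / "enrichment.tsv", header)
        report["stages"]["enrich"] = {
            "sets_tested": len(enr),
            "sets_significant": int(enr["significant"].sum()) if len(enr) else 0,
        }

    # -- design evaluation ---------------------------------------------------
    if config.run_design_eval:
        grid = make_fraction_grid(config.grid_step)
        gene_sets = read_gmt(config.gene_sets_path) if config.gene_sets_path else None
        ev = run_design_evaluation(
            filtered,
            list(config.eval_designs),
            grid=grid,
            seed=config.seed,
            gene_sets=gene_sets,
            fdr=config.fdr,
            spline_df=config.spline_df,
            spline_df_gene_sets=config.spline_df_gene_sets,
            max_combinations=config.max_combinations,
        )
        _write(ev.points, out / "design_eval_points.tsv", header)
        _write(ev.curves, out / "design_eval_curves.tsv", header)
        report["stages"]["design_eval"] = {
            "designs": list(config.eval_designs),
            "n_points": len(ev.points),
        }

    config.to_yaml(out / "config.yaml")
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _write(df: pd.DataFrame, path: Path, header: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
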