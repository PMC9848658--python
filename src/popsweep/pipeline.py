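"""End-to-end orchestration: simulate → filter → stats → sweeps → HGT →
tree → survey, as one configured, logged, reproducible run.

Also houses the small presentation-layer arithmetic used in run reports
(round-half-up percentages and mean gene-length decomposition); internal
values are kept at full precision and rounded only when reported.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import yaml

from . import hgt as hgt_mod
from . import simulate as sim
from . import survey as survey_mod
from . import sweeps as sweeps_mod
from . import trees as trees_mod
from .popgen import make_windows, window_stats
from .variants import FilterConfig, filter_snps, read_vcf
from .sweeps import ScanConfig

logger = logging.getLogger(__name__)


def percentage(numerator: int, denominator: int, decimals: int = 2) -> float:
    """Round-half-up percentage 100·numerator/denominator."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    frac = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    q = Decimal(1).scaleb(-decimals)
    return float(frac.quantize(q, rounding=ROUND_HALF_UP))


def mean_length_decomposition(mean_cds: float, mean_intron: float) -> float:
    """Mean gene span as the sum of its coding and intron components."""
    return mean_cds + mean_intron


@dataclass
class PipelineConfig:
    """One file's worth of knobs for a full demonstration run."""

    seed: int = 1
    out_dir: str = "popsweep_run"
    # stage toggles
    run_panel: bool = True
    run_sweep_scan: bool = True
    run_hgt: bool = True
    run_tree: bool = True
    run_survey: bool = True
    # panel / scan
    panel: dict = field(default_factory=dict)
    filter: dict = field(default_factory=dict)
    window_size: int = 50_000
    window_step: int | None = None
    n_sweeps: int = 2
    # hit table
    n_genes: int = 1_000
    n_hgt: int = 3
    donor_group: str = "virus"
    bit_separation: float = 100.0
    # survey
    survey_genome_size: int = 100_000
    survey_depth: float = 30.0
    survey_read_length: int = 100

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def write_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def run(config: PipelineConfig) -> dict:
    """Execute the configured stages and write all artifacts.

    Returns the run report (also written as ``report.json``): per-stage
    record counts, filter survivors, selected-bin counts at the 1% and 5%
    tails, HGT candidate counts and the genome-size estimate.  Deterministic
    given ``config.seed``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.write_yaml(out / "effective_config.yaml")
    report: dict = {"seed": config.seed}

    if config.run_panel:
        panel_kwargs = dict(config.panel)
        panel_kwargs.setdefault("seed", config.seed)
        cfg = sim.SimPanelConfig(**panel_kwargs)
        if config.n_sweeps and not cfg.sweep_intervals:
            size = config.window_size
            intervals = []
            for k in range(config.n_sweeps):
                start = (3 * k + 1) * size + 1
                intervals.append((cfg.chrom_names[0], start, start + size - 1,
                                  "pop2"))
            cfg = sim.SimPanelConfig(**{**panel_kwargs,
                                        "sweep_intervals": tuple(intervals)})
        sim.simulate_two_pop_panel(cfg, out_dir=out)
        table, popmap = read_vcf(out / "panel.vcf", out / "popmap.tsv")
        filt_cfg = FilterConfig(**config.filter)
        filtered, fstats = filter_snps(table, filt_cfg, return_stats=True)
        report["panel"] = {
            "n_sites_simulated": table.n_sites,
            "n_samples": table.n_samples,
            "n_sites_after_filter": filtered.n_sites,
            "n_genotypes_depth_masked": fstats.n_genotypes_masked_low_depth,
            "n_sites_dropped_call_rate": fstats.n_sites_dropped_call_rate,
            "n_sites_dropped_maf": fstats.n_sites_dropped_maf,
            "filter_survivor_percent": percentage(
                filtered.n_sites, max(table.n_sites, 1)),
        }

        if config.run_sweep_scan:
            windows = make_windows(cfg.chrom_lengths, config.window_size,
                                   config.window_step)
            stats = window_stats(filtered, popmap, windows)
            genes = sim.simulate_gene_models(
                max(config.n_genes // 10, 10), cfg.chrom_lengths,
                seed=config.seed + 1, out_path=out / "genes.gff3")
            scan_cfg = ScanConfig(window_size=config.window_size,
                                  step=config.window_step,
                                  ratio_direction=("pop1", "pop2"))
            scan_df = sweeps_mod.scan(stats, scan_cfg, genes=genes)
            scan_df.to_csv(out / "windows.tsv", sep="\t", index=False)
            for tag in ("top1", "top5"):
                sel = sweeps_mod.selected_windows(scan_df, f"combined_{tag}")
                sweeps_mod.write_bed(sel, out / f"sweeps_combined_{tag}.bed")
            report["sweep_scan"] = {
                "n_windows": len(scan_df),
                "ratio_top1_bins": int(scan_df["ratio_top1"].sum()),
                "ratio_top5_bins": int(scan_df["ratio_top5"].sum()),
                "combined_top1_bins": int(scan_df["combined_top1"].sum()),
                "combined_top5_bins": int(scan_df["combined_top5"].sum()),
                "genes_in_ratio_top5": len({
                    gid for g in scan_df.loc[scan_df["ratio_top5"], "genes"]
                    for gid in g.split(",") if gid}),
            }

        if config.run_tree:
            dm = trees_mod.genotype_distance(filtered)
            tree = trees_mod.nj_tree(dm)
            trees_mod.write_newick(tree, out / "lineages.nwk")
            report["tree"] = {
                "n_leaves": dm.shape[0],
                "bipartition_pop1_pop2": trees_mod.has_bipartition(
                    tree, set(popmap.samples_for("pop1"))),
            }

    if config.run_hgt:
        hits, truth = sim.simulate_hit_table(
            config.n_genes, config.n_hgt, config.donor_group,
            config.bit_separation, seed=config.seed + 2,
            out_path=out / "hits.tsv")
        calls, summary = hgt_mod.screen(hits)
        hgt_mod.write_screen(calls, summary, out / "hgt_calls.tsv",
                             out / "hgt_summary.json")
        called = set(summary["candidates"])
        planted = set(truth.hgt_gene_ids)
        report["hgt"] = {
            "n_genes": config.n_genes,
            "n_planted": len(planted),
            "n_called": len(called),
            "n_true_positive": len(called & planted),
        }

    if config.run_survey:
        genome, reads = sim.simulate_reads(
            config.survey_genome_size, config.survey_depth,
            config.survey_read_length, seed=config.seed + 3)
        k = survey_mod.choose_k(config.survey_genome_size)
        hist = survey_mod.kmer_histogram(reads, k)
        est = survey_mod.estimate_genome_size(hist)
        report["survey"] = {
            "k": k,
            "n_reads": len(reads),
            "peak_coverage": est.peak_coverage,
            "genome_size_estimate_bp": est.genome_size_bp,
            "true_genome_size_bp": config.survey_genome_size,
        }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
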