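"""Selective-sweep calling from window statistics.

A sweep scan ranks windows by the between-population nucleotide-diversity
ratio π_A/π_B and flags empirical upper-tail outliers ("top1" = upper 1%,
"top5" = upper 5% of the realized window distribution).  The combined
F_ST-π criterion intersects π-ratio outliers with F_ST outliers at the same
tail fraction.  Windows where the denominator population has zero diversity
are complete-fixation windows: they are excluded from the empirical
distribution used to set thresholds but always selected as outliers (their
ratio is reported as +inf).  Gene overlap reporting and gene-record
arithmetic (span, protein length) live here too.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gffutils
import numpy as np
import pandas as pd

from .popgen import Window

logger = logging.getLogger(__name__)


@dataclass
class ScanConfig:
    """Sweep-scan parameters.

    ``window_size``/``step`` default to a 50 kb non-overlapping tiling;
    ``ratio_direction`` names (numerator, denominator) populations for the
    π ratio and is echoed in all outputs.  ``min_windows_for_quantiles``
    guards against quantile estimates from too few windows (warning only).
    """

    window_size: int = 50_000
    step: int | None = None
    quantiles: tuple[float, ...] = (0.01, 0.05)
    ratio_direction: tuple[str, str] | None = None
    min_windows_for_quantiles: int = 100

    def __post_init__(self) -> None:
        for q in self.quantiles:
            if not 0.0 < q < 1.0:
                raise ValueError("quantiles must lie in (0, 1)")
        step = self.window_size if self.step is None else self.step
        if not 0 < step <= self.window_size:
            raise ValueError("require 0 < step <= window size")


@dataclass
class GeneModel:
    """A gene span with exon structure, 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    exon_count: int = 1
    cds_length: int = 0

    @property
    def length(self) -> int:
        return gene_length(self.start, self.end)


def gene_length(start: int, end: int) -> int:
    """Genomic span of a 1-based inclusive interval: end − start + 1."""
    return end - start + 1


def protein_length(cds_length: int, *, include_stop: bool = True) -> int:
    """Residues encoded by a CDS: cds/3 (``include_stop=False`` gives cds/3 − 1)."""
    if cds_length % 3 != 0:
        raise ValueError(f"CDS length {cds_length} not divisible by 3")
    n = cds_length // 3
    return n if include_stop else n - 1


def read_gff3_genes(path) -> list[GeneModel]:
    """Load gene models (gene + CDS features) from a GFF3 file."""
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    genes = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        cds_len = sum(c.end - c.start + 1 for c in db.children(g, featuretype="CDS"))
        n_exons = sum(1 for _ in db.children(g, featuretype="exon"))
        genes.append(GeneModel(
            gene_id=g.id, chrom=g.seqid, start=g.start, end=g.end,
            strand=g.strand or "+", exon_count=max(n_exons, 1),
            cds_length=cds_len,
        ))
    return genes


def pi_ratio(stats: pd.DataFrame, direction: tuple[str, str]) -> pd.Series:
    """Per-window π ratio π_numerator / π_denominator.

    Windows with zero denominator π and positive numerator π are
    complete-fixation candidates and get +inf; windows with both zero are
    undefined (NaN).  Both cases are counted to the log.
    """
    num_pop, den_pop = direction
    num = stats[f"pi_{num_pop}"].to_numpy(dtype=float)
    den = stats[f"pi_{den_pop}"].to_numpy(dtype=float)
    ratio = np.full(len(stats), np.nan)
    ok = den > 0
    ratio[ok] = num[ok] / den[ok]
    fixed = (den == 0) & (num > 0)
    ratio[fixed] = np.inf
    n_undef = int(((den == 0) & (num == 0)).sum())
    if fixed.any() or n_undef:
        logger.info("pi_ratio: %d complete-fixation windows (ratio=inf), "
                    "%d windows with zero diversity in both populations (undefined)",
                    int(fixed.sum()), n_undef)
    return pd.Series(ratio, index=stats.index, name="pi_ratio")


def empirical_outliers(values: Sequence[float] | np.ndarray, top_fraction: float
                       ) -> np.ndarray:
    """Boolean mask of empirical upper-tail outliers.

    The threshold is the k-th largest finite value with
    k = ceil(top_fraction × n_finite); all values ≥ threshold are selected,
    so ties at the threshold may expand the set beyond k.  +inf values are
    always selected but never set the threshold; NaNs are never selected.
    """
    if not 0.0 < top_fraction < 1.0:
        raise ValueError("top_fraction must lie in (0, 1)")
    vals = np.asarray(values, dtype=float)
    finite = np.isfinite(vals)
    mask = np.zeros(len(vals), dtype=bool)
    mask[np.isposinf(vals)] = True
    n = int(finite.sum())
    if n == 0:
        return mask
    k = max(1, math.ceil(top_fraction * n))
    ordered = np.sort(vals[finite])[::-1]
    threshold = ordered[k - 1]
    if ordered[0] == ordered[-1]:
        logger.warning("empirical_outliers: all %d values identical; "
                       "every window selected", n)
    mask |= finite & (vals >= threshold)
    return mask


def combined_fst_pi(ratio_mask: np.ndarray, fst_mask: np.ndarray) -> np.ndarray:
    """Combined F_ST-π selection: windows extreme in both statistics."""
    return np.asarray(ratio_mask, bool) & np.asarray(fst_mask, bool)


def genes_in_bins(genes: Sequence[GeneModel], windows: Sequence[Window]
                  ) -> tuple[list[list[str]], list[str]]:
    """Genes overlapping each window (≥1 bp, same chromosome) and their union.

    A gene spanning several windows is reported in each but counted once in
    the deduplicated union, which preserves gene order of first appearance.
    """
    per_window: list[list[str]] = []
    union: dict[str, None] = {}
    for w in windows:
        ids = [g.gene_id for g in genes
               if g.chrom == w.chrom and g.start <= w.end and g.end >= w.start]
        per_window.append(ids)
        for gid in ids:
            union.setdefault(gid, None)
    return per_window, list(union)


def scan(stats: pd.DataFrame, config: ScanConfig,
         genes: Sequence[GeneModel] | None = None) -> pd.DataFrame:
    """Full sweep scan over a window-statistics table.

    Adds the π ratio, per-quantile outlier flags for the ratio and F_ST, the
    combined F_ST-π flags, a top-5% d_XY flag, and (optionally) overlapping
    gene lists.  Flag columns are named ``ratio_top1``, ``fst_top5``,
    ``combined_top1`` etc. after the percent tail.
    """
    direction = config.ratio_direction
    if direction is None:
        pi_cols = [c for c in stats.columns if c.startswith("pi_")]
        if len(pi_cols) != 2:
            raise ValueError("cannot infer ratio direction; set ScanConfig.ratio_direction")
        direction = (pi_cols[0][3:], pi_cols[1][3:])
    out = stats.copy()
    out["pi_ratio"] = pi_ratio(stats, direction)
    out.attrs["ratio_direction"] = direction

    n_defined = int(np.isfinite(out["pi_ratio"].to_numpy()).sum())
    if n_defined < config.min_windows_for_quantiles:
        logger.warning("scan: only %d windows with a defined pi ratio; "
                       "empirical quantiles are unstable below %d",
                       n_defined, config.min_windows_for_quantiles)

    fst = out["fst"].to_numpy(dtype=float)
    for q in sorted(config.quantiles):
        tag = f"top{int(round(q * 100))}"
        ratio_mask = empirical_outliers(out["pi_ratio"].to_numpy(), q)
        fst_mask = empirical_outliers(fst, q)
        out[f"ratio_{tag}"] = ratio_mask
        out[f"fst_{tag}"] = fst_mask
        out[f"combined_{tag}"] = combined_fst_pi(ratio_mask, fst_mask)
    out["dxy_top5"] = empirical_outliers(out["dxy"].to_numpy(), 0.05)

    if genes is not None:
        windows = [Window(r.chrom, int(r.start), int(r.end))
                   for r in out.itertuples()]
        per_window, _ = genes_in_bins(genes, windows)
        out["genes"] = [",".join(ids) for ids in per_window]
    return out


def selected_windows(scan_df: pd.DataFrame, flag: str) -> list[Window]:
    """Windows carrying a given boolean flag column of a scan table."""
    sub = scan_df[scan_df[flag]]
    return [Window(r.chrom, int(r.start), int(r.end)) for r in sub.itertuples()]


def write_bed(windows: Iterable[Window], path) -> None:
    """Write windows as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f"{w.chrom}\t{w.start - 1}\t{w.end}\n")
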