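"""Reading, filtering and summarising diploid SNP panels.

The analysis substrate is a :class:`VariantTable`: biallelic SNP sites with a
per-site × per-sample alternate-allele dosage (0/1/2, or missing) and a
per-call read depth.  Tables are read from VCF together with a two-column
sample→population map, passed through the high-reliability SNP filter
(per-genotype depth support, per-site call rate and minor-allele frequency)
and reduced to per-population allele counts that feed every downstream
statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

#: dosage / depth value marking a missing call
MISSING = -1


@dataclass
class VariantTable:
    """Biallelic SNP sites with genotype dosages and per-call depths.

    Attributes
    ----------
    sites : pandas.DataFrame
        One row per site with columns ``chrom``, ``pos`` (1-based), ``ref``,
        ``alt``; positions strictly increasing within each chromosome.
    genotypes : numpy.ndarray
        ``(n_sites, n_samples)`` int8 array of alternate-allele dosages in
        {0, 1, 2}; :data:`MISSING` where the call is absent.
    depths : numpy.ndarray
        ``(n_sites, n_samples)`` int32 array of supporting read counts;
        :data:`MISSING` where the VCF carried no DP for the call.
    samples : list of str
        Column order of the genotype matrix.
    """

    sites: pd.DataFrame
    genotypes: np.ndarray
    depths: np.ndarray
    samples: list[str]

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def take(self, index: np.ndarray) -> "VariantTable":
        """Row-subset the table, preserving site order."""
        return VariantTable(
            sites=self.sites.iloc[index].reset_index(drop=True),
            genotypes=self.genotypes[index],
            depths=self.depths[index],
            samples=list(self.samples),
        )

    def validate(self) -> None:
        if self.genotypes.shape != (self.n_sites, self.n_samples):
            raise ValueError("genotype matrix shape does not match sites/samples")
        if self.depths.shape != self.genotypes.shape:
            raise ValueError("depth matrix shape does not match genotype matrix")
        for _, grp in self.sites.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("positions not strictly increasing within chromosome")
        g = self.genotypes
        if np.any((g < MISSING) | (g > 2)):
            raise ValueError("genotype dosages must be in {0,1,2} or missing")


@dataclass
class PopulationMap:
    """Sample → population assignment."""

    assignments: Mapping[str, str]

    @property
    def populations(self) -> list[str]:
        """Population labels in first-appearance order."""
        seen: dict[str, None] = {}
        for pop in self.assignments.values():
            seen.setdefault(pop, None)
        return list(seen)

    def samples_for(self, population: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == population]

    @classmethod
    def read_tsv(cls, path) -> "PopulationMap":
        df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"],
                         dtype=str, comment="#")
        return cls(assignments=dict(zip(df["sample"], df["population"])))

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for sample, pop in self.assignments.items():
                fh.write(f"{sample}\t{pop}\n")


@dataclass
class FilterConfig:
    """High-reliability SNP filter thresholds.

    ``min_support`` masks individual genotype calls backed by fewer reads;
    ``min_maf`` and ``min_call_rate`` then drop whole sites.  Defaults follow
    common resequencing practice for low-coverage panels: calls need at least
    4 supporting reads, sites need a minor-allele frequency of at least 0.05
    among called alleles and a genotype in at least half the samples.
    """

    min_support: int = 4
    min_maf: float = 0.05
    min_call_rate: float = 0.5

    def __post_init__(self) -> None:
        if self.min_support < 0:
            raise ValueError("min_support must be >= 0")
        if not 0.0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must be in [0, 0.5]")
        if not 0.0 < self.min_call_rate <= 1.0:
            raise ValueError("min_call_rate must be in (0, 1]")


@dataclass
class FilterStats:
    """Per-step bookkeeping for :func:`filter_snps`."""

    n_input_sites: int = 0
    n_genotypes_masked_low_depth: int = 0
    n_sites_dropped_call_rate: int = 0
    n_sites_dropped_maf: int = 0
    n_output_sites: int = 0


def read_vcf(vcf_path, popmap_path=None, *, missing_depth_passes: bool = True
             ) -> tuple[VariantTable, PopulationMap | None]:
    """Load a VCF (GT, optionally DP per call) into a :class:`VariantTable`.

    Multi-allelic and non-SNP records are dropped and counted.  When
    ``missing_depth_passes`` is true (default) absent DP values are stored as
    :data:`MISSING` and treated as sufficient support by the depth filter.

    Raises
    ------
    ValueError
        If ``popmap_path`` is given and any VCF sample is unassigned.
    """
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)

    popmap = None
    if popmap_path is not None:
        popmap = PopulationMap.read_tsv(popmap_path)
        unassigned = [s for s in samples if s not in popmap.assignments]
        if unassigned:
            raise ValueError(
                "VCF samples missing from population map: " + ", ".join(unassigned)
            )

    chroms, poss, refs, alts = [], [], [], []
    gt_rows, dp_rows = [], []
    n_dropped = 0
    bases = {"A", "C", "G", "T"}
    for v in vcf:
        if len(v.ALT) != 1 or v.REF not in bases or v.ALT[0] not in bases:
            n_dropped += 1
            continue
        row = np.full(len(samples), MISSING, dtype=np.int8)
        for j, call in enumerate(v.genotypes):
            a, b = call[0], call[1]
            if a >= 0 and b >= 0:
                row[j] = a + b
        try:
            dp = v.format("DP")
        except KeyError:  # DP absent from the header entirely
            dp = None
        if dp is None:
            dp_row = np.full(len(samples), MISSING, dtype=np.int32)
        else:
            dp_row = dp.astype(np.int32).reshape(-1)
            dp_row[dp_row < 0] = MISSING
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        gt_rows.append(row)
        dp_rows.append(dp_row)
    if n_dropped:
        logger.info("read_vcf: dropped %d multi-allelic/non-SNP records", n_dropped)

    sites = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    genotypes = (np.vstack(gt_rows) if gt_rows
                 else np.empty((0, len(samples)), dtype=np.int8))
    depths = (np.vstack(dp_rows) if dp_rows
              else np.empty((0, len(samples)), dtype=np.int32))
    table = VariantTable(sites=sites, genotypes=genotypes, depths=depths,
                         samples=samples)
    table._missing_depth_passes = missing_depth_passes  # type: ignore[attr-defined]
    return table, popmap


def write_vcf(table: VariantTable, path, *, contig_lengths: Mapping[str, int] | None = None
              ) -> None:
    """Write a :class:`VariantTable` as VCF v4.2 with GT:DP per call."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=popsweep\n")
        if contig_lengths:
            for chrom, length in contig_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        else:
            for chrom in dict.fromkeys(table.sites["chrom"]):
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.samples) + "\n")
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for i in range(table.n_sites):
            row = table.sites.iloc[i]
            calls = []
            for j in range(table.n_samples):
                g = gt_str[int(table.genotypes[i, j])]
                d = int(table.depths[i, j])
                calls.append(f"{g}:{d if d >= 0 else '.'}")
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\t"
                     "GT:DP\t" + "\t".join(calls) + "\n")


def filter_snps(table: VariantTable, cfg: FilterConfig | None = None,
                *, return_stats: bool = False):
    """Apply the high-reliability SNP filter.

    Step 1 masks genotypes whose supporting read depth is below
    ``cfg.min_support`` (depths recorded as missing pass when the table was
    read with ``missing_depth_passes``).  Step 2 keeps sites whose call rate
    over all samples is at least ``cfg.min_call_rate`` and whose minor-allele
    frequency over *called* alleles is at least ``cfg.min_maf``.  Site order
    is preserved and the operation is idempotent.
    """
    cfg = cfg or FilterConfig()
    stats = FilterStats(n_input_sites=table.n_sites)
    missing_passes = getattr(table, "_missing_depth_passes", True)

    geno = table.genotypes.copy()
    known_depth = table.depths >= 0
    low = known_depth & (table.depths < cfg.min_support)
    if not missing_passes:
        low = low | ~known_depth
    newly_masked = low & (geno != MISSING)
    stats.n_genotypes_masked_low_depth = int(newly_masked.sum())
    geno[newly_masked] = MISSING

    called = geno != MISSING
    n_called = called.sum(axis=1)
    call_rate = (n_called / table.n_samples if table.n_samples
                 else np.zeros(table.n_sites))
    with np.errstate(divide="ignore", invalid="ignore"):
        alt = np.where(called, geno, 0).sum(axis=1)
        p = np.where(n_called > 0, alt / (2.0 * np.maximum(n_called, 1)), np.nan)
    maf = np.minimum(p, 1.0 - p)

    pass_rate = call_rate >= cfg.min_call_rate
    pass_maf = ~np.isnan(maf) & (maf >= cfg.min_maf)
    stats.n_sites_dropped_call_rate = int((~pass_rate).sum())
    stats.n_sites_dropped_maf = int((pass_rate & ~pass_maf).sum())
    keep = np.flatnonzero(pass_rate & pass_maf)
    stats.n_output_sites = len(keep)
    logger.info(
        "filter_snps: %d sites in, %d genotypes depth-masked, %d dropped by "
        "call rate, %d by MAF, %d sites out",
        stats.n_input_sites, stats.n_genotypes_masked_low_depth,
        stats.n_sites_dropped_call_rate, stats.n_sites_dropped_maf,
        stats.n_output_sites,
    )

    out = VariantTable(
        sites=table.sites.iloc[keep].reset_index(drop=True),
        genotypes=geno[keep],
        depths=table.depths[keep],
        samples=list(table.samples),
    )
    out._missing_depth_passes = missing_passes  # type: ignore[attr-defined]
    if return_stats:
        return out, stats
    return out


@dataclass
class SiteAlleleCounts:
    """Per-population called-allele summaries at every site.

    For population *i* at each site: ``n`` called alleles (2 × called
    individuals), ``alt`` alternate-allele count, ``het`` heterozygous
    individuals and ``n_ind`` called individuals.  These carry the
    per-population allele frequency p_i = alt/n and observed heterozygosity
    h_i = het/n_ind used by all divergence statistics.
    """

    populations: list[str]
    n: dict[str, np.ndarray] = field(default_factory=dict)
    alt: dict[str, np.ndarray] = field(default_factory=dict)
    het: dict[str, np.ndarray] = field(default_factory=dict)
    n_ind: dict[str, np.ndarray] = field(default_factory=dict)


def allele_counts(table: VariantTable, popmap: PopulationMap) -> SiteAlleleCounts:
    """Collapse genotypes to per-population allele counts per site."""
    pops = popmap.populations
    out = SiteAlleleCounts(populations=pops)
    sample_index = {s: j for j, s in enumerate(table.samples)}
    for pop in pops:
        idx = [sample_index[s] for s in popmap.samples_for(pop)
               if s in sample_index]
        g = table.genotypes[:, idx]
        called = g != MISSING
        n_ind = called.sum(axis=1)
        out.n_ind[pop] = n_ind.astype(np.int64)
        out.n[pop] = (2 * n_ind).astype(np.int64)
        out.alt[pop] = np.where(called, g, 0).sum(axis=1).astype(np.int64)
        out.het[pop] = (g == 1).sum(axis=1).astype(np.int64)
    return out
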