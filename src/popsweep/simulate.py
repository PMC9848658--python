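"""Synthetic inputs with full ground truth for every pipeline stage.

The panel generator draws a two-population diploid SNP panel from the
Balding–Nichols model: each site has an ancestral allele frequency p, each
population's frequency is Beta-distributed with mean p and variance
p(1−p)·F, so the expected differentiation between the populations is the
single dial F.  Planted sweep intervals replace the target population's
frequency with a Bernoulli(p) fixation draw, collapsing within-interval
diversity toward zero.  Companion generators emit proteome-scale homology
hit tables with planted HGT genes, non-overlapping gene models,
GC-controlled sequences and error-free reads; every planted feature is
recorded in a :class:`TruthRecord` so recovery can be asserted exactly.

All generators are deterministic given their seed: identical seeds give
byte-identical output files within one package version.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .hgt import GROUPS
from .sweeps import GeneModel
from .variants import MISSING, PopulationMap, VariantTable, write_vcf

logger = logging.getLogger(__name__)


@dataclass
class SimPanelConfig:
    """Parameters of the two-population panel generator.

    Defaults mirror a small resequencing study: 15 + 13 diploid samples,
    a between-population F of 0.25, site depths around 8× and an ancestral
    minor-allele-frequency spectrum uniform on (0.05, 0.5).
    ``sweep_intervals`` is a list of (chrom, start, end, target_pop) tuples
    whose sites are driven to fixation in the target population.
    """

    seed: int
    n_pop1: int = 15
    n_pop2: int = 13
    n_chrom: int = 1
    chrom_length: int = 1_000_000
    n_sites: int = 5_000
    divergence_F: float = 0.25
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    sweep_intervals: tuple[tuple[str, int, int, str], ...] = ()
    mean_depth: float = 8.0
    missing_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.n_pop1 < 2 or self.n_pop2 < 2:
            raise ValueError("each population needs at least 2 samples")
        if not 0.0 < self.divergence_F < 1.0:
            raise ValueError("divergence_F must lie in (0, 1)")
        if self.chrom_length < self.n_sites:
            raise ValueError("chromosome shorter than the requested site count")
        if self.chrom_length <= 0:
            raise ValueError("zero-length chromosomes are not allowed")
        lo, hi = self.ancestral_maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError("ancestral_maf_range must lie in (0, 0.5]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        chroms = self.chrom_names
        for chrom, start, end, pop in self.sweep_intervals:
            if chrom not in chroms:
                raise ValueError(f"sweep interval on unknown chromosome {chrom!r}")
            if not 1 <= start <= end <= self.chrom_length:
                raise ValueError(
                    f"sweep interval {chrom}:{start}-{end} outside chromosome bounds")
            if pop not in ("pop1", "pop2"):
                raise ValueError(f"sweep target {pop!r} must be 'pop1' or 'pop2'")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names}


@dataclass
class TruthRecord:
    """Ground truth for a simulated data set; JSON round-trip is lossless."""

    seed: int
    divergence_F: float | None = None
    sweep_windows: list[list] = field(default_factory=list)
    hgt_gene_ids: list[str] = field(default_factory=list)
    genome_size_bp: int | None = None

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def read_json(cls, path) -> "TruthRecord":
        with open(path) as fh:
            return cls(**json.load(fh))


_BASES = np.array(list("ACGT"))


def simulate_two_pop_panel(config: SimPanelConfig, out_dir=None
                           ) -> tuple[VariantTable, PopulationMap, TruthRecord]:
    """Draw a Balding–Nichols two-population diploid SNP panel.

    Per site: ancestral frequency p uniform over the configured MAF range
    (folded to 1−p with probability 1/2); population frequencies
    Beta(p(1−F)/F, (1−p)(1−F)/F); genotypes Binomial(2, p_k); per-call
    depths Poisson(mean_depth); genotypes masked missing at
    ``missing_rate``.  Sites inside a sweep interval have the target
    population's frequency replaced by a Bernoulli(p) fixation draw.

    When ``out_dir`` is given, writes ``panel.vcf``, ``popmap.tsv`` and
    ``truth.json`` there.
    """
    rng = np.random.default_rng(config.seed)
    F = config.divergence_F
    lo, hi = config.ancestral_maf_range
    samples = ([f"pop1_s{i + 1:02d}" for i in range(config.n_pop1)]
               + [f"pop2_s{i + 1:02d}" for i in range(config.n_pop2)])
    popmap = PopulationMap(assignments={
        s: ("pop1" if s.startswith("pop1") else "pop2") for s in samples})

    all_sites = []
    geno_blocks = []
    depth_blocks = []
    for chrom in config.chrom_names:
        pos = np.sort(rng.choice(config.chrom_length, size=config.n_sites,
                                 replace=False) + 1)
        maf = rng.uniform(lo, hi, size=config.n_sites)
        flip = rng.random(config.n_sites) < 0.5
        p_anc = np.where(flip, 1.0 - maf, maf)
        shape1 = p_anc * (1.0 - F) / F
        shape2 = (1.0 - p_anc) * (1.0 - F) / F
        p_pop = {pop: rng.beta(shape1, shape2) for pop in ("pop1", "pop2")}
        for sw_chrom, start, end, target in config.sweep_intervals:
            if sw_chrom != chrom:
                continue
            in_sweep = (pos >= start) & (pos <= end)
            fix = (rng.random(int(in_sweep.sum())) < p_anc[in_sweep]).astype(float)
            p_pop[target] = p_pop[target].copy()
            p_pop[target][in_sweep] = fix
        g1 = rng.binomial(2, p_pop["pop1"][:, None],
                          size=(config.n_sites, config.n_pop1))
        g2 = rng.binomial(2, p_pop["pop2"][:, None],
                          size=(config.n_sites, config.n_pop2))
        geno = np.hstack([g1, g2]).astype(np.int8)
        depth = rng.poisson(config.mean_depth, size=geno.shape).astype(np.int32)
        if config.missing_rate > 0:
            miss = rng.random(geno.shape) < config.missing_rate
            geno[miss] = MISSING
        ref_idx = rng.integers(0, 4, size=config.n_sites)
        alt_idx = (ref_idx + rng.integers(1, 4, size=config.n_sites)) % 4
        all_sites.append(pd.DataFrame({
            "chrom": chrom, "pos": pos,
            "ref": _BASES[ref_idx], "alt": _BASES[alt_idx]}))
        geno_blocks.append(geno)
        depth_blocks.append(depth)

    table = VariantTable(
        sites=pd.concat(all_sites, ignore_index=True),
        genotypes=np.vstack(geno_blocks),
        depths=np.vstack(depth_blocks),
        samples=samples,
    )
    truth = TruthRecord(
        seed=config.seed,
        divergence_F=F,
        sweep_windows=[list(iv) for iv in config.sweep_intervals],
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_vcf(table, out / "panel.vcf", contig_lengths=config.chrom_lengths)
        popmap.write_tsv(out / "popmap.tsv")
        truth.write_json(out / "truth.json")
    return table, popmap, truth


def evalue_from_bitscore(bitscore: float, db_size: float = 1e9) -> float:
    """Karlin–Altschul-shaped link E = db_size · 2^(−bitscore)."""
    return db_size * 2.0 ** (-bitscore)


def simulate_hit_table(n_genes: int, n_hgt: int, donor_group: str = "virus",
                       bit_separation: float = 100.0, db_size: float = 1e9,
                       seed: int = 0, out_path=None
                       ) -> tuple[pd.DataFrame, TruthRecord]:
    """Generate a proteome-scale homology hit table with planted HGT genes.

    Ordinary genes have their best in-group (plant) bit score at least
    ``bit_separation`` bits above any out-group hit; planted HGT genes have
    their best ``donor_group`` bit score at least that far above any
    in-group hit (which may be absent entirely).  Each gene carries 3–20
    hits; E-values follow E = db_size·2^(−bit).
    """
    if donor_group not in GROUPS or donor_group == "plant":
        raise ValueError(f"unknown or in-group donor group {donor_group!r}")
    if n_hgt >= n_genes:
        raise ValueError("n_hgt must be smaller than n_genes")
    if bit_separation <= 0:
        raise ValueError("bit_separation must be positive")
    rng = np.random.default_rng(seed)
    outgroups = [g for g in GROUPS if g != "plant"]
    hgt_idx = set(rng.choice(n_genes, size=n_hgt, replace=False).tolist())

    lineages = {
        "plant": "Eukaryota;Viridiplantae;Streptophyta",
        "archaea": "Archaea;Euryarchaeota",
        "bacteria": "Bacteria;Proteobacteria",
        "fungi": "Eukaryota;Fungi;Ascomycota",
        "virus": "Viruses;Riboviria",
        "metazoan": "Eukaryota;Metazoa;Chordata",
        "other": "Eukaryota;Amoebozoa",
    }

    rows = []
    truth_ids = []
    for gi in range(n_genes):
        gene = f"gene{gi + 1:05d}"
        n_hits = int(rng.integers(3, 21))
        hits: list[tuple[str, float]] = []
        if gi in hgt_idx:
            truth_ids.append(gene)
            b_donor = float(rng.uniform(max(bit_separation + 80.0, 200.0), 450.0))
            hits.append((donor_group, b_donor))
            has_ingroup = rng.random() >= 0.3
            b_in = None
            if has_ingroup:
                b_in = float(rng.uniform(31.0, b_donor - bit_separation))
                hits.append(("plant", b_in))
            cap = b_in if b_in is not None else b_donor - bit_separation
            for _ in range(n_hits - len(hits)):
                grp = outgroups[int(rng.integers(len(outgroups)))]
                top = b_donor if grp == donor_group else cap
                hits.append((grp, float(rng.uniform(30.0, max(top, 31.0)))))
        else:
            b_in = float(rng.uniform(max(bit_separation + 60.0, 150.0), 420.0))
            hits.append(("plant", b_in))
            cap = b_in - bit_separation
            for _ in range(n_hits - 1):
                grp = GROUPS[int(rng.integers(len(GROUPS)))]
                top = b_in if grp == "plant" else cap
                if top <= 31.0:
                    grp, top = "plant", b_in
                hits.append((grp, float(rng.uniform(30.0, top))))
        for hj, (grp, bit) in enumerate(hits):
            bit = round(bit, 1)
            rows.append({
                "query": gene,
                "subject": f"{grp[:3]}_{gi + 1:05d}_{hj}",
                "taxon": lineages[grp],
                "bitscore": bit,
                "evalue": evalue_from_bitscore(bit, db_size),
            })
    df = pd.DataFrame(rows)
    truth = TruthRecord(seed=seed, hgt_gene_ids=truth_ids)
    if out_path is not None:
        df.to_csv(out_path, sep="\t", index=False, header=False,
                  float_format="%.6g")
    return df, truth


def simulate_gene_models(n_genes: int, chrom_lengths: dict[str, int],
                         seed: int = 0, out_path=None) -> list[GeneModel]:
    """Place non-overlapping gene models with 1–5 exons on chromosomes.

    Every exon length is a multiple of 3, so the CDS divides evenly into
    codons; gene span equals exon total plus intron total by construction.
    Writes GFF3 when ``out_path`` is given.
    """
    rng = np.random.default_rng(seed)
    chroms = list(chrom_lengths)
    genes: list[GeneModel] = []
    exon_rows: list[tuple[GeneModel, list[tuple[int, int]]]] = []
    per_chrom = np.array_split(np.arange(n_genes), len(chroms))
    for chrom, idxs in zip(chroms, per_chrom):
        cursor = 1
        for gi in idxs:
            n_ex = int(rng.integers(1, 6))
            exon_lens = 3 * rng.integers(20, 201, size=n_ex)
            intron_lens = rng.integers(50, 501, size=max(n_ex - 1, 0))
            span = int(exon_lens.sum() + intron_lens.sum())
            gap = int(rng.integers(100, 1001))
            start = cursor + gap
            end = start + span - 1
            if end > chrom_lengths[chrom]:
                raise ValueError(
                    f"chromosome {chrom} too small for {n_genes} genes")
            exons = []
            pos = start
            for e in range(n_ex):
                exons.append((pos, pos + int(exon_lens[e]) - 1))
                pos += int(exon_lens[e])
                if e < n_ex - 1:
                    pos += int(intron_lens[e])
            strand = "+" if rng.random() < 0.5 else "-"
            gm = GeneModel(gene_id=f"gene{gi + 1:05d}", chrom=chrom,
                           start=start, end=end, strand=strand,
                           exon_count=n_ex, cds_length=int(exon_lens.sum()))
            genes.append(gm)
            exon_rows.append((gm, exons))
            cursor = end + 1
    if out_path is not None:
        with open(out_path, "w") as fh:
            fh.write("##gff-version 3\n")
            for chrom, length in chrom_lengths.items():
                fh.write(f"##sequence-region {chrom} 1 {length}\n")
            for gm, exons in exon_rows:
                fh.write(f"{gm.chrom}\tpopsweep\tgene\t{gm.start}\t{gm.end}\t.\t"
                         f"{gm.strand}\t.\tID={gm.gene_id}\n")
                mrna = f"{gm.gene_id}.t1"
                fh.write(f"{gm.chrom}\tpopsweep\tmRNA\t{gm.start}\t{gm.end}\t.\t"
                         f"{gm.strand}\t.\tID={mrna};Parent={gm.gene_id}\n")
                for k, (s, e) in enumerate(exons, 1):
                    fh.write(f"{gm.chrom}\tpopsweep\texon\t{s}\t{e}\t.\t"
                             f"{gm.strand}\t.\tID={mrna}.exon{k};Parent={mrna}\n")
                    fh.write(f"{gm.chrom}\tpopsweep\tCDS\t{s}\t{e}\t.\t"
                             f"{gm.strand}\t0\tID={mrna}.cds{k};Parent={mrna}\n")
    return genes


def simulate_sequences(n: int, length: int, gc_target: float, seed: int = 0,
                       out_path=None) -> list[SeqRecord]:
    """Random sequences with per-base Bernoulli(gc_target) G/C choice."""
    if not 0.0 <= gc_target <= 1.0:
        raise ValueError("gc_target must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        is_gc = rng.random(length) < gc_target
        pick = rng.integers(0, 2, size=length)
        gc_bases = np.where(pick == 0, "G", "C")
        at_bases = np.where(pick == 0, "A", "T")
        seq = "".join(np.where(is_gc, gc_bases, at_bases))
        records.append(SeqRecord(Seq(seq), id=f"seq{i + 1:04d}", description=""))
    if out_path is not None:
        SeqIO.write(records, str(out_path), "fasta")
    return records


def simulate_reads(genome_size: int, depth: float, read_length: int,
                   seed: int = 0, out_path=None) -> tuple[str, list[str]]:
    """Error-free reads uniformly sampled from a random genome.

    Returns the genome string and the reads; total bases ≈ depth ×
    genome_size.  Writes 4-line FASTQ (uniform quality) when ``out_path``
    is given.
    """
    if genome_size < read_length:
        raise ValueError("genome shorter than the read length")
    rng = np.random.default_rng(seed)
    genome = "".join(_BASES[rng.integers(0, 4, size=genome_size)])
    n_reads = int(round(depth * genome_size / read_length))
    starts = rng.integers(0, genome_size - read_length + 1, size=n_reads)
    reads = [genome[s:s + read_length] for s in starts]
    if out_path is not None:
        records = [
            SeqRecord(Seq(r), id=f"read{i + 1:06d}", description="",
                      letter_annotations={"phred_quality": [40] * len(r)})
            for i, r in enumerate(reads)
        ]
        SeqIO.write(records, str(out_path), "fastq")
    return genome, reads
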