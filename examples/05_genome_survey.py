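"""Estimate genome size from a k-mer spectrum of simulated reads.

genome size = total k-mers / coverage at the homozygous peak.
"""

from popsweep import (choose_k, estimate_genome_size, kmer_histogram,
                      simulate_reads)

genome_size = 100_000
_, reads = simulate_reads(genome_size, depth=30.0, read_length=100, seed=5)
k = choose_k(genome_size)
hist = kmer_histogram(reads, k)
est = estimate_genome_size(hist)

print(f"chosen k (4^k > 200 x genome): {k}")
print(f"reads: {len(reads)}; total k-mers: {hist.total_kmers}")
print(f"coverage peak: {est.peak_coverage}x")
print(f"estimated genome size: {est.genome_size_bp:,.0f} bp "
      f"(truth {genome_size:,} bp)")
# With error-free 30x reads the peak sits at depth x (L-k+1)/L and the
# estimate lands within a few percent of the true size.
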