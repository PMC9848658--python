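# Methods

This note records the models implemented, the parameter choices that
matter, what the simulators do and do not emulate, and the numerical
decisions taken where the design was genuinely open.

## SNP filtering

The filter has three rules, applied in order: (1) genotype calls supported
by fewer than `min_support` reads (default 4) are masked missing; calls
whose depth the VCF does not record pass by default (configurable), since
an absent DP is a reporting gap, not evidence of low support. (2) Sites
are kept only if their call rate over all samples is ≥ `min_call_rate`
(default 0.5) and (3) their minor-allele frequency over *called* alleles
is ≥ `min_maf` (default 0.05). Depth is interpreted per genotype, not per
site: masking individual low-support calls is what makes the subsequent
call-rate rule meaningful, and matches standard resequencing practice. The
filter is idempotent and never rewrites a dosage other than by masking.

Coordinates are 1-based inclusive everywhere internally; BED exports
convert to 0-based half-open.

## Window statistics

π uses the unbiased pairwise form 2c(n−c)/(n(n−1)) with each site's own
called-allele count n; the window denominator is window length in bp
(per-SNP mode available). Sites absent from the VCF are assumed invariant —
the usual assumption when a variant-only call set is windowed — so window π
is an underestimate wherever invariant-site filtering removed callable bp.

Tajima's D is computed per population per window with the haplotype count
fixed at 2 × (population sample count), while S counts sites polymorphic
among called alleles and π sums over each site's own n. With missing data
these disagree slightly; this is a documented approximation shared with the
common VCF-based implementations of D, and it vanishes at full call rate.
D is undefined (NaN, never 0) when S = 0.

F_ST follows Weir & Cockerham (1984) exactly: per-site components
a, b, c from the two populations' called-individual counts, allele
frequencies and observed heterozygote proportions, combined per window as
Σa/Σ(a+b+c). Sites where both populations are fixed for the same allele
contribute nothing; sites where either population has no called individual,
or where the mean sample size n̄ ≤ 1, are excluded from F_ST and d_XY but
still feed the other population's π. Negative window estimates are
reported raw (a clamping flag exists) so that downstream empirical
quantiles see the estimator's true distribution.

d_XY is p₁(1−p₂)+p₂(1−p₁) summed over sites and divided by window bp.

## Sweep calling

"Top 1%" and "top 5%" are empirical upper quantiles of the realized window
distribution, not parametric p-values: the threshold is the k-th largest
defined value with k = ceil(fraction × n); ties at the threshold all enter
the selection. The combined criterion is the intersection of π-ratio and
F_ST outlier sets at the same fraction, so it is a subset of both by
construction.

Windows where the denominator population's π is exactly zero need a
decision: they are the strongest possible sweep evidence (complete
fixation), yet their ratio is undefined as a number. The scan therefore
reports them as +inf — excluded from the finite distribution used to set
thresholds, always included in the selection, and counted in the log. The
alternative (dropping them) would blind the scan to precisely the windows
a hard sweep produces.

Window size and step default to 50 kb non-overlapping and are fully
configurable; there is no single field-standard choice, and bin counts are
sensitive to it, so reported bin counts are only comparable within one
configuration.

Gene-record arithmetic uses span = end − start + 1 and protein length =
CDS/3 (a flag switches to CDS/3 − 1 for the stop-exclusive convention).

## HGT screen

The screen operationalises the two published index families in their
standard cited forms, which the source methods reference but do not print:
AI = ln(E_in + ε) − ln(E_out + ε) with ε = 1e-200 (keeping zero E-values
finite), and h = bit_out − bit_in. Absent in-group hits are treated as
E = 1 and bit = 0 (both configurable) — i.e. "no detectable plant homolog"
is maximal alienness. "Both indices lead to a similar conclusion" is
implemented as both exceeding their thresholds, defaults AI ≥ 45 and
h ≥ 30, the common settings in the index literature; both are parameters.
The taxon vocabulary is plant, archaea, bacteria, fungi, virus, metazoan,
other; metazoan can be folded into other for the stricter six-group
vocabulary. Taxonomy assignment is a user-supplied keyword→group map
matched as case-insensitive substrings of the hit's lineage label, with
self-exclusion patterns for the recipient's own taxa; live taxonomy-
database lookups are out of scope. Phylogenetic confirmation of candidates
(ML homolog trees) is likewise out of scope — the screen's output is the
candidate list to hand to tree software.

GC flagging (gene GC exceeding the genome background by ≥ 0.10 by default)
is a secondary compositional signature, reported but never used as a
filter.

## Lineage trees

The allele-sharing distance d_ij = mean |g_i − g_j|/2 over co-called sites
is chosen for transparency; it is a semimetric on dosage vectors. NJ is
the standard Saitou–Nei agglomeration with ties broken by the smallest
index pair and negative branch-length estimates clamped to zero (logged).
NJ's consistency on additive matrices is the correctness anchor: the tests
require exact path-length recovery of random additive trees up to 12 taxa
and agreement with an independent NJ implementation.

## Genome survey

k is the smallest odd value with 4^k > 200 × genome-size guess, so that
random k-mer collisions are negligible relative to the genome. Counting is
exact over canonical k-mers (2-bit packed, k ≤ 31); reads shorter than k
are skipped and ambiguous bases dropped. The "average k-mer coverage" in
the size formula is read as the coverage peak — the spectrum mode above
the error tail (first local minimum, else coverage 2) — which is standard
survey practice; a mean-above-cutoff mode is available. Because the peak
is an integer, the estimate is quantized in steps of roughly 1/peak; at
the default demonstration scale (100 kb genome, 30× error-free 100 bp
reads) this keeps the estimate within ~5% of truth. Heterozygosity-rate
estimation would require a spectrum mixture model and is out of scope.

## Synthetic data

The panel generator is a Balding–Nichols sampler: ancestral frequencies
uniform on the configured MAF range (folded), population frequencies
Beta(p(1−F)/F, (1−p)(1−F)/F), diploid genotypes Binomial(2, p_k), depths
Poisson(mean 8), missingness Bernoulli (2%). Defaults — 15 + 13 samples,
F = 0.25, 5,000 sites on a 1 Mb chromosome — mirror the scale of a small
two-pedigree resequencing study. Sweeps replace the target population's
per-site frequency inside the interval with a Bernoulli(p) fixation draw,
which collapses within-interval diversity to zero: a deliberately extreme
hard-sweep caricature. What the generator does *not* emulate: linkage and
recombination (sites are exchangeable), coalescent genealogies, sequencing
error, indels, multi-allelic sites, or depth–genotype error coupling.
Passing tests therefore demonstrate estimator correctness and recovery
under the assumed sampling model, not robustness to real-data artefacts.

The hit-table generator enforces the screen's planted contrasts directly
(best in-group above best out-group by ≥ bit_separation for ordinary
genes, the reverse for planted HGTs, 3–20 hits per gene) and links
E-values to bit scores by E = db_size·2^(−bit) (db 1e9): monotone,
invertible and Karlin–Altschul-shaped. With the default separation of 100
bits the implied AI contrast is 100·ln 2 ≈ 69, comfortably above the
threshold, so recovery failures indicate implementation defects rather
than borderline statistics.

All generators draw from one seeded `numpy` Generator per call and are
byte-deterministic given the seed; every planted feature is addressable in
the emitted files and recorded in a JSON `TruthRecord`.

## Problem sizes in the acceptance run

The acceptance script uses 20 replicate panels of 5,000 sites for F
recovery, 5 panels of 10,000 sites over 100 windows (one planted sweep,
1% of windows) for sweep sensitivity, 1,000-gene hit tables with 3 planted
HGTs, 6 random additive trees up to 12 taxa, and a 100 kb genome at 30×
for the survey — sizes at which each stochastic check is stable across
seeds while the whole run stays in the seconds range.

## Known limitations

- No linkage: window statistics on simulated panels have less
  autocorrelation than real data, making empirical quantiles better
  behaved than they would be genome-wide.
- Tajima's D with heavy missingness mixes per-site n (π) with fixed n
  (constants), as noted above.
- The π-ratio's +inf convention means a single zero-diversity window
  always outranks any finite outlier; with real (noisier) data complete
  zeros are rare and the convention is inert.
- The HGT screen is a homology-contrast filter, not proof of transfer;
  donor assignment is only as good as the taxonomy map.
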