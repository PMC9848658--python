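"""K-mer-survey genome-size estimation.

genome size = (total number of k-mers) / (k-mer coverage at the homozygous
peak).  The word size k is the smallest odd value for which the k-mer space
comfortably exceeds the genome (4^k > 200 × genome-size guess), counting is
exact over canonical k-mers (the lexicographic minimum of a k-mer and its
reverse complement), and the peak is the mode of the coverage histogram
above the low-coverage error tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[ord(chr(_b).lower())] = _i


@dataclass
class KmerHistogram:
    """Coverage spectrum: multiplicity → number of distinct k-mers."""

    k: int
    counts: dict[int, int]

    @property
    def total_kmers(self) -> int:
        """Total k-mers extracted from the reads (Σ multiplicity × count)."""
        return sum(mult * n for mult, n in self.counts.items())


@dataclass
class SurveyEstimate:
    k: int
    peak_coverage: int
    genome_size_bp: float


def choose_k(genome_size_guess: float) -> int:
    """Smallest odd k with 4^k > 200 × genome-size guess."""
    if genome_size_guess <= 0:
        raise ValueError("genome size guess must be positive")
    k = 3
    while 4**k <= 200 * genome_size_guess:
        k += 2
    return k


def _canonical_codes(mat: np.ndarray, k: int) -> np.ndarray:
    """Canonical 2-bit k-mer codes for every window of every row."""
    n, L = mat.shape
    W = L - k + 1
    fwd = np.zeros((n, W), dtype=np.uint64)
    rev = np.zeros((n, W), dtype=np.uint64)
    for t in range(k):
        fwd = fwd * np.uint64(4) + mat[:, t:t + W].astype(np.uint64)
        comp = (np.uint64(3) - mat[:, k - 1 - t:k - 1 - t + W].astype(np.uint64))
        rev = rev * np.uint64(4) + comp
    return np.minimum(fwd, rev).ravel()


def kmer_histogram(reads, k: int) -> KmerHistogram:
    """Exact canonical k-mer coverage histogram over a read set.

    ``reads`` is an iterable of sequence strings (or objects with a ``seq``
    attribute); reads shorter than k are skipped.  Counting is hash-exact —
    no probabilistic sketches — so this targets desk-scale read sets.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > 31:
        raise ValueError("k > 31 overflows the 2-bit packing")
    by_length: dict[int, list[np.ndarray]] = {}
    for read in reads:
        seq = str(getattr(read, "seq", read))
        if len(seq) < k:
            continue
        arr = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
        if np.any(arr == 255):
            arr = arr[arr != 255]  # drop ambiguous bases, keep the rest
            if len(arr) < k:
                continue
        by_length.setdefault(len(arr), []).append(arr)
    codes = [
        _canonical_codes(np.vstack(rows), k)
        for rows in by_length.values()
    ]
    if not codes:
        return KmerHistogram(k=k, counts={})
    _, mult = np.unique(np.concatenate(codes), return_counts=True)
    cov, n_kmers = np.unique(mult, return_counts=True)
    return KmerHistogram(k=k, counts={int(c): int(n) for c, n in zip(cov, n_kmers)})


def _error_cutoff(hist: KmerHistogram) -> int:
    """First local minimum of the spectrum, else 2."""
    covs = sorted(hist.counts)
    for prev, cur, nxt in zip(covs, covs[1:], covs[2:]):
        if hist.counts[cur] < hist.counts[prev] and hist.counts[cur] <= hist.counts[nxt]:
            return cur
    return 2


def estimate_genome_size(hist: KmerHistogram,
                         error_cov_cutoff: int | None = None,
                         *, peak: str = "mode") -> SurveyEstimate:
    """Genome size from a k-mer spectrum: total k-mers / peak coverage.

    The peak is the spectrum mode among coverages above the error cutoff
    (default cutoff: first local minimum of the spectrum, else 2);
    ``peak="mean"`` instead uses the rounded mean coverage above the cutoff.
    """
    if not hist.counts:
        raise ValueError("empty k-mer histogram")
    cutoff = _error_cutoff(hist) if error_cov_cutoff is None else error_cov_cutoff
    above = {c: n for c, n in hist.counts.items() if c > cutoff}
    if not above:
        raise ValueError(f"no coverage peak above cutoff {cutoff}")
    if peak == "mode":
        peak_cov = max(above, key=lambda c: (above[c], -c))
    elif peak == "mean":
        tot = sum(n for n in above.values())
        peak_cov = int(round(sum(c * n for c, n in above.items()) / tot))
    else:
        raise ValueError("peak must be 'mode' or 'mean'")
    size = hist.total_kmers / peak_cov
    logger.info("genome survey: k=%d peak=%dx total=%d estimate=%.0f bp",
                hist.k, peak_cov, hist.total_kmers, size)
    return SurveyEstimate(k=hist.k, peak_coverage=peak_cov, genome_size_bp=size)
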