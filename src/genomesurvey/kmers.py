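"""Canonical k-mer counting, spectrum analysis and genome-size estimation.

A diploid genome sequenced at depth ``d`` produces a bimodal k-mer
spectrum: k-mers from homozygous regions occur on both haplotypes and
pile up around the k-mer coverage ``d``, while k-mers overlapping a
heterozygous site are private to one haplotype and pile up around
``d / 2``.  The genome (haploid) size follows from dividing the total
number of counted k-mers by the coverage-peak depth.

All counting is exact: k-mers are 2-bit encoded into 64-bit integers
(hence k <= 31) and tallied with vectorised numpy unique/sort passes,
which is fast enough for the multi-megabase simulations this package
targets.  Base coverage and k-mer coverage differ by the factor
``(L - k + 1) / L`` for reads of length L; functions in this module
always speak in k-mer coverage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "KmerHistogram",
    "PeakSet",
    "GenomeSizeEstimate",
    "NoPeakError",
    "count_canonical_kmers",
    "smooth_histogram",
    "find_error_trough",
    "detect_peaks",
    "classify_peaks",
    "estimate_genome_size",
]

# 2-bit base codes; anything that is not ACGT (case-insensitive) maps to 4
# and invalidates every window containing it.
_CODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lower case


class NoPeakError(ValueError):
    """Raised when a spectrum has no usable peak structure."""


@dataclass
class KmerHistogram:
    """Multiplicity -> number of distinct canonical k-mers."""

    k: int
    counts: dict[int, int]

    @property
    def total_kmers(self) -> int:
        """Total number of counted k-mer instances (sum m * count[m])."""
        return int(sum(m * c for m, c in self.counts.items()))

    @property
    def distinct_kmers(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def max_multiplicity(self) -> int:
        return max(self.counts) if self.counts else 0

    def dense(self) -> np.ndarray:
        """Counts as a dense array indexed by multiplicity - 1 (m = 1..max)."""
        out = np.zeros(self.max_multiplicity, dtype=float)
        for m, c in self.counts.items():
            out[m - 1] = c
        return out

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for m in sorted(self.counts):
                fh.write(f"{m}\t{self.counts[m]}\n")

    @classmethod
    def from_tsv(cls, path, k: int) -> "KmerHistogram":
        counts: dict[int, int] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                m, c = line.split()[:2]
                counts[int(m)] = int(c)
        return cls(k=k, counts=counts)


@dataclass
class PeakSet:
    """Peaks of a smoothed spectrum, optionally classified."""

    error_trough: int
    peaks: list[tuple[int, float]]  # (multiplicity, smoothed height), sorted by multiplicity
    coverage_peak: int | None = None
    het_peak: int | None = None


@dataclass
class GenomeSizeEstimate:
    size_bp: float
    coverage_peak: int
    kmers_used: int
    k: int


def _validate_k(k: int) -> None:
    if k % 2 == 0:
        raise ValueError("k must be odd (even k admits reverse-complement palindromes)")
    if not 1 <= k <= 31:
        raise ValueError("k must be in [1, 31] for 2-bit packed counting")


def _canonical_codes_2d(vals: np.ndarray, k: int) -> np.ndarray:
    """Canonical k-mer codes for every valid window of a (n, L) base-code array."""
    n, L = vals.shape
    W = L - k + 1
    if W <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros((n, W), dtype=np.int64)
    invalid = np.zeros((n, W), dtype=bool)
    for j in range(k):
        col = vals[:, j : j + W]
        invalid |= col == 4
        codes = (codes << 2) | (col & 3)
    # reverse complement: read bases off the low end, complement, repack
    rc = np.zeros_like(codes)
    tmp = codes.copy()
    for _ in range(k):
        rc = (rc << 2) | (3 - (tmp & 3))
        tmp >>= 2
    canon = np.minimum(codes, rc)
    return canon[~invalid].ravel()


def _encode_batch(seqs: Sequence[str], L: int) -> np.ndarray:
    joined = "".join(seqs)
    return _CODE[np.frombuffer(joined.encode("ascii"), dtype=np.uint8)].reshape(len(seqs), L)


def count_canonical_kmers(
    sequences: Iterable[str], k: int, *, batch_windows: int = 4_000_000
) -> KmerHistogram:
    """Count canonical k-mers over a stream of sequences.

    Every window of length ``k`` that contains no ambiguous base
    contributes the lexicographic minimum of itself and its reverse
    complement.  Sequences longer than ~1 Mb are processed in
    overlapping slices so that memory stays bounded.
    """
    _validate_k(k)
    chunks: list[np.ndarray] = []
    pending: dict[int, list[str]] = {}
    pending_windows = 0
    slice_len = 1_000_000

    def flush() -> None:
        nonlocal pending_windows
        for L, seqs in pending.items():
            vals = _encode_batch(seqs, L)
            codes = _canonical_codes_2d(vals, k)
            if codes.size:
                chunks.append(codes)
        pending.clear()
        pending_windows = 0

    for seq in sequences:
        if len(seq) > slice_len:
            # long reference: overlapping slices preserve every window
            for start in range(0, len(seq), slice_len):
                piece = seq[start : start + slice_len + k - 1]
                if len(piece) >= k:
                    vals = _CODE[np.frombuffer(piece.encode("ascii"), dtype=np.uint8)]
                    codes = _canonical_codes_2d(vals[None, :], k)
                    if codes.size:
                        chunks.append(codes)
            continue
        if len(seq) < k:
            continue
        pending.setdefault(len(seq), []).append(seq)
        pending_windows += len(seq) - k + 1
        if pending_windows >= batch_windows:
            flush()
    flush()

    if not chunks:
        return KmerHistogram(k=k, counts={})
    codes = np.concatenate(chunks)
    del chunks
    _, per_kmer = np.unique(codes, return_counts=True)
    del codes
    mult, freq = np.unique(per_kmer, return_counts=True)
    return KmerHistogram(k=k, counts=dict(zip(mult.tolist(), freq.tolist())))


def smooth_histogram(hist: KmerHistogram, window: int = 3) -> np.ndarray:
    """Centred moving average of the dense spectrum (index i <-> multiplicity i + 1).

    Edges are averaged over the neighbours that exist, so the first and
    last bins are not dragged toward zero by out-of-range positions.
    """
    dense = hist.dense()
    if dense.size == 0:
        return dense
    kernel = np.ones(window)
    num = np.convolve(dense, kernel, mode="same")
    den = np.convolve(np.ones_like(dense), kernel, mode="same")
    return num / den


def find_error_trough(hist: KmerHistogram, *, smoothing_window: int = 3) -> int:
    """Multiplicity separating the sequencing-error component from genomic peaks.

    Returns the smallest multiplicity m >= 2 that is a local minimum of
    the smoothed spectrum, or 1 when the spectrum rises from the start
    (no error component, e.g. error-free simulated reads).
    """
    if not hist.counts:
        raise NoPeakError("empty histogram")
    if len(hist.counts) == 1:
        raise NoPeakError("histogram has a single multiplicity class")
    sm = smooth_histogram(hist, smoothing_window)
    if sm.size < 2:
        raise NoPeakError("histogram too narrow")
    if sm[0] < sm[1]:
        return 1
    for i in range(1, sm.size - 1):
        if sm[i] <= sm[i - 1] and sm[i] <= sm[i + 1]:
            return i + 1  # index -> multiplicity
    raise NoPeakError("monotone decreasing spectrum: no genomic peak above the error component")


def detect_peaks(
    hist: KmerHistogram,
    smoothing_window: int = 3,
    *,
    trough: int | None = None,
    max_peaks: int = 2,
    min_rel_height: float = 0.05,
) -> PeakSet:
    """Local maxima of the smoothed spectrum above the error trough.

    Maxima below ``min_rel_height`` of the tallest one are discarded as
    sampling noise; the survivors are ranked by smoothed height and at
    most ``max_peaks`` are retained (the spectrum of a diploid genome
    has two genuine modes).
    """
    if trough is None:
        trough = find_error_trough(hist, smoothing_window=smoothing_window)
    sm = smooth_histogram(hist, smoothing_window)
    maxima: list[tuple[int, float]] = []
    for i in range(1, sm.size - 1):
        m = i + 1
        if m <= trough:
            continue
        # >= on the left, > on the right: a flat-topped peak is reported
        # once, at its leftmost bin; boundary bins are never peaks
        if sm[i] >= sm[i - 1] and sm[i] > sm[i + 1] and sm[i] > 0:
            maxima.append((m, float(sm[i])))
    if not maxima:
        raise NoPeakError("no local maximum above the error trough")
    tallest = max(h for _, h in maxima)
    maxima = [(m, h) for m, h in maxima if h >= min_rel_height * tallest]
    maxima.sort(key=lambda t: -t[1])
    kept = sorted(maxima[:max_peaks])
    return PeakSet(error_trough=trough, peaks=kept)


def classify_peaks(
    histograms: Sequence[KmerHistogram],
    *,
    smoothing_window: int = 3,
    match_tolerance: float = 0.20,
) -> list[PeakSet]:
    """Assign coverage vs heterozygous peaks across several k values.

    The homozygous (coverage) peak holds one k-mer per genomic position
    regardless of k, so its height is nearly constant across k, while
    the heterozygous peak grows with k (a longer window is more likely
    to overlap a heterozygous site).  The candidate whose height has the
    smaller coefficient of variation across k is therefore the coverage
    peak; the other is the heterozygous peak.
    """
    if len(histograms) < 2:
        raise ValueError("need at least two histograms (different k) to classify peaks")
    peaksets = [detect_peaks(h, smoothing_window) for h in histograms]
    n_peaks = {len(ps.peaks) for ps in peaksets}
    if n_peaks == {1}:
        # haploid-like spectrum: single peak, no heterozygous component
        for ps in peaksets:
            ps.coverage_peak = ps.peaks[0][0]
            ps.het_peak = None
        return peaksets
    if n_peaks != {2}:
        raise NoPeakError("histograms do not share the same two candidate peaks")

    groups = []  # lower-multiplicity candidates, higher-multiplicity candidates
    for rank in (0, 1):
        pos = np.array([ps.peaks[rank][0] for ps in peaksets], dtype=float)
        hgt = np.array([ps.peaks[rank][1] for ps in peaksets], dtype=float)
        med = np.median(pos)
        if np.any(np.abs(pos - med) > match_tolerance * med):
            raise NoPeakError("candidate peaks are not matchable across k (positions diverge)")
        groups.append((pos, hgt))

    cvs = [float(np.std(h) / np.mean(h)) for _, h in groups]
    cov_rank = int(np.argmin(cvs))
    het_rank = 1 - cov_rank
    for ps in peaksets:
        ps.coverage_peak = ps.peaks[cov_rank][0]
        ps.het_peak = ps.peaks[het_rank][0]
        ratio = ps.het_peak / ps.coverage_peak
        if not 0.4 <= ratio <= 0.6:
            warnings.warn(
                f"het/coverage peak ratio {ratio:.2f} outside [0.4, 0.6]; "
                "peak assignment may be unreliable",
                stacklevel=2,
            )
    return peaksets


def estimate_genome_size(
    hist: KmerHistogram,
    coverage_peak: int,
    *,
    exclude_below: int | None = None,
) -> GenomeSizeEstimate:
    """Haploid genome size: total k-mer count divided by the coverage-peak depth.

    K-mers below ``exclude_below`` (default: the detected error trough)
    are left out of the total so that sequencing-error k-mers do not
    inflate the estimate; on error-free input this is a no-op.
    """
    if coverage_peak <= 0:
        raise ValueError("coverage_peak must be positive")
    if exclude_below is None:
        exclude_below = find_error_trough(hist)
    kmers_used = sum(m * c for m, c in hist.counts.items() if m >= exclude_below)
    if kmers_used == 0:
        raise NoPeakError("no k-mers at or above the error trough")
    return GenomeSizeEstimate(
        size_bp=kmers_used / coverage_peak,
        coverage_peak=coverage_peak,
        kmers_used=int(kmers_used),
        k=hist.k,
    )
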