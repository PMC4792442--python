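"""Raw paired-end read filtering.

Five whole-read drop rules, applied in a fixed order to each pair:

a. too many ambiguous bases (N fraction strictly above a cutoff),
b. poly-A structure (A fraction at or above a cutoff),
c. too many low-quality base calls,
d. adapter contamination (ungapped adapter alignment with a minimum
   number of aligned positions and a mismatch budget),
e. mate overlap (for short-insert fragments the two reads read into
   each other; the reverse complement of mate 2 aligns ungapped against
   mate 1).

Reads are dropped whole, never trimmed, and a pair is dropped when
either mate trips any rule, keeping the mate files synchronised.  The
report attributes each dropped pair to the first rule (in a..e order)
that fired.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ReadPair",
    "QCConfig",
    "QCReport",
    "RULE_ORDER",
    "check_n_fraction",
    "check_polya",
    "check_low_quality",
    "check_adapter",
    "check_overlap",
    "filter_pairs",
]

# Widely used sequencing-adapter prefix; the true adapter of any given
# library is unknown to this package and should be passed explicitly.
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"

RULE_ORDER = ("N", "polyA", "lowQ", "adapter", "overlap")

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class ReadPair:
    id: str
    seq1: str
    seq2: str
    qual1: Sequence[int]
    qual2: Sequence[int]

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"sequence/quality length mismatch in pair {self.id!r}")


@dataclass
class QCConfig:
    max_n_fraction: float = 0.05
    polya_min_fraction: float = 0.80
    lowq_phred_threshold: int = 7
    lowq_max_count: int = 20
    adapter_sequence: str = DEFAULT_ADAPTER
    adapter_min_match: int = 11
    adapter_max_mismatch: int = 3
    overlap_min: int = 10
    overlap_max_mismatch_fraction: float = 0.10
    apply_overlap_filter_only_to_short_insert: bool = False

    def __post_init__(self) -> None:
        for name in ("max_n_fraction", "polya_min_fraction", "overlap_max_mismatch_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "lowq_phred_threshold",
            "lowq_max_count",
            "adapter_min_match",
            "adapter_max_mismatch",
            "overlap_min",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class QCReport:
    pairs_in: int = 0
    pairs_kept: int = 0
    drops: dict[str, int] = field(default_factory=lambda: {r: 0 for r in RULE_ORDER})

    def check_conservation(self) -> bool:
        return self.pairs_in == self.pairs_kept + sum(self.drops.values())

    def to_dict(self) -> dict:
        return {"pairs_in": self.pairs_in, "pairs_kept": self.pairs_kept, "drops": dict(self.drops)}


def check_n_fraction(seq: str, config: QCConfig) -> bool:
    """True (pass) unless the N fraction strictly exceeds the cutoff."""
    if not seq:
        raise ValueError("empty read")
    n = seq.count("N") + seq.count("n")
    return not (n / len(seq) > config.max_n_fraction)


def check_polya(seq: str, config: QCConfig) -> bool:
    """True (pass) unless the A fraction reaches the poly-A cutoff (>=)."""
    if not seq:
        raise ValueError("empty read")
    a = seq.count("A") + seq.count("a")
    return not (a / len(seq) >= config.polya_min_fraction)


def check_low_quality(qual: Sequence[int], config: QCConfig) -> bool:
    """True (pass) unless >= lowq_max_count bases have Phred <= threshold."""
    q = np.asarray(qual)
    return not (int(np.count_nonzero(q <= config.lowq_phred_threshold)) >= config.lowq_max_count)


def _mismatches(a: str, b: str) -> int:
    """Mismatch count between equal-length strings; N mismatches everything."""
    return sum(
        1
        for x, y in zip(a, b)
        if x != y or x in "Nn"
    )


def check_adapter(seq: str, config: QCConfig) -> bool:
    """True (pass) unless an ungapped adapter alignment has >= adapter_min_match
    aligned positions with <= adapter_max_mismatch mismatches.

    Every diagonal (adapter offset against the read, including partial
    overhangs off either end) is scanned; an alignment of length L >=
    adapter_min_match with a small mismatch count exists on a diagonal
    iff some window of length exactly adapter_min_match does, so a
    sliding window of that length suffices.
    """
    adapter = config.adapter_sequence
    if not adapter:
        raise ValueError("adapter_sequence must be non-empty")
    la, lr = len(adapter), len(seq)
    min_m = config.adapter_min_match
    max_mm = config.adapter_max_mismatch
    if min_m == 0:
        return False
    for offset in range(-(la - 1), lr):
        a_lo = max(0, -offset)
        a_hi = min(la, lr - offset)
        if a_hi - a_lo < min_m:
            continue
        running = 0
        mm_flags = []
        for i in range(a_lo, a_hi):
            x, y = adapter[i], seq[offset + i]
            bad = 1 if (x != y or y in "Nn") else 0
            mm_flags.append(bad)
            running += bad
            if len(mm_flags) > min_m:
                running -= mm_flags[-min_m - 1]
            if len(mm_flags) >= min_m and running <= max_mm:
                return False
    return True


def check_overlap(pair: ReadPair, config: QCConfig) -> bool:
    """True (pass) unless the mates overlap by >= overlap_min bases.

    The reverse complement of mate 2 is slid over mate 1 (suffix of
    mate 1 against prefix of rc(mate 2), the geometry of a short
    fragment); an overlap fails the pair when its mismatch fraction is
    <= overlap_max_mismatch_fraction.
    """
    rc2 = revcomp(pair.seq2)
    l1, l2 = len(pair.seq1), len(rc2)
    for ov in range(config.overlap_min, min(l1, l2) + 1):
        mm = _mismatches(pair.seq1[l1 - ov :], rc2[:ov])
        if mm / ov <= config.overlap_max_mismatch_fraction:
            return False
    return True


def first_failing_rule(pair: ReadPair, config: QCConfig, *, short_insert: bool = True) -> str | None:
    """Name of the first rule (a..e order) the pair trips, or None."""
    for mate_seq in (pair.seq1, pair.seq2):
        if not check_n_fraction(mate_seq, config):
            return "N"
    for mate_seq in (pair.seq1, pair.seq2):
        if not check_polya(mate_seq, config):
            return "polyA"
    for mate_q in (pair.qual1, pair.qual2):
        if not check_low_quality(mate_q, config):
            return "lowQ"
    for mate_seq in (pair.seq1, pair.seq2):
        if not check_adapter(mate_seq, config):
            return "adapter"
    apply_overlap = short_insert or not config.apply_overlap_filter_only_to_short_insert
    if apply_overlap and not check_overlap(pair, config):
        return "overlap"
    return None


def filter_pairs(
    pairs: Iterable[ReadPair],
    config: QCConfig | None = None,
    *,
    short_insert_ids: set[str] | None = None,
) -> tuple[list[ReadPair], QCReport]:
    """Apply all five rules to a pair stream.

    ``short_insert_ids`` restricts the overlap rule to the named pairs
    when ``apply_overlap_filter_only_to_short_insert`` is set; by
    default the overlap rule is applied to every pair.
    """
    if config is None:
        config = QCConfig()
    kept: list[ReadPair] = []
    report = QCReport()
    for pair in pairs:
        report.pairs_in += 1
        short = short_insert_ids is None or pair.id in short_insert_ids
        rule = first_failing_rule(pair, config, short_insert=short)
        if rule is None:
            kept.append(pair)
            report.pairs_kept += 1
        else:
            report.drops[rule] += 1
    return kept, report
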