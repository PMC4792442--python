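"""Assembly contiguity statistics and repeat-landscape summaries.

Scaffolds are split into contigs at runs of >= 25 consecutive Ns (a
"captured gap"); shorter N runs stay inside contigs.  The contiguity
report mirrors the classic assembly-metrics convention: scaffold
counts, size-class tallies, N50, and the split of assembled bases
between scaffolded contigs (contigs from scaffolds holding a captured
gap) and unscaffolded contigs.

Repeat summaries take externally produced masked intervals (e.g. a
RepeatMasker run) and report, per repeat family and class, the union
length masked, its percentage of the assembly, and its percentage of
the total masked length.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScaffoldSet",
    "AssemblyStats",
    "RepeatSummary",
    "split_into_contigs",
    "compute_stats",
    "summarize_repeats",
    "union_length",
]

DEFAULT_MIN_GAP = 25
SIZE_THRESHOLDS = (500, 1_000, 10_000, 100_000, 1_000_000)


def split_into_contigs(scaffold: str, min_gap_len: int = DEFAULT_MIN_GAP) -> list[str]:
    """Maximal substrings not interrupted by >= min_gap_len consecutive Ns."""
    if min_gap_len < 1:
        raise ValueError("min_gap_len must be >= 1")
    pieces = re.split("[Nn]{%d,}" % min_gap_len, scaffold)
    return [p for p in pieces if p]


@dataclass
class ScaffoldSet:
    sequences: dict[str, str]
    min_gap_len: int = DEFAULT_MIN_GAP

    def contigs(self) -> dict[str, list[str]]:
        return {
            sid: split_into_contigs(seq, self.min_gap_len) for sid, seq in self.sequences.items()
        }


@dataclass
class AssemblyStats:
    n_scaffolds: int
    total_size: int
    longest: int
    shortest: int
    n_above: dict[int, int]
    pct_above: dict[int, float]
    mean_size: float
    median_size: float
    n50: int
    pct_in_scaffolded_contigs: float
    pct_in_unscaffolded_contigs: float
    mean_contigs_per_scaffold: float

    def to_dict(self) -> dict:
        d = {
            "Number of scaffolds": self.n_scaffolds,
            "Total size of scaffolds": self.total_size,
            "Longest scaffold": self.longest,
            "Shortest scaffold": self.shortest,
            "Mean scaffold size": round(self.mean_size),
            "Median scaffold size": self.median_size,
            "N50 scaffold length": self.n50,
            "Percentage of assembly in scaffolded contigs": round(
                self.pct_in_scaffolded_contigs, 1
            ),
            "Percentage of assembly in unscaffolded contigs": round(
                self.pct_in_unscaffolded_contigs, 1
            ),
            "Average number of contigs per scaffold": round(self.mean_contigs_per_scaffold, 1),
        }
        for t in sorted(self.n_above):
            label = f"{t // 1000}K" if t >= 1000 and t < 1_000_000 else (
                "1M" if t >= 1_000_000 else str(t)
            )
            d[f"Number of scaffolds > {label} nt"] = self.n_above[t]
            d[f"Percentage of scaffolds > {label} nt"] = round(self.pct_above[t], 1)
        return d


def compute_n50(lengths: Sequence[int]) -> int:
    """Largest L such that sequences of length >= L hold >= half the total bases."""
    arr = np.sort(np.asarray(lengths))[::-1]
    half = arr.sum() / 2.0
    cum = np.cumsum(arr)
    idx = int(np.searchsorted(cum, half))
    return int(arr[idx])


def compute_stats(scaffolds: ScaffoldSet | Mapping[str, str]) -> AssemblyStats:
    if not isinstance(scaffolds, ScaffoldSet):
        scaffolds = ScaffoldSet(dict(scaffolds))
    seqs = scaffolds.sequences
    if not seqs:
        raise ValueError("empty scaffold set")
    lengths = np.array([len(s) for s in seqs.values()])
    total = int(lengths.sum())
    contigs = scaffolds.contigs()
    contig_bases = sum(sum(len(c) for c in cs) for cs in contigs.values())
    scaffolded_bases = sum(
        sum(len(c) for c in cs) for cs in contigs.values() if len(cs) >= 2
    )
    n_contigs = sum(len(cs) for cs in contigs.values())
    n_above = {t: int(np.count_nonzero(lengths > t)) for t in SIZE_THRESHOLDS}
    return AssemblyStats(
        n_scaffolds=len(seqs),
        total_size=total,
        longest=int(lengths.max()),
        shortest=int(lengths.min()),
        n_above=n_above,
        pct_above={t: 100.0 * n / len(seqs) for t, n in n_above.items()},
        mean_size=float(lengths.mean()),
        median_size=float(np.median(lengths)),
        n50=compute_n50(lengths),
        pct_in_scaffolded_contigs=100.0 * scaffolded_bases / contig_bases,
        pct_in_unscaffolded_contigs=100.0 * (contig_bases - scaffolded_bases) / contig_bases,
        mean_contigs_per_scaffold=n_contigs / len(seqs),
    )


def union_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total length of the union of 0-based half-open intervals."""
    ivs = sorted(intervals)
    total = 0
    cur_start, cur_end = None, None
    for start, end in ivs:
        if start > end:
            raise ValueError(f"inverted interval ({start}, {end})")
        if cur_end is None or start > cur_end:
            if cur_end is not None:
                total += cur_end - cur_start
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    if cur_end is not None:
        total += cur_end - cur_start
    return total


@dataclass
class RepeatSummary:
    assembly_length: int
    masked_total: int  # union over all intervals
    pct_assembly_masked: float
    per_family: pd.DataFrame  # family, repeat_class, masked_bp, pct_assembly
    per_class: pd.DataFrame  # repeat_class, masked_bp, pct_assembly, pct_of_masked


def summarize_repeats(
    assembly_length: int,
    intervals: pd.DataFrame,
) -> RepeatSummary:
    """Summarise masked intervals per repeat family and class.

    ``intervals`` needs columns ``chrom, start, end, family, repeat_class``
    (0-based half-open, per-contig coordinates).  Union lengths are
    computed per (contig, family); a base masked by two families is
    counted once in the overall masked total but once per family in the
    per-family/per-class breakdown, whose percentages therefore
    partition the per-class masked total.
    """
    required = {"chrom", "start", "end", "family", "repeat_class"}
    if intervals.empty:
        empty = pd.DataFrame(columns=["family", "repeat_class", "masked_bp", "pct_assembly"])
        empty_c = pd.DataFrame(columns=["repeat_class", "masked_bp", "pct_assembly", "pct_of_masked"])
        return RepeatSummary(assembly_length, 0, 0.0, empty, empty_c)
    if not required <= set(intervals.columns):
        raise ValueError(f"interval table must have columns {sorted(required)}")
    if (intervals["start"] > intervals["end"]).any():
        raise ValueError("inverted interval in repeat table")
    if (intervals["start"] < 0).any():
        raise ValueError("negative interval coordinate")

    masked_total = sum(
        union_length(zip(g["start"], g["end"])) for _, g in intervals.groupby("chrom")
    )
    if masked_total > assembly_length:
        raise ValueError("masked union exceeds assembly length")

    fam_rows = []
    for (family, rclass), g in intervals.groupby(["family", "repeat_class"]):
        bp = sum(union_length(zip(gg["start"], gg["end"])) for _, gg in g.groupby("chrom"))
        fam_rows.append({"family": family, "repeat_class": rclass, "masked_bp": bp})
    per_family = pd.DataFrame(fam_rows)
    per_family["pct_assembly"] = 100.0 * per_family["masked_bp"] / assembly_length
    per_family = per_family.sort_values("masked_bp", ascending=False).reset_index(drop=True)

    per_class = (
        per_family.groupby("repeat_class", as_index=False)["masked_bp"].sum()
    )
    per_class["pct_assembly"] = 100.0 * per_class["masked_bp"] / assembly_length
    class_total = per_class["masked_bp"].sum()
    per_class["pct_of_masked"] = 100.0 * per_class["masked_bp"] / class_total
    per_class = per_class.sort_values("masked_bp", ascending=False).reset_index(drop=True)

    return RepeatSummary(
        assembly_length=assembly_length,
        masked_total=int(masked_total),
        pct_assembly_masked=100.0 * masked_total / assembly_length,
        per_family=per_family,
        per_class=per_class,
    )
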