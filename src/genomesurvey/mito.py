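"""Mitochondrial sequence analysis on a circular reference.

The workflow mirrors how organelle genomes are pulled out of a nuclear
genome survey: contig alignments against a mitochondrial reference are
filtered for specificity (e-value, identity, accumulated per-contig
alignment coverage), the surviving contigs are chained into a tiling
path over the reference, the raw reads are mapped back to profile
depth, and single-nucleotide variants are called from the pileup and
binned per annotated gene.

Circularity is handled with the doubled-sequence trick: reads are
seeded and extended on ``ref + ref`` and every reported coordinate is
reduced modulo the reference length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .assembly import union_length

__all__ = [
    "AlignmentRecord",
    "TilingPath",
    "TilingSegment",
    "DepthProfile",
    "Placement",
    "Variant",
    "Gene",
    "GeneVariantTable",
    "filter_mito_alignments",
    "reference_coverage",
    "build_tiling",
    "map_reads_minimal",
    "depth_profile",
    "call_snvs",
    "variant_density_by_gene",
    "placements_from_sam",
]

_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i
_BASES = "ACGT"
_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


# ---------------------------------------------------------------------------
# contig alignments


@dataclass
class AlignmentRecord:
    query_id: str
    query_len: int
    ref_id: str
    ref_len: int
    q_start: int
    q_end: int
    r_start: int
    r_end: int
    identity: float  # percent, 0..100
    evalue: float
    reverse: bool = False  # True when the match is on the reverse strand

    def __post_init__(self) -> None:
        if not (0 <= self.q_start < self.q_end <= self.query_len):
            raise ValueError(f"query interval out of bounds for {self.query_id!r}")
        if not (0 <= self.r_start < self.r_end <= self.ref_len):
            raise ValueError(f"ref interval out of bounds for {self.query_id!r}")
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError("identity must be a percentage in [0, 100]")


def filter_mito_alignments(
    records: Sequence[AlignmentRecord],
    *,
    max_evalue: float = 1e-6,
    min_identity: float = 90.0,
    min_query_coverage: float = 0.90,
) -> list[AlignmentRecord]:
    """Drop non-specific alignments.

    A record survives when its e-value is <= ``max_evalue`` and its
    identity >= ``min_identity``; a contig's records are then kept only
    when the contig's accumulated (union) aligned fraction of its own
    length is >= ``min_query_coverage``.
    """
    stage1 = [r for r in records if r.evalue <= max_evalue and r.identity >= min_identity]
    by_query: dict[str, list[AlignmentRecord]] = {}
    for r in stage1:
        by_query.setdefault(r.query_id, []).append(r)
    kept: list[AlignmentRecord] = []
    for recs in by_query.values():
        covered = union_length([(r.q_start, r.q_end) for r in recs])
        if covered / recs[0].query_len >= min_query_coverage:
            kept.extend(recs)
    return kept


def reference_coverage(
    records: Sequence[AlignmentRecord], ref_length: int
) -> tuple[float, int]:
    """Fraction of the reference covered by the records, and contributing contigs."""
    if not records:
        return 0.0, 0
    covered = union_length([(r.r_start, r.r_end) for r in records])
    return covered / ref_length, len({r.query_id for r in records})


@dataclass
class TilingSegment:
    record: AlignmentRecord
    r_start: int
    r_end: int
    reverse: bool


@dataclass
class TilingPath:
    segments: list[TilingSegment]
    ref_length: int
    covered_fraction: float
    gaps: list[tuple[int, int]]  # uncovered [start, end) holes between segments


def build_tiling(
    records: Sequence[AlignmentRecord],
    ref_length: int | None = None,
    *,
    max_gap: int = 0,
    min_record_length: int = 100,
) -> TilingPath:
    """Greedy left-to-right chain of alignments over the reference.

    Records shorter than ``min_record_length`` on the reference are
    ignored.  Among records starting at or before the current chain end
    plus ``max_gap``, the one extending furthest right is selected;
    records fully contained in the already-tiled span are skipped.
    Where no record continues the chain, the hole is recorded as a gap
    and the chain restarts at the next record.
    """
    if ref_length is None:
        ref_length = records[0].ref_len if records else 0
    usable = sorted(
        (r for r in records if r.r_end - r.r_start >= min_record_length),
        key=lambda r: (r.r_start, -r.r_end),
    )
    segments: list[TilingSegment] = []
    gaps: list[tuple[int, int]] = []
    i = 0
    cur_end: int | None = None
    remaining = usable
    while remaining:
        if cur_end is None:
            window_end = remaining[0].r_start  # start a fresh chain at the leftmost record
        else:
            window_end = cur_end + max_gap
        candidates = [r for r in remaining if r.r_start <= window_end]
        candidates = [r for r in candidates if cur_end is None or r.r_end > cur_end]
        if not candidates:
            nxt = next((r for r in remaining if cur_end is None or r.r_end > cur_end), None)
            if nxt is None:
                break
            if cur_end is not None:
                gaps.append((cur_end, nxt.r_start))
            cur_end = None
            remaining = [r for r in remaining if r.r_start >= nxt.r_start]
            continue
        best = max(candidates, key=lambda r: (r.r_end, -r.r_start))
        segments.append(
            TilingSegment(record=best, r_start=best.r_start, r_end=best.r_end, reverse=best.reverse)
        )
        cur_end = best.r_end
        remaining = [r for r in remaining if r is not best and r.r_end > cur_end]
    covered = union_length([(s.r_start, s.r_end) for s in segments])
    frac = covered / ref_length if ref_length else 0.0
    return TilingPath(segments=segments, ref_length=ref_length, covered_fraction=frac, gaps=gaps)


# ---------------------------------------------------------------------------
# read mapping, depth and variants


@dataclass
class Placement:
    read_id: str
    pos: int  # 0-based start on the forward reference, modulo ref length
    reverse: bool
    mismatches: int
    length: int
    bases: np.ndarray = field(repr=False)  # 2-bit codes, oriented to the forward strand


def map_reads_minimal(
    reads: Iterable[tuple[str, str]],
    ref: str,
    *,
    seed_k: int = 21,
    circular: bool = True,
) -> tuple[list[Placement], list[str]]:
    """Seed-and-extend ungapped mapper for a short circular reference.

    Exact ``seed_k``-mers anchor candidate placements on the doubled
    reference; each candidate is scored by full-length ungapped mismatch
    count and the unique best placement wins.  A tie between distinct
    placements is ambiguous and the read is left unmapped, as is a read
    with no exact seed hit.  Returns ``(placements, unmapped_ids)``.
    """
    L = len(ref)
    doubled = ref + ref if circular else ref
    dl = len(doubled)
    enc_ref = _encode(doubled)

    # vectorised rolling codes for every seed_k window of the doubled reference
    W = dl - seed_k + 1
    vals = enc_ref.astype(np.int64)
    codes = np.zeros(W, dtype=np.int64)
    invalid = np.zeros(W, dtype=bool)
    for j in range(seed_k):
        col = vals[j : j + W]
        invalid |= col == 4
        codes = (codes << 2) | (col & 3)
    index: dict[int, list[int]] = {}
    for p in np.flatnonzero(~invalid):
        index.setdefault(int(codes[p]), []).append(int(p))

    placements: list[Placement] = []
    unmapped: list[str] = []
    for read_id, seq in reads:
        if len(seq) > L:
            raise ValueError(f"read {read_id!r} longer than the reference")
        best: tuple[int, int, bool] | None = None  # (mismatches, pos, reverse)
        best_enc: np.ndarray | None = None
        tie = False
        for reverse in (False, True):
            oriented = _revcomp(seq) if reverse else seq
            enc = _encode(oriented)
            n = enc.size
            offsets = list(range(0, n - seed_k + 1, seed_k))
            if offsets and offsets[-1] != n - seed_k:
                offsets.append(n - seed_k)
            seen: set[int] = set()
            for off in offsets:
                window = enc[off : off + seed_k]
                if np.any(window == 4):
                    continue
                code = 0
                for v in window:
                    code = (code << 2) | int(v)
                for p in index.get(code, ()):
                    s = p - off
                    if s < 0 or s + n > dl:
                        continue
                    key = (s % L) if circular else s
                    if key in seen:
                        continue
                    seen.add(key)
                    mm = int(np.count_nonzero(enc != enc_ref[s : s + n]))
                    cand = (mm, key, reverse)
                    if best is None or mm < best[0]:
                        best, best_enc, tie = cand, enc, False
                    elif mm == best[0] and (key, reverse) != (best[1], best[2]):
                        tie = True
        if best is None or tie:
            unmapped.append(read_id)
        else:
            placements.append(
                Placement(
                    read_id=read_id,
                    pos=best[1],
                    reverse=best[2],
                    mismatches=best[0],
                    length=best_enc.size,
                    bases=best_enc,
                )
            )
    return placements, unmapped


@dataclass
class DepthProfile:
    depth: np.ndarray
    mean_depth: float
    min_window_start: int
    min_window_depth: float
    window: int


def depth_profile(
    placements: Sequence[Placement], ref_length: int, window: int = 50
) -> DepthProfile:
    """Per-position depth on the circular reference plus the shallowest window."""
    depth = np.zeros(ref_length, dtype=np.int64)
    if placements:
        pos = np.concatenate(
            [(p.pos + np.arange(p.length)) % ref_length for p in placements]
        )
        np.add.at(depth, pos, 1)
    window = min(window, ref_length)
    # circular sliding-window mean
    ext = np.concatenate([depth, depth[: window - 1]]).astype(float)
    csum = np.concatenate([[0.0], np.cumsum(ext)])
    win_mean = (csum[window:] - csum[:-window]) / window
    start = int(np.argmin(win_mean))
    return DepthProfile(
        depth=depth,
        mean_depth=float(depth.mean()),
        min_window_start=start,
        min_window_depth=float(win_mean[start]),
        window=window,
    )


@dataclass
class Variant:
    pos: int
    ref: str
    alt: str
    depth: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.alt == self.ref:
            raise ValueError("alternate allele equals reference")
        if self.alt_count > self.depth:
            raise ValueError("alternate count exceeds depth")


def call_snvs(
    placements: Sequence[Placement],
    ref: str,
    *,
    min_depth: int = 10,
    min_alt_frac: float = 0.2,
    min_alt_count: int = 4,
) -> list[Variant]:
    """Pileup-based SNV caller.

    A site is called when its depth is >= ``min_depth`` and the most
    frequent non-reference allele reaches both ``min_alt_count`` reads
    and ``min_alt_frac`` of the depth.
    """
    L = len(ref)
    counts = np.zeros((4, L), dtype=np.int64)
    for p in placements:
        pos = (p.pos + np.arange(p.length)) % L
        valid = p.bases < 4
        np.add.at(counts, (p.bases[valid].astype(np.int64), pos[valid]), 1)
    depth = counts.sum(axis=0)
    enc_ref = _encode(ref).astype(np.int64)
    alt_counts = counts.copy()
    ref_valid = enc_ref < 4
    alt_counts[enc_ref[ref_valid], np.flatnonzero(ref_valid)] = -1
    alt_idx = alt_counts.argmax(axis=0)
    alt_n = alt_counts.max(axis=0)
    callable_ = (
        ref_valid
        & (depth >= min_depth)
        & (alt_n >= min_alt_count)
        & (alt_n >= min_alt_frac * depth)
    )
    variants = []
    for i in np.flatnonzero(callable_):
        variants.append(
            Variant(
                pos=int(i),
                ref=_BASES[enc_ref[i]],
                alt=_BASES[alt_idx[i]],
                depth=int(depth[i]),
                alt_count=int(alt_n[i]),
            )
        )
    return variants


# ---------------------------------------------------------------------------
# per-gene variant density


@dataclass
class Gene:
    name: str
    start: int
    end: int
    coding: bool = True


@dataclass
class GeneVariantTable:
    rows: "pd.DataFrame"
    coding_variants: int
    noncoding_variants: int
    intergenic_variants: int


def variant_density_by_gene(
    variants: Sequence[Variant], genes: Sequence[Gene], ref_length: int | None = None
) -> GeneVariantTable:
    """Per-gene variant counts and variants-per-bp percentages, ranked by density.

    A variant inside two overlapping genes is attributed to both.  The
    coding/non-coding totals and the intergenic remainder each count a
    variant once.
    """
    import pandas as pd

    for g in genes:
        if not 0 <= g.start < g.end:
            raise ValueError(f"bad gene interval for {g.name!r}")
        if ref_length is not None and g.end > ref_length:
            raise ValueError(f"gene {g.name!r} extends past the reference")
    rows = []
    in_coding: set[int] = set()
    in_noncoding: set[int] = set()
    for g in genes:
        count = sum(1 for v in variants if g.start <= v.pos < g.end)
        rows.append(
            {
                "gene": g.name,
                "length_bp": g.end - g.start,
                "variants": count,
                "pct_variants_per_bp": 100.0 * count / (g.end - g.start),
                "coding": g.coding,
            }
        )
        hit = {v.pos for v in variants if g.start <= v.pos < g.end}
        (in_coding if g.coding else in_noncoding).update(hit)
    df = pd.DataFrame(
        rows, columns=["gene", "length_bp", "variants", "pct_variants_per_bp", "coding"]
    )
    if not df.empty:
        df = df.sort_values("pct_variants_per_bp", ascending=False).reset_index(drop=True)
    all_pos = {v.pos for v in variants}
    genic = in_coding | in_noncoding
    return GeneVariantTable(
        rows=df,
        coding_variants=len(in_coding),
        noncoding_variants=len(in_noncoding - in_coding),
        intergenic_variants=len(all_pos - genic),
    )


def placements_from_sam(path: str, ref_length: int) -> list[Placement]:
    """Load read placements from a SAM file (e.g. an external mapper's output)."""
    import pysam

    placements = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.query_sequence is None:
                continue
            enc = _encode(rec.query_sequence)
            placements.append(
                Placement(
                    read_id=rec.query_name,
                    pos=rec.reference_start % ref_length,
                    reverse=rec.is_reverse,
                    mismatches=int(rec.get_tag("NM")) if rec.has_tag("NM") else 0,
                    length=enc.size,
                    bases=enc,
                )
            )
    return placements
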