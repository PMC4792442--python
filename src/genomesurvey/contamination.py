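"""Two-stage bacterial-contamination screen for draft assemblies.

Stage one flags candidate contigs from nucleotide-level matches to
bacterial references: a contig is a candidate when the accumulated
(union) length of its matched regions is strictly more than 10% of the
contig length.  Stage two confirms a candidate by its best protein hit
(lowest e-value, ties broken by highest bit-score): the contig is
confirmed bacterial only when that best hit is of bacterial origin and
passes the e-value cutoff.  Confirmed contigs are removed from the
assembly before gene prediction; the match and hit classifiers
themselves (e.g. a k-mer taxonomy tool, BLASTX) are upstream of this
module, which consumes their tabular output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .assembly import union_length

__all__ = [
    "MatchInterval",
    "HitRecord",
    "ContigScreen",
    "ScreenResult",
    "flag_candidate",
    "confirm_bacterial",
    "screen_assembly",
    "union_length",
]

CANDIDATE_FRACTION = 0.10
CONFIRM_EVALUE = 1e-6


@dataclass
class MatchInterval:
    contig_id: str
    start: int
    end: int
    source: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end}) on {self.contig_id}")


@dataclass
class HitRecord:
    contig_id: str
    subject_id: str
    bacterial: bool
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("e-value must be >= 0")


@dataclass
class ContigScreen:
    contig_id: str
    length: int
    union_matched_bp: int
    matched_fraction: float
    candidate: bool
    confirmed: bool


@dataclass
class ScreenResult:
    per_contig: list[ContigScreen]
    n_in: int
    n_candidates: int
    n_confirmed: int

    def removed_ids(self) -> set[str]:
        return {c.contig_id for c in self.per_contig if c.confirmed}


def flag_candidate(
    contig_length: int,
    intervals: Sequence[MatchInterval | tuple[int, int]],
    threshold: float = CANDIDATE_FRACTION,
) -> bool:
    """Candidate iff union of matched regions > threshold of contig length (strict)."""
    if contig_length <= 0:
        raise ValueError("contig length must be positive")
    ivs = [
        (iv.start, iv.end) if isinstance(iv, MatchInterval) else tuple(iv) for iv in intervals
    ]
    for s, e in ivs:
        if e > contig_length:
            raise ValueError("match interval extends past contig end")
    return union_length(ivs) / contig_length > threshold


def confirm_bacterial(hits: Sequence[HitRecord], evalue_cutoff: float = CONFIRM_EVALUE) -> bool:
    """Confirmed iff the best hit is bacterial and passes the cutoff.

    Best hit: lowest e-value, ties broken by highest bit-score.  A tie
    that survives both criteria between a bacterial and a non-bacterial
    subject is resolved conservatively as not confirmed.
    """
    if not hits:
        return False
    best_key = min((h.evalue, -h.bitscore) for h in hits)
    best = [h for h in hits if (h.evalue, -h.bitscore) == best_key]
    if any(not h.bacterial for h in best):
        return False
    return best[0].evalue <= evalue_cutoff


def screen_assembly(
    contigs: Mapping[str, str] | Mapping[str, int],
    intervals: Iterable[MatchInterval],
    hits: Iterable[HitRecord],
) -> tuple[dict[str, str | int], ScreenResult]:
    """Run both stages over an assembly and drop confirmed contigs.

    ``contigs`` maps id -> sequence (or id -> length).  Returns the
    cleaned contig mapping plus a per-contig report.
    """
    lengths = {
        cid: (len(v) if isinstance(v, str) else int(v)) for cid, v in contigs.items()
    }
    by_contig_iv: dict[str, list[MatchInterval]] = {}
    for iv in intervals:
        if iv.contig_id not in lengths:
            raise KeyError(f"match interval references unknown contig {iv.contig_id!r}")
        by_contig_iv.setdefault(iv.contig_id, []).append(iv)
    by_contig_hits: dict[str, list[HitRecord]] = {}
    for h in hits:
        if h.contig_id not in lengths:
            raise KeyError(f"hit references unknown contig {h.contig_id!r}")
        by_contig_hits.setdefault(h.contig_id, []).append(h)

    per_contig = []
    for cid, length in lengths.items():
        ivs = by_contig_iv.get(cid, [])
        bp = union_length([(iv.start, iv.end) for iv in ivs])
        candidate = flag_candidate(length, ivs) if ivs else False
        confirmed = candidate and confirm_bacterial(by_contig_hits.get(cid, []))
        per_contig.append(
            ContigScreen(
                contig_id=cid,
                length=length,
                union_matched_bp=bp,
                matched_fraction=bp / length,
                candidate=candidate,
                confirmed=confirmed,
            )
        )
    result = ScreenResult(
        per_contig=per_contig,
        n_in=len(lengths),
        n_candidates=sum(c.candidate for c in per_contig),
        n_confirmed=sum(c.confirmed for c in per_contig),
    )
    cleaned = {cid: v for cid, v in contigs.items() if cid not in result.removed_ids()}
    return cleaned, result
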