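"""Core-gene completeness scoring and gene-repertoire extrapolation.

A genome assembly's gene space is scored against a universal set of
core eukaryotic proteins (248 by convention).  A core protein with a
significant alignment spanning strictly more than 90% of its length is
"complete"; any other significant alignment is "partial".  Because the
core set is expected to be present in full in any eukaryote, the
fraction recovered estimates the recovered fraction of the whole gene
repertoire, so the total repertoire is extrapolated as
``n_predicted_genes / completeness_fraction``.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable

import pandas as pd

__all__ = [
    "CegMatch",
    "CompletenessReport",
    "RepertoireEstimate",
    "classify_ceg",
    "completeness_report",
    "extrapolate_repertoire",
]

COMPLETE_SPAN_FRACTION = 0.90
DEFAULT_N_CORE = 248


@dataclass
class CegMatch:
    protein_id: str
    aligned_fraction: float
    significant: bool = True


@dataclass
class CompletenessReport:
    n_total: int
    n_complete: int
    n_partial: int  # complete + partial-only, i.e. any significant match
    pct_complete: float
    pct_partial: float


@dataclass
class RepertoireEstimate:
    raw: float
    rounded_to_thousand: int
    completeness_fraction: float


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def classify_ceg(match: CegMatch, *, complete_span: float = COMPLETE_SPAN_FRACTION) -> str:
    """'complete' (span strictly > 90%), 'partial', or 'missing'."""
    if not 0.0 < match.aligned_fraction <= 1.0:
        raise ValueError(f"aligned fraction must be in (0, 1], got {match.aligned_fraction}")
    if not match.significant:
        return "missing"
    return "complete" if match.aligned_fraction > complete_span else "partial"


def completeness_report(
    matches: Iterable[CegMatch] | pd.DataFrame,
    n_total: int = DEFAULT_N_CORE,
) -> CompletenessReport:
    """Tally complete / partial core-gene matches against the full core set.

    Percentages are computed against ``n_total`` and rounded half-up to
    two decimals.
    """
    if isinstance(matches, pd.DataFrame):
        matches = [
            CegMatch(str(r.protein_id), float(r.aligned_fraction), bool(r.significant))
            for r in matches.itertuples()
        ]
    matches = list(matches)
    ids = [m.protein_id for m in matches]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate protein ids in match table")
    if n_total < len(matches):
        raise ValueError("more matches than core proteins")
    classes = [classify_ceg(m) for m in matches]
    n_complete = classes.count("complete")
    n_partial = n_complete + classes.count("partial")
    return CompletenessReport(
        n_total=n_total,
        n_complete=n_complete,
        n_partial=n_partial,
        pct_complete=_round2(100.0 * n_complete / n_total),
        pct_partial=_round2(100.0 * n_partial / n_total),
    )


def extrapolate_repertoire(n_predicted_genes: int, completeness_fraction: float) -> RepertoireEstimate:
    """Scale the predicted gene count by the recovered core-gene fraction.

    ``completeness_fraction`` is typically ``n_partial / n_total`` (any
    recovered match counts as evidence the gene space holds the gene).
    """
    if not 0.0 < completeness_fraction <= 1.0:
        raise ValueError("completeness fraction must be in (0, 1]")
    raw = n_predicted_genes / completeness_fraction
    rounded = int((raw + 500.0) // 1000) * 1000
    return RepertoireEstimate(
        raw=raw, rounded_to_thousand=rounded, completeness_fraction=completeness_fraction
    )
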