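"""Per-term comparison of GO annotation counts between two gene sets.

Each term is tested with a two-sided Fisher's exact test on the 2x2
table ``[[a, totalA - a], [b, totalB - b]]`` (genes annotated with the
term vs not, in each set), followed by Benjamini-Hochberg control of
the false discovery rate across all tested terms.  Direction symbols
follow the over-/under-representation convention: "++" when set A has
the larger proportion, "--" when smaller, and "⌘" for non-significant
terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import fisher_exact as _scipy_fisher
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GoCountTable",
    "EnrichmentResult",
    "fisher_exact_two_sided",
    "bh_fdr",
    "compare_go_sets",
]

SYMBOL_OVER = "++"
SYMBOL_UNDER = "--"
SYMBOL_NS = "⌘"


@dataclass
class GoCountTable:
    """Per-term gene counts for one annotated gene set."""

    label: str
    total: int
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValueError("total annotated genes must be positive")
        for term, c in self.counts.items():
            if not 0 <= c <= self.total:
                raise ValueError(f"count for {term} outside [0, total]")


@dataclass
class EnrichmentResult:
    term: str
    count_a: int
    total_a: int
    count_b: int
    total_b: int
    p: float
    q: float
    significant: bool
    symbol: str


def fisher_exact_two_sided(a: int, total_a: int, b: int, total_b: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, totalA-a], [b, totalB-b]].

    The two-sided p is the sum of hypergeometric probabilities of all
    tables (with the observed margins) no more probable than the
    observed one.
    """
    if min(a, b) < 0 or a > total_a or b > total_b:
        raise ValueError("counts must satisfy 0 <= a <= totalA and 0 <= b <= totalB")
    if total_a <= 0 or total_b <= 0:
        raise ValueError("totals must be positive")
    _, p = _scipy_fisher([[a, total_a - a], [b, total_b - b]], alternative="two-sided")
    return float(min(p, 1.0))


def bh_fdr(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and significance flags.

    Returns ``(q, flags)`` with ``flags[i] == (q[i] <= alpha)``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.empty(0), np.empty(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    flags, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, flags


def compare_go_sets(
    table_a: GoCountTable,
    table_b: GoCountTable,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Fisher + BH-FDR over the union of terms annotated in either set.

    Terms present in neither table would contribute nothing but a
    multiple-testing penalty and are excluded.
    """
    universe = sorted(set(table_a.counts) | set(table_b.counts))
    if not universe:
        raise ValueError("no GO terms annotated in either set")
    a = np.array([table_a.counts.get(t, 0) for t in universe])
    b = np.array([table_b.counts.get(t, 0) for t in universe])
    p = np.array(
        [fisher_exact_two_sided(ai, table_a.total, bi, table_b.total) for ai, bi in zip(a, b)]
    )
    q, flags = bh_fdr(p, alpha=alpha)
    results = []
    for i, term in enumerate(universe):
        if not flags[i]:
            symbol = SYMBOL_NS
        elif a[i] / table_a.total > b[i] / table_b.total:
            symbol = SYMBOL_OVER
        else:
            symbol = SYMBOL_UNDER
        results.append(
            EnrichmentResult(
                term=term,
                count_a=int(a[i]),
                total_a=table_a.total,
                count_b=int(b[i]),
                total_b=table_b.total,
                p=float(p[i]),
                q=float(q[i]),
                significant=bool(flags[i]),
                symbol=symbol,
            )
        )
    return results
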