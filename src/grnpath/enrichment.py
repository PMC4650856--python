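"""Fisher's exact enrichment of candidate genes in DE features.

The question: are the shortest-path candidate genes more often differentially
expressed than the background of their role class? Answered with a 2x2
contingency table and Fisher's exact test (two-sided by default).

Two background conventions are supported and both are reported: the standard
one removes the candidate set from the background row (disjoint rows), while
the "printed" convention leaves the background row as the full class including
the candidates, the way published overlap tables are often typeset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from scipy import stats

__all__ = ["ContingencyTable2x2", "make_table", "table_from_counts",
           "fisher_exact", "enrichment_report"]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows: candidate / background rest; columns: DE / non-DE."""

    a: int  # candidate & DE
    b: int  # candidate & non-DE
    c: int  # rest & DE
    d: int  # rest & non-DE

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> list[list[int]]:
        return [[self.a, self.b], [self.c, self.d]]


def make_table(candidate: Iterable[str], de: Iterable[str],
               background: Iterable[str]) -> ContingencyTable2x2:
    """Contingency table under the disjoint-rows convention.

    ``candidate`` must be a subset of ``background``; the second row is the
    background with the candidates removed.
    """
    cand, de_set, bg = set(candidate), set(de), set(background)
    if not cand <= bg:
        raise ValueError("candidate set must be a subset of the background")
    rest = bg - cand
    return ContingencyTable2x2(
        a=len(cand & de_set),
        b=len(cand - de_set),
        c=len(rest & de_set),
        d=len(rest - de_set),
    )


def table_from_counts(n_candidate: int, n_candidate_de: int,
                      n_background: int, n_background_de: int,
                      disjoint: bool = True) -> ContingencyTable2x2:
    """Build a table from summary counts, as printed in overlap tables.

    With ``disjoint=True`` the candidate counts are subtracted from the
    background row; otherwise the background row is used as printed.
    """
    if n_candidate_de > n_candidate or n_background_de > n_background:
        raise ValueError("DE counts cannot exceed set sizes")
    if disjoint:
        if n_candidate > n_background or n_candidate_de > n_background_de:
            raise ValueError("candidate counts exceed background counts")
        c = n_background_de - n_candidate_de
        d = (n_background - n_background_de) - (n_candidate - n_candidate_de)
    else:
        c = n_background_de
        d = n_background - n_background_de
    return ContingencyTable2x2(n_candidate_de, n_candidate - n_candidate_de, c, d)


def fisher_exact(table: ContingencyTable2x2, alternative: str = "two_sided") -> float:
    """Exact hypergeometric p-value of a 2x2 table.

    ``two_sided`` sums all tables with fixed margins whose probability does not
    exceed the observed one; ``greater`` is the upper enrichment tail.
    Degenerate margins (an empty row or column) give p = 1 by convention.
    """
    if alternative not in ("two_sided", "greater"):
        raise ValueError("alternative must be 'two_sided' or 'greater'")
    if (table.a + table.b == 0 or table.c + table.d == 0
            or table.a + table.c == 0 or table.b + table.d == 0):
        return 1.0
    alt = "two-sided" if alternative == "two_sided" else "greater"
    return float(stats.fisher_exact(table.as_array(), alternative=alt).pvalue)


def odds_ratio(table: ContingencyTable2x2) -> float:
    if table.b == 0 or table.c == 0:
        return float("inf") if table.a * table.d > 0 else float("nan")
    return (table.a * table.d) / (table.b * table.c)


def enrichment_report(candidate: Iterable[str], de: Iterable[str],
                      background: Iterable[str],
                      alternative: str = "two_sided") -> pd.DataFrame:
    """One row per background convention: counts, odds ratio and Fisher p."""
    cand, de_set, bg = set(candidate), set(de), set(background)
    disjoint = make_table(cand, de_set, bg)
    printed = table_from_counts(len(cand), len(cand & de_set),
                                len(bg), len(bg & de_set), disjoint=False)
    rows = []
    for convention, table in (("disjoint_background", disjoint),
                              ("printed_background", printed)):
        rows.append({
            "convention": convention,
            "a": table.a, "b": table.b, "c": table.c, "d": table.d,
            "odds_ratio": odds_ratio(table),
            "p_value": fisher_exact(table, alternative),
            "alternative": alternative,
        })
    return pd.DataFrame(rows)
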