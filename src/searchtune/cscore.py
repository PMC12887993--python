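"""Quartile-rank comparison score (CScore) between two FDR-gated searches.

A test search is compared against a reference search by converting every
validated PSM hyperscore — from both searches — into a rank 1..4 defined by
the quartiles of the *reference* hyperscore distribution, then combining

    CScore = shared + gained - lost

where ``shared`` sums rank changes of PSMs paired by spectrum (shifts of a
single quartile are disregarded as noise), ``gained`` sums the ranks of PSMs
unique to the test search, and ``lost`` sums the ranks of PSMs unique to the
reference. Because only quartile ranks enter, the score is invariant under
any strictly increasing transform applied jointly to all hyperscores, which
is what makes scores from different engines comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .search_core import PSM, SearchResult


@dataclass(frozen=True)
class QuartileRanks:
    """First quartile, median and third quartile of the reference hyperscores."""

    q1: float
    median: float
    q3: float

    def __post_init__(self) -> None:
        if not (self.q1 <= self.median <= self.q3):
            raise ValueError("quartiles must be ordered q1 <= median <= q3")


@dataclass(frozen=True)
class RankedPSM:
    psm: PSM
    rank: int

    def __post_init__(self) -> None:
        if self.rank not in (1, 2, 3, 4):
            raise ValueError("rank must be in 1..4")


@dataclass(frozen=True)
class CScoreBreakdown:
    """The three CScore components and their supporting PSM counts."""

    shared: int
    gained: int
    lost: int
    n_paired: int
    n_gained: int
    n_lost: int

    @property
    def total(self) -> int:
        return self.shared + self.gained - self.lost


def reference_quartiles(reference: list[PSM]) -> QuartileRanks:
    """Quartiles of the reference validated hyperscores (linear interpolation)."""
    if len(reference) < 4:
        raise ValueError(
            f"reference has {len(reference)} validated PSMs; at least 4 are "
            "needed to define quartile sections"
        )
    scores = np.array([p.hyperscore for p in reference])
    q1, med, q3 = np.quantile(scores, [0.25, 0.5, 0.75])
    return QuartileRanks(float(q1), float(med), float(q3))


def rank_hyperscore(score: float, q: QuartileRanks) -> int:
    """Map a hyperscore to its reference quartile rank (1 low .. 4 high).

    Intervals are half-open with rank 4 closed at the top, so for degenerate
    quartiles (all equal) a score at the common value ranks 4.
    """
    if math.isnan(score):
        raise ValueError("cannot rank a NaN hyperscore")
    if score >= q.q3:
        return 4
    if score >= q.median:
        return 3
    if score >= q.q1:
        return 2
    return 1


def shared_score(pairs: list[tuple[int, int]]) -> int:
    """Sum of (test - reference) rank differences over paired PSMs.

    Shifts between adjacent quartiles (|difference| <= 1) are disregarded to
    damp minor score fluctuations.
    """
    total = 0
    for ref_rank, test_rank in pairs:
        d = test_rank - ref_rank
        if abs(d) > 1:
            total += d
    return total


def gained_score(test_unique_ranks: list[int]) -> int:
    """Sum of ranks of PSMs identified only in the test search."""
    return sum(test_unique_ranks)


def lost_score(ref_unique_ranks: list[int]) -> int:
    """Sum of ranks of PSMs identified only in the reference search."""
    return sum(ref_unique_ranks)


def cscore(reference: SearchResult, test: SearchResult) -> CScoreBreakdown:
    """CScore breakdown of a test search against a reference search.

    Both results must be FDR-gated; PSMs are paired by spectrum id and every
    rank is computed against the reference quartiles (the only quartiles
    defined).
    """
    q = reference_quartiles(reference.validated)
    ref_by_id = {p.spectrum_id: p for p in reference.validated}
    test_by_id = {p.spectrum_id: p for p in test.validated}

    pairs = []
    for sid in ref_by_id.keys() & test_by_id.keys():
        pairs.append(
            (
                rank_hyperscore(ref_by_id[sid].hyperscore, q),
                rank_hyperscore(test_by_id[sid].hyperscore, q),
            )
        )
    gained_ranks = [
        rank_hyperscore(p.hyperscore, q)
        for sid, p in test_by_id.items()
        if sid not in ref_by_id
    ]
    lost_ranks = [
        rank_hyperscore(p.hyperscore, q)
        for sid, p in ref_by_id.items()
        if sid not in test_by_id
    ]
    return CScoreBreakdown(
        shared=shared_score(pairs),
        gained=gained_score(gained_ranks),
        lost=lost_score(lost_ranks),
        n_paired=len(pairs),
        n_gained=len(gained_ranks),
        n_lost=len(lost_ranks),
    )
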