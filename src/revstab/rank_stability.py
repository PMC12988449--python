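"""Ranking churn: how risk-factor league tables move between release iterations.

Within each release iteration, risks in a user-chosen comparable set are
ranked by attributable burden (rank 1 = largest).  A risk's rank trajectory
across iterations then shows whether revisions reshuffle the league table —
e.g. a risk dropping from eighth to thirteenth place between consecutive
releases is a rank change of −5.

Iterations in which any member of the risk set lacks a value are dropped
from the ranking entirely (and ledgered) rather than ranked on a shrunken
set, so rank numbers stay comparable across iterations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .alignment import IndexYearSeries

__all__ = [
    "RankTrajectory",
    "RankingResult",
    "rank_within_iteration",
    "rank_trajectories",
    "max_run_length",
    "trajectories_to_frame",
]


def rank_within_iteration(values: Mapping[str, float],
                          name_of: Optional[Mapping[str, str]] = None,
                          ) -> dict[str, int]:
    """Rank risks by value within one iteration; rank 1 is the largest.

    Ties are broken by canonical name (lexicographic), falling back to the
    identifier, so ranking is deterministic.
    """
    if not values:
        raise ValueError("cannot rank an empty value set")
    if any(v < 0 for v in values.values()):
        raise ValueError("burden values must be nonnegative")
    name_of = name_of or {}
    order = sorted(values, key=lambda rid: (-values[rid], name_of.get(rid, rid)))
    return {rid: rank for rank, rid in enumerate(order, start=1)}


def max_run_length(seq: Sequence[int]) -> int:
    """Longest run of identical consecutive entries; 1 for a single entry."""
    if not seq:
        return 0
    best = run = 1
    for prev, cur in zip(seq, seq[1:]):
        run = run + 1 if cur == prev else 1
        best = max(best, run)
    return best


@dataclass
class RankTrajectory:
    """One risk's rank across the iterations in which the full set was rankable."""

    risk_id: str
    metric: str
    ranks: list[tuple[int, int]]  # (iteration, rank), iterations increasing

    @property
    def rank_values(self) -> list[int]:
        return [r for _, r in self.ranks]

    @property
    def max_consecutive_constant(self) -> int:
        return max_run_length(self.rank_values)

    @property
    def range_of_ranks(self) -> int:
        rv = self.rank_values
        return max(rv) - min(rv)

    def rank_changes(self) -> list[tuple[int, int, int]]:
        """(iteration_from, iteration_to, change) with change = old rank − new rank.

        Negative change means the risk dropped in the league table (its rank
        number grew).
        """
        return [
            (it0, it1, r0 - r1)
            for (it0, r0), (it1, r1) in zip(self.ranks, self.ranks[1:])
        ]


@dataclass
class RankingResult:
    """Trajectories over the rankable iterations plus the dropped-iteration ledger."""

    trajectories: list[RankTrajectory]
    dropped_iterations: pd.DataFrame  # columns: metric, iteration, missing_risk_ids


def rank_trajectories(series: Iterable[IndexYearSeries],
                      risk_set: Sequence[str],
                      name_of: Optional[Mapping[str, str]] = None,
                      ) -> RankingResult:
    """Build rank trajectories for a comparable risk set from index-year series.

    Only iterations where *every* member of ``risk_set`` has a value are
    ranked; others are recorded in the dropped-iteration ledger.  Within a
    ranked iteration the ranks are a permutation of 1..K.
    """
    risk_set = list(risk_set)
    if not risk_set:
        raise ValueError("risk_set must be nonempty")
    wanted = set(risk_set)
    by_metric: dict[str, dict[str, dict[int, float]]] = {}
    for s in series:
        if s.risk_id not in wanted:
            continue
        by_metric.setdefault(s.metric, {}).setdefault(s.risk_id, {}).update(
            dict(s.points)
        )

    trajectories: list[RankTrajectory] = []
    dropped_rows = []
    for metric in sorted(by_metric):
        values_of = by_metric[metric]
        iterations = sorted({it for d in values_of.values() for it in d})
        per_risk: dict[str, list[tuple[int, int]]] = {rid: [] for rid in risk_set}
        for it in iterations:
            missing = [rid for rid in risk_set if it not in values_of.get(rid, {})]
            if missing:
                dropped_rows.append(
                    {"metric": metric, "iteration": it,
                     "missing_risk_ids": ";".join(sorted(missing))}
                )
                continue
            ranks = rank_within_iteration(
                {rid: values_of[rid][it] for rid in risk_set}, name_of
            )
            assert sorted(ranks.values()) == list(range(1, len(risk_set) + 1))
            for rid, rank in ranks.items():
                per_risk[rid].append((it, rank))
        for rid in risk_set:
            if per_risk[rid]:
                trajectories.append(RankTrajectory(rid, metric, per_risk[rid]))
    dropped = pd.DataFrame(
        dropped_rows, columns=["metric", "iteration", "missing_risk_ids"]
    )
    return RankingResult(trajectories, dropped)


def trajectories_to_frame(trajectories: Iterable[RankTrajectory]) -> pd.DataFrame:
    """Tidy export: one row per (risk, metric, iteration, rank)."""
    rows = [
        {"risk_id": t.risk_id, "metric": t.metric, "iteration": it, "rank": rank}
        for t in trajectories
        for it, rank in t.ranks
    ]
    return pd.DataFrame(rows, columns=["risk_id", "metric", "iteration", "rank"])
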