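"""Instability statistics: range-to-mean, coefficient of variation, flags, group summaries.

Two dimensionless statistics summarize how much a vector of repeatedly
published values for the same quantity moved across release iterations:

* **R:M** (range to mean): (max − min) / mean.  For two values a ≤ b this is
  2(b − a)/(a + b).  R:M > 1 — the spread exceeds the typical magnitude — is
  flagged as of concern; R:M > 1.5 as extreme instability.
* **CV** (coefficient of variation): sd / mean, with the sample (n−1)
  standard deviation by default.  CV > 0.2 is flagged high, > 0.5 very high.

All threshold comparisons are strict (>, not ≥).  Both statistics are scale
invariant — multiplying every value by a positive constant leaves them
unchanged — so they are comparable across risks whose burdens differ by
orders of magnitude.  They use point estimates only; published uncertainty
around each value is not propagated.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .alignment import IndexYearSeries, MatchedYearPanel

__all__ = [
    "RMFlag",
    "CVFlag",
    "Thresholds",
    "InstabilitySummary",
    "InsufficientDataError",
    "range_to_mean",
    "coefficient_of_variation",
    "classify_instability",
    "summarize_panel",
    "summarize_panels",
    "summaries_to_frame",
    "summarize_group",
    "percent_round_half_up",
]


class InsufficientDataError(ValueError):
    """Fewer than two values: revision spread is undefined."""


class RMFlag(str, enum.Enum):
    LOW = "low"
    CONCERN = "concern"
    EXTREME = "extreme"


class CVFlag(str, enum.Enum):
    LOW = "low"
    HIGH = "high"
    VERY_HIGH = "very_high"


@dataclass(frozen=True)
class Thresholds:
    """Flag cutoffs; comparisons are strict (value must exceed the cutoff)."""

    rm_concern: float = 1.0
    rm_extreme: float = 1.5
    cv_high: float = 0.2
    cv_very_high: float = 0.5

    def __post_init__(self):
        if not (0 < self.rm_concern < self.rm_extreme):
            raise ValueError("require 0 < rm_concern < rm_extreme")
        if not (0 < self.cv_high < self.cv_very_high):
            raise ValueError("require 0 < cv_high < cv_very_high")


def _as_array(values: Sequence[float]) -> np.ndarray:
    arr = np.asarray(list(values), dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D vector of values")
    if len(arr) < 2:
        raise InsufficientDataError(
            f"need at least 2 values to measure revision spread, got {len(arr)}"
        )
    if np.any(arr < 0):
        raise ValueError("burden values must be nonnegative")
    return arr


def range_to_mean(values: Sequence[float], denominator: str = "mean") -> float:
    """(max − min) divided by the central value of the vector.

    Parameters
    ----------
    values
        At least two nonnegative burden values (same risk, metric and
        context; only the release iteration differs).
    denominator
        ``"mean"`` (default, the conventional reading) or ``"median"``.

    Returns 0.0 for an all-zero vector (zero range).
    """
    arr = _as_array(values)
    center = float(np.mean(arr)) if denominator == "mean" else float(np.median(arr))
    if denominator not in ("mean", "median"):
        raise ValueError(f"unknown denominator {denominator!r}")
    rng = float(arr.max() - arr.min())
    if center == 0.0:
        # nonnegative values with zero mean are all zero, hence zero range
        assert rng == 0.0
        return 0.0
    return rng / center


def coefficient_of_variation(values: Sequence[float], ddof: int = 1) -> float:
    """Standard deviation divided by mean; 0 for a constant vector.

    ``ddof=1`` (sample standard deviation) is the default; the population
    form is available via ``ddof=0``.  With the small panels typical here
    (n ≤ 8) the choice is material, so it is explicit.
    """
    arr = _as_array(values)
    if arr.max() == arr.min():
        # exact zero for constant vectors: the accumulated-mean rounding in a
        # two-pass sd would otherwise leak ~1e-16 into a flagless statistic
        return 0.0
    mean = float(arr.mean())
    return float(arr.std(ddof=ddof)) / mean


def classify_instability(rm: float, cv: Optional[float] = None,
                         thresholds: Optional[Thresholds] = None,
                         ) -> tuple[RMFlag, Optional[CVFlag]]:
    """Map R:M (and optionally CV) onto categorical instability flags.

    Cutoffs are exclusive: R:M of exactly 1.0 is still ``low``, CV of exactly
    0.2 is still ``low``.
    """
    if rm < 0:
        raise ValueError("R:M is nonnegative by construction")
    t = thresholds or Thresholds()
    if rm > t.rm_extreme:
        rm_flag = RMFlag.EXTREME
    elif rm > t.rm_concern:
        rm_flag = RMFlag.CONCERN
    else:
        rm_flag = RMFlag.LOW
    cv_flag: Optional[CVFlag] = None
    if cv is not None:
        if cv < 0:
            raise ValueError("CV is nonnegative by construction")
        if cv > t.cv_very_high:
            cv_flag = CVFlag.VERY_HIGH
        elif cv > t.cv_high:
            cv_flag = CVFlag.HIGH
        else:
            cv_flag = CVFlag.LOW
    return rm_flag, cv_flag


@dataclass
class InstabilitySummary:
    """Full numeric and categorical summary of one revision panel."""

    risk_id: str
    metric: str
    context: str  # "index_year" or "matched_year:<year>"
    n: int
    min: float
    max: float
    mean: float
    median: float
    sd: float
    rm: float
    cv: float
    rm_flag: RMFlag
    cv_flag: CVFlag


Panel = Union[IndexYearSeries, MatchedYearPanel]


def summarize_panel(panel: Panel,
                    thresholds: Optional[Thresholds] = None,
                    cv_ddof: int = 1,
                    rm_denominator: str = "mean") -> InstabilitySummary:
    """Compute the instability summary of one index-year series or matched-year panel."""
    values = panel.values
    arr = _as_array(values)
    rm = range_to_mean(values, denominator=rm_denominator)
    cv = coefficient_of_variation(values, ddof=cv_ddof)
    rm_flag, cv_flag = classify_instability(rm, cv, thresholds)
    context = (
        f"matched_year:{panel.year}" if isinstance(panel, MatchedYearPanel) else "index_year"
    )
    return InstabilitySummary(
        risk_id=panel.risk_id,
        metric=panel.metric,
        context=context,
        n=len(arr),
        min=float(arr.min()),
        max=float(arr.max()),
        mean=float(arr.mean()),
        median=float(np.median(arr)),
        sd=float(arr.std(ddof=cv_ddof)),
        rm=rm,
        cv=cv,
        rm_flag=rm_flag,
        cv_flag=cv_flag,
    )


def summarize_panels(panels: Iterable[Panel],
                     thresholds: Optional[Thresholds] = None,
                     cv_ddof: int = 1,
                     rm_denominator: str = "mean",
                     ) -> tuple[list[InstabilitySummary], pd.DataFrame]:
    """Summarize each panel; panels with n < 2 are skipped and ledgered, never zero-filled."""
    summaries: list[InstabilitySummary] = []
    skipped: list[dict] = []
    for p in panels:
        if len(p) < 2:
            context = f"matched_year:{p.year}" if isinstance(p, MatchedYearPanel) else "index_year"
            skipped.append(
                {"risk_id": p.risk_id, "metric": p.metric, "context": context,
                 "reason": "fewer-than-2-values", "n": len(p)}
            )
            continue
        summaries.append(
            summarize_panel(p, thresholds=thresholds, cv_ddof=cv_ddof,
                            rm_denominator=rm_denominator)
        )
    ledger = pd.DataFrame(skipped, columns=["risk_id", "metric", "context", "reason", "n"])
    return summaries, ledger


def summaries_to_frame(summaries: Iterable[InstabilitySummary]) -> pd.DataFrame:
    """Tidy export: one row per (risk, metric, context) summary."""
    rows = [
        {
            "risk_id": s.risk_id, "metric": s.metric, "context": s.context,
            "n": s.n, "min": s.min, "max": s.max, "mean": s.mean,
            "median": s.median, "sd": s.sd, "rm": s.rm, "cv": s.cv,
            "rm_flag": s.rm_flag.value, "cv_flag": s.cv_flag.value,
        }
        for s in summaries
    ]
    return pd.DataFrame(
        rows,
        columns=["risk_id", "metric", "context", "n", "min", "max", "mean",
                 "median", "sd", "rm", "cv", "rm_flag", "cv_flag"],
    )


def percent_round_half_up(numerator: int, denominator: int) -> int:
    """Integer percent with round-half-up, the convention used in report text.

    17 of 34 → 50; 145 of 675 → 21 (21.48 rounds down); 0.5 rounds up.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    pct = Decimal(numerator) * 100 / Decimal(denominator)
    return int(pct.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def summarize_group(summaries: Iterable[InstabilitySummary],
                    group_of: dict[str, str],
                    thresholds: Optional[Thresholds] = None,
                    ) -> pd.DataFrame:
    """Aggregate instability flags per risk group and metric.

    Parameters
    ----------
    summaries
        Per-risk summaries (one context: do not mix index-year and
        matched-year summaries in a single call unless intended).
    group_of
        Maps risk_id → grouping label (a level-1 group such as
        ``behavioral``, or a level-2 parent identifier).  Risks missing from
        the mapping are grouped under ``"ungrouped"``.

    Returns one row per (group, metric): risk/panel count, count and
    proportion with R:M above the concern cutoff, median and range of R:M,
    median CV, and proportions of CV above the high and very-high cutoffs.
    ``pct_rm_flagged`` is the integer round-half-up percent used in report
    prose.
    """
    t = thresholds or Thresholds()
    df = summaries_to_frame(summaries)
    if df.empty:
        raise ValueError("no summaries to aggregate")
    df["grouping"] = df["risk_id"].map(group_of).fillna("ungrouped")
    rows = []
    for (grouping, metric), g in df.groupby(["grouping", "metric"], sort=True):
        n = len(g)
        n_rm = int((g["rm"] > t.rm_concern).sum())
        rows.append(
            {
                "grouping": grouping,
                "metric": metric,
                "n_risks": n,
                "n_flagged_rm_gt1": n_rm,
                "proportion_rm_gt1": n_rm / n,
                "pct_rm_flagged": percent_round_half_up(n_rm, n),
                "median_rm": float(g["rm"].median()),
                "rm_min": float(g["rm"].min()),
                "rm_max": float(g["rm"].max()),
                "median_cv": float(g["cv"].median()),
                "proportion_cv_high": float((g["cv"] > t.cv_high).mean()),
                "proportion_cv_very_high": float((g["cv"] > t.cv_very_high).mean()),
            }
        )
    return pd.DataFrame(rows)
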