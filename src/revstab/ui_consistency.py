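"""Consistency of later point estimates with earlier 95% uncertainty intervals.

A release's published 95% uncertainty interval (UI) is a statement about
where the quantity plausibly lies.  If the next release's point estimate for
the very same (risk, metric, stratum, year) cell routinely lands outside the
previous release's UI, the published uncertainty understated the true
revision uncertainty.  This module classifies each later point against the
earlier interval (below / within / above, closed interval) and tabulates the
per-risk and aggregate proportions.

Comparisons are cell-wise at the finest available stratification
(sex × location × cause group × year); cells missing the reference UI or the
comparison point are ledgered, not counted, so denominators are data-driven.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .estimates import EstimateTable, IntegrityError

__all__ = [
    "Verdict",
    "ComparisonResult",
    "classify_point_vs_ui",
    "compare_iterations",
    "summarize_coverage",
]

STRATUM_COLS = ["sex", "location", "cause_group"]
CELL_KEY = ["risk_id", "metric"] + STRATUM_COLS + ["year"]


class Verdict(str, enum.Enum):
    BELOW = "below"
    WITHIN = "within"
    ABOVE = "above"


def classify_point_vs_ui(point: float, lower: float, upper: float) -> Verdict:
    """Closed-interval containment: a point on the boundary counts as within."""
    if lower > upper:
        raise ValueError(f"inverted interval: lower {lower} > upper {upper}")
    if point < lower:
        return Verdict.BELOW
    if point > upper:
        return Verdict.ABOVE
    return Verdict.WITHIN


@dataclass
class ComparisonResult:
    """Cell-wise verdicts plus the ledger of cells excluded for missing data.

    ``comparisons`` has one row per overlapping cell with columns
    ``risk_id, metric, sex, location, cause_group, year,
    reference_iteration, comparison_iteration, ui_lower, ui_upper,
    point, verdict``; ``ledger`` records cells present on one side only or
    lacking a reference UI.
    """

    comparisons: pd.DataFrame
    ledger: pd.DataFrame

    def __len__(self) -> int:
        return len(self.comparisons)


def compare_iterations(table: EstimateTable,
                       reference_iteration: int,
                       comparison_iteration: int) -> ComparisonResult:
    """Classify every comparison-iteration point against the reference UI.

    Restricted to cells where the reference iteration published a UI and the
    comparison iteration published a point estimate for the same
    (risk, metric, sex, location, cause group, year).
    """
    if not table.harmonized:
        raise IntegrityError("compare_iterations requires a harmonized table")
    if comparison_iteration <= reference_iteration:
        raise ValueError(
            "comparison iteration must be later than the reference iteration"
        )
    df = table.df
    ref = df[df["iteration"] == reference_iteration]
    comp = df[df["iteration"] == comparison_iteration]

    ref_cells = ref[CELL_KEY + ["ui_lower", "ui_upper"]]
    comp_cells = comp[CELL_KEY + ["value"]].rename(columns={"value": "point"})
    merged = ref_cells.merge(comp_cells, on=CELL_KEY, how="outer", indicator=True)

    ledger_rows = []
    only_ref = merged["_merge"] == "left_only"
    only_comp = merged["_merge"] == "right_only"
    no_ui = (merged["_merge"] == "both") & merged["ui_lower"].isna()
    for mask, reason in ((only_ref, "missing-comparison-point"),
                         (only_comp, "missing-reference-cell"),
                         (no_ui, "reference-ui-absent")):
        sub = merged.loc[mask, CELL_KEY].copy()
        sub["reason"] = reason
        ledger_rows.append(sub)
    ledger = pd.concat(ledger_rows, ignore_index=True)

    ok = merged[(merged["_merge"] == "both") & merged["ui_lower"].notna()].copy()
    if (ok["ui_lower"] > ok["ui_upper"]).any():
        raise ValueError("inverted reference interval encountered")
    ok["verdict"] = Verdict.WITHIN.value
    ok.loc[ok["point"] < ok["ui_lower"], "verdict"] = Verdict.BELOW.value
    ok.loc[ok["point"] > ok["ui_upper"], "verdict"] = Verdict.ABOVE.value
    ok["reference_iteration"] = reference_iteration
    ok["comparison_iteration"] = comparison_iteration
    cols = CELL_KEY + ["reference_iteration", "comparison_iteration",
                       "ui_lower", "ui_upper", "point", "verdict"]
    comparisons = ok[cols].sort_values(CELL_KEY).reset_index(drop=True)
    if comparisons.empty:
        import warnings

        warnings.warn(
            f"no overlapping cells with UIs between iterations "
            f"{reference_iteration} and {comparison_iteration}",
            stacklevel=2,
        )
    return ComparisonResult(comparisons, ledger)


def summarize_coverage(result: ComparisonResult,
                       per: tuple[str, ...] = ("risk_id", "metric"),
                       ) -> pd.DataFrame:
    """Count verdicts per risk and in aggregate; order by proportion outside, descending.

    Each row satisfies ``n_below + n_within + n_above == n_total`` and
    ``proportion_outside = (n_below + n_above) / n_total``.  An ``__all__``
    aggregate row per metric is appended.
    """
    df = result.comparisons
    if df.empty:
        raise ValueError("no comparisons to summarize")

    def _counts(g: pd.DataFrame) -> dict:
        n_below = int((g["verdict"] == Verdict.BELOW.value).sum())
        n_within = int((g["verdict"] == Verdict.WITHIN.value).sum())
        n_above = int((g["verdict"] == Verdict.ABOVE.value).sum())
        n_total = len(g)
        return {
            "n_total": n_total,
            "n_below": n_below,
            "n_within": n_within,
            "n_above": n_above,
            "proportion_outside": (n_below + n_above) / n_total,
        }

    pair_cols = ["reference_iteration", "comparison_iteration"]
    rows = []
    for key, g in df.groupby(list(per) + pair_cols, sort=True):
        row = dict(zip(list(per) + pair_cols, key))
        row.update(_counts(g))
        rows.append(row)
    for key, g in df.groupby(["metric"] + pair_cols, sort=True):
        row = {"risk_id": "__all__", "metric": key[0],
               "reference_iteration": key[1], "comparison_iteration": key[2]}
        row.update(_counts(g))
        rows.append(row)
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["proportion_outside", "n_total"], ascending=[False, False]
    ).reset_index(drop=True)
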