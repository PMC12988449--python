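"""Construct the analytic panels: index-year series, matched-year panels, time series.

Three views of a harmonized estimate table drive the downstream statistics:

* **Index-year series** — for each (risk, metric), the value each release
  iteration published for its *own* final estimation year (its index year):
  the 2010 release's estimate for 2010, the 2013 release's for 2013, and so
  on.  Instability here mixes genuine temporal change with revision noise.
* **Matched-year panels** — for each (risk, metric, calendar year), every
  value published for that same year by successive iterations: the original
  estimate plus its later revisions.  The only thing that differs across the
  panel is the release, so spread here is pure revision instability.
* **Time-series panels** — per (risk, metric, iteration, stratum) full
  year-by-year series with uncertainty intervals, the input to the
  point-vs-prior-interval consistency analysis.

No value is ever imputed: iterations that did not publish a cell are simply
absent, and panel sample sizes are recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .estimates import EstimateTable, IntegrityError

__all__ = [
    "DEFAULT_ITERATIONS",
    "IterationIndexMap",
    "IndexYearSeries",
    "MatchedYearPanel",
    "TimeSeriesPanel",
    "build_index_year_series",
    "build_matched_year_panels",
    "build_time_series_panels",
    "series_to_frame",
    "panels_to_frame",
]

#: release iterations covered by the revision analysis
DEFAULT_ITERATIONS = (2010, 2013, 2015, 2016, 2017, 2019, 2021, 2023)

#: default analysis stratum: overall totals
GLOBAL_STRATUM = {"sex": "both", "location": "global", "cause_group": "all"}


@dataclass(frozen=True)
class IterationIndexMap:
    """Maps each release iteration to its index year (its final estimation year)."""

    entries: Mapping[int, int] = field(
        default_factory=lambda: {it: it for it in DEFAULT_ITERATIONS}
    )

    def __post_init__(self):
        for iteration, index_year in self.entries.items():
            if index_year > iteration:
                raise IntegrityError(
                    f"index year {index_year} exceeds iteration {iteration}"
                )

    def index_year(self, iteration: int) -> Optional[int]:
        return self.entries.get(iteration)


@dataclass
class IndexYearSeries:
    """Values each iteration published for its own index year, one (risk, metric)."""

    risk_id: str
    metric: str
    points: list[tuple[int, float]]  # (iteration, value), iterations increasing

    @property
    def iterations(self) -> list[int]:
        return [it for it, _ in self.points]

    @property
    def values(self) -> list[float]:
        return [v for _, v in self.points]

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class MatchedYearPanel:
    """All values published for one (risk, metric, calendar year) across iterations."""

    risk_id: str
    metric: str
    year: int
    points: list[tuple[int, float]]  # (iteration, value), iterations increasing

    @property
    def iterations(self) -> list[int]:
        return [it for it, _ in self.points]

    @property
    def values(self) -> list[float]:
        return [v for _, v in self.points]

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class TimeSeriesPanel:
    """One iteration's full series for a (risk, metric, stratum), years ascending."""

    risk_id: str
    metric: str
    iteration: int
    sex: str
    location: str
    cause_group: str
    series: pd.DataFrame  # columns: year, value, ui_lower, ui_upper


def _default_stratum_slice(df: pd.DataFrame,
                           stratum: Optional[Mapping[str, str]]) -> pd.DataFrame:
    stratum = GLOBAL_STRATUM if stratum is None else stratum
    mask = pd.Series(True, index=df.index)
    for col, val in stratum.items():
        mask &= df[col] == val
    return df[mask]


def build_index_year_series(table: EstimateTable,
                            index_map: Optional[IterationIndexMap] = None,
                            stratum: Optional[Mapping[str, str]] = None,
                            ) -> list[IndexYearSeries]:
    """One series per (risk, metric): each iteration's estimate for its index year.

    Iterations lacking an index-year record for a risk are simply absent from
    its series; nothing is interpolated.
    """
    if not table.harmonized:
        raise IntegrityError("build_index_year_series requires a harmonized table")
    index_map = index_map or IterationIndexMap()
    df = _default_stratum_slice(table.df, stratum)
    idx_years = df["iteration"].map(index_map.index_year)
    on_index = df[df["year"] == idx_years]
    out: list[IndexYearSeries] = []
    for (risk_id, metric), g in on_index.groupby(["risk_id", "metric"], sort=True):
        g = g.sort_values("iteration")
        out.append(
            IndexYearSeries(risk_id, metric, list(zip(g["iteration"], g["value"])))
        )
    return out


def build_matched_year_panels(table: EstimateTable,
                              min_iterations: int = 2,
                              stratum: Optional[Mapping[str, str]] = None,
                              ) -> list[MatchedYearPanel]:
    """One panel per (risk, metric, year) estimated by ≥ ``min_iterations`` releases.

    Panels hold the original estimate for a calendar year and every revision
    of it; years are never pooled.  Output is invariant to input row order.
    """
    if min_iterations < 2:
        raise ValueError("min_iterations must be ≥ 2: a single value has no revision spread")
    if not table.harmonized:
        raise IntegrityError("build_matched_year_panels requires a harmonized table")
    df = _default_stratum_slice(table.df, stratum)
    out: list[MatchedYearPanel] = []
    for (risk_id, metric, year), g in df.groupby(["risk_id", "metric", "year"], sort=True):
        if g["iteration"].nunique() < min_iterations:
            continue
        g = g.sort_values("iteration")
        out.append(
            MatchedYearPanel(risk_id, metric, int(year),
                             list(zip(g["iteration"], g["value"])))
        )
    return out


def build_time_series_panels(table: EstimateTable,
                             risk_filter: Optional[Iterable[str]] = None,
                             iterations: Optional[Iterable[int]] = None,
                             strata: Optional[Mapping[str, Sequence[str]]] = None,
                             ) -> list[TimeSeriesPanel]:
    """Full per-year series, one panel per (risk, metric, iteration, stratum).

    ``strata`` restricts stratum columns to the listed values; an empty/None
    filter keeps all strata.  Years are sorted within each panel regardless
    of input order.
    """
    if not table.harmonized:
        raise IntegrityError("build_time_series_panels requires a harmonized table")
    df = table.df
    if risk_filter is not None:
        df = df[df["risk_id"].isin(list(risk_filter))]
    if iterations is not None:
        df = df[df["iteration"].isin(list(iterations))]
    if strata:
        for col, vals in strata.items():
            df = df[df[col].isin(list(vals))]
    out: list[TimeSeriesPanel] = []
    keys = ["risk_id", "metric", "iteration", "sex", "location", "cause_group"]
    for key, g in df.groupby(keys, sort=True):
        series = (
            g.sort_values("year")[["year", "value", "ui_lower", "ui_upper"]]
            .reset_index(drop=True)
        )
        out.append(TimeSeriesPanel(*key, series=series))
    return out


def series_to_frame(series: Iterable[IndexYearSeries]) -> pd.DataFrame:
    """Tidy export: one row per (risk, metric, iteration, value)."""
    rows = [
        {"risk_id": s.risk_id, "metric": s.metric, "iteration": it, "value": v}
        for s in series
        for it, v in s.points
    ]
    return pd.DataFrame(rows, columns=["risk_id", "metric", "iteration", "value"])


def panels_to_frame(panels: Iterable[MatchedYearPanel]) -> pd.DataFrame:
    """Tidy export: one row per panel value."""
    rows = [
        {"risk_id": p.risk_id, "metric": p.metric, "year": p.year,
         "iteration": it, "value": v}
        for p in panels
        for it, v in p.points
    ]
    return pd.DataFrame(rows, columns=["risk_id", "metric", "year", "iteration", "value"])
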