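"""Model/Results interface tying the pipeline stages together.

:class:`RevisionInstability` is constructed from a harmonized estimate table
(or, via :meth:`RevisionInstability.from_csv`, from the canonical CSV files)
and holds the analysis configuration — iteration index map, flag thresholds,
uncertainty-interval comparison pairs, optional rank set.  Its :meth:`fit`
executes align → instability metrics → interval coverage → rankings and
returns a :class:`RevisionInstabilityResults` carrying every table the
analysis produces, with a :meth:`~RevisionInstabilityResults.summary` text
report and a CSV bundle writer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import alignment, metrics, rank_stability, ui_consistency
from .alignment import IterationIndexMap
from .estimates import (
    EstimateTable,
    FilterRules,
    HarmonizationMap,
    RiskHierarchy,
    filter_analysis_set,
    harmonize,
    read_estimates_csv,
)
from .metrics import Thresholds

__all__ = ["RevisionInstability", "RevisionInstabilityResults"]

#: default point-vs-prior-interval comparisons: each release against the
#: previous one that published intervals
DEFAULT_UI_PAIRS = ((2019, 2021), (2021, 2023))


class RevisionInstability:
    """Revision-instability analysis of a multi-release estimate table.

    Parameters
    ----------
    table
        Harmonized, analysis-filtered :class:`EstimateTable`.
    index_map
        Release-iteration → index-year map (defaults to iteration = index
        year for the 2010–2023 releases).
    thresholds
        Flag cutoffs for R:M and CV.
    ui_pairs
        (reference, comparison) iteration pairs for the interval-coverage
        analysis; pairs without overlapping UI cells are skipped with a note
        in the ledger.
    rank_risk_set
        Optional comparable risk set to rank within each iteration; ``None``
        disables the ranking analysis.
    cv_ddof, rm_denominator, min_iterations
        Statistic conventions passed through to the metric layer.
    """

    def __init__(self, table: EstimateTable, *,
                 index_map: Optional[IterationIndexMap] = None,
                 thresholds: Optional[Thresholds] = None,
                 ui_pairs: Sequence[tuple[int, int]] = DEFAULT_UI_PAIRS,
                 rank_risk_set: Optional[Sequence[str]] = None,
                 risk_names: Optional[Mapping[str, str]] = None,
                 cv_ddof: int = 1,
                 rm_denominator: str = "mean",
                 min_iterations: int = 2):
        self.table = table
        self.index_map = index_map or IterationIndexMap()
        self.thresholds = thresholds or Thresholds()
        self.ui_pairs = tuple(ui_pairs)
        self.rank_risk_set = list(rank_risk_set) if rank_risk_set else None
        self.risk_names = dict(risk_names or {})
        self.cv_ddof = cv_ddof
        self.rm_denominator = rm_denominator
        self.min_iterations = min_iterations
        self._ingest_ledgers: dict[str, pd.DataFrame] = {}
        self._n_input_records: Optional[int] = None

    @classmethod
    def from_csv(cls, estimates_path: str | Path,
                 harmonization_path: str | Path,
                 hierarchy_path: str | Path,
                 filter_rules: Optional[FilterRules] = None,
                 schema: Optional[Mapping[str, str]] = None,
                 **kwargs) -> "RevisionInstability":
        """Build the model from canonical CSV inputs: ingest, harmonize, filter."""
        hierarchy = RiskHierarchy.from_csv(hierarchy_path)
        hmap = HarmonizationMap.from_csv(harmonization_path, hierarchy=hierarchy)
        raw = read_estimates_csv(estimates_path, schema=schema)
        harm = harmonize(raw, hmap, hierarchy=hierarchy)
        filt = filter_analysis_set(harm.table, filter_rules)
        names = {d.risk_id: d.canonical_name for d in hierarchy}
        model = cls(filt.table, risk_names=names, **kwargs)
        model._ingest_ledgers = {"unmapped": harm.unmapped, "filtered": filt.ledger}
        model._n_input_records = len(raw)
        return model

    def fit(self) -> "RevisionInstabilityResults":
        """Run the full analysis and collect results."""
        df = self.table.df
        group_of = (
            dict(zip(df["risk_id"], df["group"])) if "group" in df.columns else {}
        )

        index_series = alignment.build_index_year_series(self.table, self.index_map)
        matched_panels = alignment.build_matched_year_panels(
            self.table, min_iterations=self.min_iterations
        )
        kw = dict(thresholds=self.thresholds, cv_ddof=self.cv_ddof,
                  rm_denominator=self.rm_denominator)
        index_summaries, index_skipped = metrics.summarize_panels(index_series, **kw)
        matched_summaries, matched_skipped = metrics.summarize_panels(matched_panels, **kw)

        group_summaries = {}
        if group_of:
            if index_summaries:
                group_summaries["index_year"] = metrics.summarize_group(
                    index_summaries, group_of, self.thresholds
                )
            if matched_summaries:
                group_summaries["matched_year"] = metrics.summarize_group(
                    matched_summaries, group_of, self.thresholds
                )

        comparisons = []
        coverage_frames = []
        ui_ledgers = []
        available = set(df["iteration"].unique())
        for ref, comp in self.ui_pairs:
            if ref not in available or comp not in available:
                ui_ledgers.append(pd.DataFrame(
                    [{"reason": f"iteration-pair-absent:{ref}-{comp}"}]
                ))
                continue
            res = ui_consistency.compare_iterations(self.table, ref, comp)
            ui_ledgers.append(res.ledger)
            if len(res):
                comparisons.append(res.comparisons)
                coverage_frames.append(ui_consistency.summarize_coverage(res))

        ranking = None
        if self.rank_risk_set:
            ranking = rank_stability.rank_trajectories(
                index_series, self.rank_risk_set, self.risk_names
            )

        return RevisionInstabilityResults(
            model=self,
            index_series=index_series,
            matched_panels=matched_panels,
            index_summaries=index_summaries,
            matched_summaries=matched_summaries,
            group_summaries=group_summaries,
            ui_comparisons=(
                pd.concat(comparisons, ignore_index=True) if comparisons
                else pd.DataFrame()
            ),
            coverage=(
                pd.concat(coverage_frames, ignore_index=True) if coverage_frames
                else pd.DataFrame()
            ),
            ranking=ranking,
            skipped_panels=pd.concat(
                [index_skipped, matched_skipped], ignore_index=True
            ),
            ui_ledger=(
                pd.concat(ui_ledgers, ignore_index=True) if ui_ledgers
                else pd.DataFrame()
            ),
            ingest_ledgers=dict(self._ingest_ledgers),
        )


@dataclass
class RevisionInstabilityResults:
    """Everything the revision-instability analysis produced."""

    model: RevisionInstability
    index_series: list
    matched_panels: list
    index_summaries: list
    matched_summaries: list
    group_summaries: dict[str, pd.DataFrame]
    ui_comparisons: pd.DataFrame
    coverage: pd.DataFrame
    ranking: Optional[rank_stability.RankingResult]
    skipped_panels: pd.DataFrame
    ui_ledger: pd.DataFrame
    ingest_ledgers: dict[str, pd.DataFrame] = field(default_factory=dict)

    # -- derived views -------------------------------------------------
    @property
    def index_summary_frame(self) -> pd.DataFrame:
        return metrics.summaries_to_frame(self.index_summaries)

    @property
    def matched_summary_frame(self) -> pd.DataFrame:
        return metrics.summaries_to_frame(self.matched_summaries)

    def heatmap_matrix(self, metric: str = "deaths") -> pd.DataFrame:
        """Risks × contexts matrix of R:M values (index year, then matched years)."""
        frames = [self.index_summary_frame, self.matched_summary_frame]
        df = pd.concat(frames, ignore_index=True)
        df = df[df["metric"] == metric]
        if df.empty:
            return pd.DataFrame()
        return df.pivot(index="risk_id", columns="context", values="rm")

    # -- reporting -----------------------------------------------------
    def summary(self) -> str:
        """Plain-text analysis report."""
        lines = ["Revision instability analysis", "=" * 31, ""]
        for label, frame in (("Index-year", self.index_summary_frame),
                             ("Matched-year", self.matched_summary_frame)):
            if frame.empty:
                continue
            lines.append(f"{label} panels: {len(frame)}")
            for metric_name, g in frame.groupby("metric"):
                n = len(g)
                n_rm = int((g["rm"] > self.model.thresholds.rm_concern).sum())
                n_cv = int((g["cv"] > self.model.thresholds.cv_high).sum())
                lines.append(
                    f"  {metric_name}: median R:M {g['rm'].median():.2f} "
                    f"(range {g['rm'].min():.2f}-{g['rm'].max():.2f}); "
                    f"R:M>{self.model.thresholds.rm_concern:g}: {n_rm} of {n} "
                    f"({metrics.percent_round_half_up(n_rm, n)}%); "
                    f"CV>{self.model.thresholds.cv_high:g}: {n_cv} of {n} "
                    f"({metrics.percent_round_half_up(n_cv, n)}%)"
                )
            lines.append("")
        if not self.coverage.empty:
            agg = self.coverage[self.coverage["risk_id"] == "__all__"]
            lines.append("Point vs prior 95% interval:")
            for row in agg.itertuples():
                n_out = row.n_below + row.n_above
                lines.append(
                    f"  {row.metric}, {row.comparison_iteration} vs "
                    f"{row.reference_iteration} UI: {n_out} of {row.n_total} outside "
                    f"({metrics.percent_round_half_up(n_out, row.n_total)}%)"
                )
            lines.append("")
        if self.ranking is not None and self.ranking.trajectories:
            worst = max(self.ranking.trajectories, key=lambda t: t.range_of_ranks)
            stable = max(
                t.max_consecutive_constant for t in self.ranking.trajectories
            )
            lines.append(
                f"Rankings: {len(self.ranking.trajectories)} trajectories; "
                f"largest rank range {worst.range_of_ranks} ({worst.risk_id}); "
                f"longest constant run {stable} iterations"
            )
            lines.append("")
        return "\n".join(lines)

    def record_accounting(self) -> dict[str, int]:
        """Input / analyzed / ledgered record counts for conservation checks."""
        analyzed = len(self.model.table)
        ledgered = 0
        unmapped = self.ingest_ledgers.get("unmapped")
        if unmapped is not None and len(unmapped):
            ledgered += int(unmapped["n_records"].sum())
        filtered = self.ingest_ledgers.get("filtered")
        if filtered is not None and len(filtered):
            ledgered += int(filtered["n_records"].sum())
        return {"analyzed": analyzed, "ledgered": ledgered,
                "total": analyzed + ledgered}

    def to_csv_bundle(self, outdir: str | Path) -> dict[str, Path]:
        """Write every result table as tidy CSV; returns name → path."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written: dict[str, Path] = {}

        def _write(name: str, frame: pd.DataFrame) -> None:
            path = outdir / f"{name}.csv"
            frame.to_csv(path, index=False)
            written[name] = path

        _write("instability_index_year", self.index_summary_frame)
        _write("instability_matched_year", self.matched_summary_frame)
        for context, frame in self.group_summaries.items():
            _write(f"group_summary_{context}", frame)
        hm = self.heatmap_matrix("deaths")
        if not hm.empty:
            _write("rm_heatmap_deaths", hm.reset_index())
        cvdist = pd.concat(
            [self.index_summary_frame.assign(panel="index_year"),
             self.matched_summary_frame.assign(panel="matched_year")],
            ignore_index=True,
        )[["panel", "risk_id", "metric", "context", "n", "cv"]]
        _write("cv_distribution", cvdist)
        if not self.ui_comparisons.empty:
            _write("ui_comparisons", self.ui_comparisons)
            _write("ui_coverage", self.coverage)
        if self.ranking is not None:
            _write("rank_trajectories",
                   rank_stability.trajectories_to_frame(self.ranking.trajectories))
            _write("rank_dropped_iterations", self.ranking.dropped_iterations)
        _write("skipped_panels", self.skipped_panels)
        if not self.ui_ledger.empty:
            _write("ui_ledger", self.ui_ledger)
        for name, frame in self.ingest_ledgers.items():
            _write(f"ledger_{name}", frame)
        return written
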