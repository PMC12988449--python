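"""Pipeline orchestration: run configuration, report bundle, manifest.

A :class:`RunConfig` (YAML file plus overrides) names the three canonical
CSV inputs — estimates, harmonization map, risk hierarchy — and every
analysis knob (index map, thresholds, filter rules, interval-comparison
pairs, rank set).  :func:`run_pipeline` executes the full analysis and
writes the report bundle: instability summary tables, the R:M heatmap
matrix, the CV distribution, interval-coverage tables, rank trajectories,
exclusion ledgers, and a manifest recording the config echo, input and
output checksums and package versions.  Re-running an unchanged config
reproduces identical checksums.

Every threshold is a config value with the conventional default; nothing is
hard-coded in the statistics layer.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .alignment import DEFAULT_ITERATIONS, IterationIndexMap
from .estimates import DEFAULT_EXCLUDED_RISK_IDS, FilterRules
from .metrics import Thresholds
from .model import DEFAULT_UI_PAIRS, RevisionInstability

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

logger = logging.getLogger("revstab")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Full configuration of one analysis run."""

    estimates: str
    harmonization: str
    hierarchy: str
    out_dir: str = "results"
    index_map: dict = field(
        default_factory=lambda: {it: it for it in DEFAULT_ITERATIONS}
    )
    drop_levels: tuple[int, ...] = (4,)
    exclude_risk_ids: tuple[str, ...] = DEFAULT_EXCLUDED_RISK_IDS
    min_iterations: int = 2
    rm_concern: float = 1.0
    rm_extreme: float = 1.5
    cv_high: float = 0.2
    cv_very_high: float = 0.5
    cv_ddof: int = 1
    rm_denominator: str = "mean"
    ui_pairs: tuple[tuple[int, int], ...] = DEFAULT_UI_PAIRS
    rank_risk_set: Optional[tuple[str, ...]] = None
    log_level: str = "INFO"

    def __post_init__(self):
        # materialize YAML lists as tuples for hashability / config echo
        self.drop_levels = tuple(self.drop_levels)
        self.exclude_risk_ids = tuple(self.exclude_risk_ids)
        self.ui_pairs = tuple(tuple(p) for p in self.ui_pairs)
        if self.rank_risk_set is not None:
            self.rank_risk_set = tuple(self.rank_risk_set)
        self.index_map = {int(k): int(v) for k, v in self.index_map.items()}

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def thresholds(self) -> Thresholds:
        return Thresholds(self.rm_concern, self.rm_extreme,
                          self.cv_high, self.cv_very_high)

    def filter_rules(self) -> FilterRules:
        return FilterRules(self.drop_levels, self.exclude_risk_ids,
                           self.min_iterations)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute ingest → harmonize → filter → align → metrics → coverage → ranks.

    Writes the report bundle and manifest under ``config.out_dir`` and
    returns the manifest.  Any stage error aborts with a stage-named
    :class:`PipelineError`; files written so far are removed.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    stage = "configure"
    try:
        stage = "ingest"
        model = RevisionInstability.from_csv(
            config.estimates, config.harmonization, config.hierarchy,
            filter_rules=config.filter_rules(),
            index_map=IterationIndexMap(config.index_map),
            thresholds=config.thresholds(),
            ui_pairs=config.ui_pairs,
            rank_risk_set=config.rank_risk_set,
            cv_ddof=config.cv_ddof,
            rm_denominator=config.rm_denominator,
            min_iterations=config.min_iterations,
        )
        acc_input = model._n_input_records
        logger.info("ingest: %s input records, %s analyzed",
                    acc_input, len(model.table))

        stage = "analyze"
        results = model.fit()
        logger.info(
            "analyze: %d index-year and %d matched-year summaries, "
            "%d interval comparisons",
            len(results.index_summaries), len(results.matched_summaries),
            len(results.ui_comparisons),
        )

        stage = "report"
        written = results.to_csv_bundle(outdir)
        summary_path = outdir / "summary.txt"
        summary_path.write_text(results.summary(), encoding="utf-8")
        written["summary"] = summary_path

        accounting = results.record_accounting()
        if acc_input is not None and accounting["total"] != acc_input:
            raise PipelineError(
                f"record accounting mismatch: input {acc_input} != "
                f"analyzed {accounting['analyzed']} + ledgered {accounting['ledgered']}"
            )

        manifest = {
            "config": _config_echo(config),
            "inputs": {
                name: _sha256(Path(p))
                for name, p in (("estimates", config.estimates),
                                ("harmonization", config.harmonization),
                                ("hierarchy", config.hierarchy))
            },
            "records": accounting,
            "outputs": {name: {"path": str(p), "sha256": _sha256(p)}
                        for name, p in sorted(written.items())},
            "versions": _versions(),
        }
        manifest_path = outdir / "manifest.yaml"
        with open(manifest_path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
        logger.info("report: %d output files under %s", len(written), outdir)
        return manifest
    except PipelineError:
        _cleanup(written)
        raise
    except Exception as exc:
        _cleanup(written)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc


def _cleanup(written: dict[str, Path]) -> None:
    for p in written.values():
        try:
            Path(p).unlink(missing_ok=True)
        except OSError:  # pragma: no cover
            pass


def _config_echo(config: RunConfig) -> dict:
    echo = asdict(config)
    echo["ui_pairs"] = [list(p) for p in config.ui_pairs]
    echo["drop_levels"] = list(config.drop_levels)
    echo["exclude_risk_ids"] = list(config.exclude_risk_ids)
    if config.rank_risk_set is not None:
        echo["rank_risk_set"] = list(config.rank_risk_set)
    return echo


def _versions() -> dict:
    import numpy, pandas, scipy

    from . import __version__

    return {
        "revstab": __version__,
        "numpy": numpy.__version__,
        "pandas": pandas.__version__,
        "scipy": scipy.__version__,
    }
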