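"""Data model, long-format CSV I/O, risk-name harmonization and analysis-set filtering.

The canonical interchange format is a long CSV with one row per published
estimate: a risk factor, a burden metric (attributable deaths or DALYs), the
release iteration that published the number, the calendar year the number
refers to, an optional stratum (sex, location, cause group), the point value
and an optional 95% uncertainty interval.  Release iterations re-estimate
past years, so one (risk, metric, year) cell may carry several values — one
per iteration — which is exactly the structure the downstream instability
statistics consume.

Values are kept in raw units (persons for deaths, person-years for DALYs);
any scaling to thousands/millions happens only when reports are rendered.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Metric",
    "Sex",
    "RiskGroup",
    "RiskDescriptor",
    "RiskHierarchy",
    "HarmonizationMap",
    "EstimateTable",
    "FilterRules",
    "FilterResult",
    "HarmonizationResult",
    "SchemaError",
    "IntegrityError",
    "ValidationError",
    "read_estimates_csv",
    "write_estimates_csv",
    "harmonize",
    "filter_analysis_set",
    "DEFAULT_EXCLUDED_RISK_IDS",
]


class SchemaError(ValueError):
    """A required column cannot be resolved from the input file."""


class IntegrityError(ValueError):
    """Rows violate a table-level invariant (duplicate keys, year > iteration)."""


class ValidationError(ValueError):
    """One or more rows fail field-level validation; message lists row numbers."""


class Metric(str, enum.Enum):
    DEATHS = "deaths"
    DALYS = "dalys"


class Sex(str, enum.Enum):
    BOTH = "both"
    MALE = "male"
    FEMALE = "female"


class RiskGroup(str, enum.Enum):
    BEHAVIORAL = "behavioral"
    METABOLIC = "metabolic"
    ENVIRONMENTAL_OCCUPATIONAL = "environmental_occupational"
    ALL_RISKS = "all_risks"


#: canonical long-format columns, in interchange order
CANONICAL_COLUMNS = [
    "risk",
    "metric",
    "iteration",
    "year",
    "sex",
    "location",
    "cause_group",
    "value",
    "ui_lower",
    "ui_upper",
]

#: columns identifying one published estimate before harmonization
RAW_KEY = ["risk", "metric", "iteration", "year", "sex", "location", "cause_group"]

#: columns identifying one published estimate after harmonization
KEY = ["risk_id", "metric", "iteration", "year", "sex", "location", "cause_group"]

_OPTIONAL_DEFAULTS = {"sex": "both", "location": "global", "cause_group": "all"}


@dataclass(frozen=True)
class RiskDescriptor:
    """One node of the risk hierarchy.

    Levels follow the burden-of-disease convention: level 0 is the all-risk
    aggregate, level 1 the broad groups (behavioral, metabolic,
    environmental/occupational), level 2 subgroups (e.g. dietary risks,
    tobacco), level 3 individual risks (e.g. diet high in sodium).
    """

    risk_id: str
    canonical_name: str
    level: int
    parent_id: Optional[str] = None
    group: RiskGroup = RiskGroup.ALL_RISKS


class RiskHierarchy:
    """Registry of :class:`RiskDescriptor` with parent/level validation."""

    def __init__(self, descriptors: Iterable[RiskDescriptor]):
        self._by_id: dict[str, RiskDescriptor] = {}
        for d in descriptors:
            if d.risk_id in self._by_id:
                raise IntegrityError(f"duplicate risk_id in hierarchy: {d.risk_id!r}")
            self._by_id[d.risk_id] = d
        self._validate()

    def _validate(self) -> None:
        for d in self._by_id.values():
            if d.level == 0:
                if d.parent_id is not None:
                    raise IntegrityError(f"level-0 risk {d.risk_id!r} must have no parent")
            else:
                if d.parent_id is None:
                    raise IntegrityError(f"level-{d.level} risk {d.risk_id!r} needs a parent")
                parent = self._by_id.get(d.parent_id)
                if parent is None:
                    raise IntegrityError(
                        f"risk {d.risk_id!r} references unknown parent {d.parent_id!r}"
                    )
                if parent.level != d.level - 1:
                    raise IntegrityError(
                        f"risk {d.risk_id!r} (level {d.level}) has parent "
                        f"{d.parent_id!r} of level {parent.level}, expected {d.level - 1}"
                    )
        # a descendant inherits the group of its level-1 ancestor
        for d in self._by_id.values():
            if d.level >= 2:
                anc = self.ancestor_at_level(d.risk_id, 1)
                if anc is not None and anc.group != d.group:
                    raise IntegrityError(
                        f"risk {d.risk_id!r} group {d.group.value!r} differs from "
                        f"level-1 ancestor {anc.risk_id!r} group {anc.group.value!r}"
                    )

    def __contains__(self, risk_id: str) -> bool:
        return risk_id in self._by_id

    def __getitem__(self, risk_id: str) -> RiskDescriptor:
        return self._by_id[risk_id]

    def __iter__(self):
        return iter(self._by_id.values())

    def __len__(self) -> int:
        return len(self._by_id)

    def ancestor_at_level(self, risk_id: str, level: int) -> Optional[RiskDescriptor]:
        d = self._by_id[risk_id]
        while d.level > level:
            if d.parent_id is None:
                return None
            d = self._by_id[d.parent_id]
        return d if d.level == level else None

    @classmethod
    def from_csv(cls, path: str | Path) -> "RiskHierarchy":
        """Load a hierarchy CSV with columns risk_id, canonical_name, level, parent_id, group."""
        df = pd.read_csv(path, dtype=str)
        required = {"risk_id", "canonical_name", "level", "parent_id", "group"}
        missing = required - set(df.columns)
        if missing:
            raise SchemaError(f"hierarchy file missing columns: {sorted(missing)}")
        descriptors = [
            RiskDescriptor(
                risk_id=row.risk_id,
                canonical_name=row.canonical_name,
                level=int(row.level),
                parent_id=None if pd.isna(row.parent_id) or row.parent_id == "" else row.parent_id,
                group=RiskGroup(row.group),
            )
            for row in df.itertuples()
        ]
        return cls(descriptors)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "risk_id": d.risk_id,
                    "canonical_name": d.canonical_name,
                    "level": d.level,
                    "parent_id": d.parent_id,
                    "group": d.group.value,
                }
                for d in self
            ]
        )


class HarmonizationMap:
    """Maps iteration-specific raw risk names onto canonical risk identifiers.

    Entries are (raw_name, iteration, risk_id); ``iteration=None`` is a
    wildcard.  Resolution prefers the exact (raw_name, iteration) entry over
    the (raw_name, any-iteration) entry, so a name that changed meaning
    between releases can be mapped per release.
    """

    def __init__(self, entries: Iterable[tuple[str, Optional[int], str]],
                 hierarchy: Optional[RiskHierarchy] = None):
        self._exact: dict[tuple[str, int], str] = {}
        self._wild: dict[str, str] = {}
        for raw_name, iteration, risk_id in entries:
            key_desc = f"({raw_name!r}, {iteration!r})"
            if iteration is None:
                if raw_name in self._wild:
                    raise IntegrityError(f"duplicate harmonization entry {key_desc}")
                self._wild[raw_name] = risk_id
            else:
                k = (raw_name, int(iteration))
                if k in self._exact:
                    raise IntegrityError(f"duplicate harmonization entry {key_desc}")
                self._exact[k] = risk_id
            if hierarchy is not None and risk_id not in hierarchy:
                raise IntegrityError(
                    f"harmonization entry {key_desc} references unknown risk_id {risk_id!r}"
                )

    def resolve(self, raw_name: str, iteration: int) -> Optional[str]:
        hit = self._exact.get((raw_name, int(iteration)))
        if hit is not None:
            return hit
        return self._wild.get(raw_name)

    def __len__(self) -> int:
        return len(self._exact) + len(self._wild)

    @classmethod
    def from_csv(cls, path: str | Path,
                 hierarchy: Optional[RiskHierarchy] = None) -> "HarmonizationMap":
        """Load a map CSV with columns raw_name, iteration (blank = any), risk_id."""
        df = pd.read_csv(path, dtype={"raw_name": str, "risk_id": str})
        required = {"raw_name", "iteration", "risk_id"}
        missing = required - set(df.columns)
        if missing:
            raise SchemaError(f"harmonization file missing columns: {sorted(missing)}")
        entries = [
            (
                row.raw_name,
                None if pd.isna(row.iteration) else int(row.iteration),
                row.risk_id,
            )
            for row in df.itertuples()
        ]
        return cls(entries, hierarchy=hierarchy)


class EstimateTable:
    """A validated long table of published estimates.

    Wraps a :class:`pandas.DataFrame` in canonical column order.  Before
    harmonization rows carry only the raw ``risk`` name; :func:`harmonize`
    adds ``risk_id`` (and, given a hierarchy, ``canonical_name``, ``level``
    and ``group``).
    """

    def __init__(self, df: pd.DataFrame, *, harmonized: bool = False):
        self._df = df.reset_index(drop=True)
        self.harmonized = harmonized

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    @property
    def risk_ids(self) -> list[str]:
        if not self.harmonized:
            raise IntegrityError("table is not harmonized; no risk_id column")
        return sorted(self._df["risk_id"].unique())

    def restrict(self, **conditions) -> "EstimateTable":
        """Return the sub-table where each named column equals (or is in) the given value(s)."""
        mask = pd.Series(True, index=self._df.index)
        for col, val in conditions.items():
            if isinstance(val, (list, tuple, set, frozenset)):
                mask &= self._df[col].isin(list(val))
            else:
                mask &= self._df[col] == val
        return EstimateTable(self._df[mask], harmonized=self.harmonized)


def _resolve_schema(columns: Sequence[str], schema: Optional[Mapping[str, str]]) -> dict[str, str]:
    """Map canonical column names to input column names."""
    schema = dict(schema or {})
    resolved = {}
    for canon in CANONICAL_COLUMNS:
        src = schema.get(canon, canon)
        if src in columns:
            resolved[canon] = src
    required = ["risk", "metric", "iteration", "year", "value"]
    missing = [c for c in required if c not in resolved]
    if missing:
        raise SchemaError(
            f"required columns not resolvable: {missing} (available: {list(columns)})"
        )
    return resolved


def read_estimates_csv(path: str | Path,
                       schema: Optional[Mapping[str, str]] = None) -> EstimateTable:
    """Read and validate a long-format estimates CSV.

    Parameters
    ----------
    path
        UTF-8 CSV with a header row.  Missing uncertainty bounds are empty
        fields.
    schema
        Optional mapping from canonical column names (``risk``, ``metric``,
        ``iteration``, ``year``, ``sex``, ``location``, ``cause_group``,
        ``value``, ``ui_lower``, ``ui_upper``) to the file's column names.

    Raises
    ------
    SchemaError
        A required column cannot be resolved.
    ValidationError
        Field-level failures (negative value, inverted uncertainty interval,
        unknown metric/sex), with 1-based data row numbers.
    IntegrityError
        Duplicate full keys or a year later than its release iteration.
    """
    # round_trip parsing: the default C float parser can be one ulp off,
    # which would break exact write/read round-trips of value fields
    raw = pd.read_csv(path, float_precision="round_trip")
    resolved = _resolve_schema(raw.columns, schema)
    df = pd.DataFrame({canon: raw[src] for canon, src in resolved.items()})
    for col, default in _OPTIONAL_DEFAULTS.items():
        if col not in df.columns:
            df[col] = default
        else:
            df[col] = df[col].fillna(default)
    for col in ("ui_lower", "ui_upper"):
        if col not in df.columns:
            df[col] = np.nan
    df = df[CANONICAL_COLUMNS]
    return validate_estimates(df)


def validate_estimates(df: pd.DataFrame) -> EstimateTable:
    """Validate a canonical-column DataFrame and wrap it as an :class:`EstimateTable`.

    Row numbers in diagnostics are 1-based over data rows (header excluded).
    """
    df = df.copy().reset_index(drop=True)
    problems: list[str] = []

    def rownum(i: int) -> int:
        return i + 1

    # dtype coercion with per-row diagnostics
    for col in ("iteration", "year"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna()]
        problems.extend(f"row {rownum(i)}: non-integer {col}={df.at[i, col]!r}" for i in bad)
        df[col] = coerced
    for col in ("value", "ui_lower", "ui_upper"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if col == "value":
            bad = df.index[coerced.isna() & df[col].notna()] if df[col].dtype == object else []
            bad = df.index[coerced.isna()]
            problems.extend(f"row {rownum(i)}: non-numeric value={df.at[i, col]!r}" for i in bad)
        df[col] = coerced

    valid_metrics = {m.value for m in Metric}
    for i in df.index[~df["metric"].isin(valid_metrics)]:
        problems.append(f"row {rownum(i)}: unknown metric {df.at[i, 'metric']!r}")
    valid_sex = {s.value for s in Sex}
    for i in df.index[~df["sex"].isin(valid_sex)]:
        problems.append(f"row {rownum(i)}: unknown sex {df.at[i, 'sex']!r}")

    for i in df.index[df["value"] < 0]:
        problems.append(f"row {rownum(i)}: negative value {df.at[i, 'value']!r}")
    # exactly one UI bound present is malformed
    one_sided = df["ui_lower"].notna() ^ df["ui_upper"].notna()
    for i in df.index[one_sided]:
        problems.append(f"row {rownum(i)}: uncertainty interval has only one bound")
    inverted = (df["ui_lower"] > df["ui_upper"]).fillna(False)
    for i in df.index[inverted]:
        problems.append(
            f"row {rownum(i)}: ui_lower {df.at[i, 'ui_lower']} > ui_upper {df.at[i, 'ui_upper']}"
        )
    if problems:
        raise ValidationError("invalid rows:\n" + "\n".join(problems))

    df["iteration"] = df["iteration"].astype(int)
    df["year"] = df["year"].astype(int)
    df["value"] = df["value"].astype(float)

    # iterations estimate past (and their own) years, never future ones
    late = df.index[df["year"] > df["iteration"]]
    if len(late):
        msgs = [
            f"row {rownum(i)}: year {df.at[i, 'year']} > iteration {df.at[i, 'iteration']}"
            for i in late
        ]
        raise IntegrityError("year later than release iteration:\n" + "\n".join(msgs))

    dup = df.duplicated(subset=RAW_KEY, keep=False)
    if dup.any():
        groups = df[dup].groupby(RAW_KEY, sort=False).groups
        msgs = [
            f"key {k}: rows {[rownum(i) for i in idx]}" for k, idx in groups.items()
        ]
        raise IntegrityError("duplicate estimate keys:\n" + "\n".join(msgs))

    # UI bounds not bracketing the point are recorded as-is but flagged
    with np.errstate(invalid="ignore"):
        df["ui_violation"] = (
            df["ui_lower"].notna()
            & ((df["value"] < df["ui_lower"]) | (df["value"] > df["ui_upper"]))
        )
    return EstimateTable(df)


def write_estimates_csv(table: EstimateTable, path: str | Path) -> None:
    """Write the canonical long CSV; float fields serialized at full precision."""
    cols = [c for c in CANONICAL_COLUMNS if c in table.df.columns]
    # 17 significant digits round-trips any IEEE double exactly
    table.df[cols].to_csv(path, index=False, float_format="%.17g")


@dataclass
class HarmonizationResult:
    """Harmonized table plus the report of raw names with no mapping."""

    table: EstimateTable
    unmapped: pd.DataFrame  # columns: risk, iteration, n_records


def harmonize(table: EstimateTable, hmap: HarmonizationMap,
              hierarchy: Optional[RiskHierarchy] = None) -> HarmonizationResult:
    """Attach canonical risk identifiers to every record.

    Records whose raw name resolves to no map entry are collected into the
    ``unmapped`` report and excluded from the harmonized table — never
    silently dropped.  Applying the same map twice is a no-op (raw names are
    retained, so resolution is stable).
    """
    df = table.df.copy()
    resolved = [
        hmap.resolve(risk, iteration)
        for risk, iteration in zip(df["risk"], df["iteration"])
    ]
    df["risk_id"] = resolved
    unmapped_mask = df["risk_id"].isna()
    unmapped = (
        df[unmapped_mask]
        .groupby(["risk", "iteration"], as_index=False)
        .size()
        .rename(columns={"size": "n_records"})
    )
    kept = df[~unmapped_mask].copy()
    if hierarchy is not None:
        meta = hierarchy.to_frame()[["risk_id", "canonical_name", "level", "group"]]
        # re-harmonizing an already-joined table must be a no-op
        kept = kept.drop(columns=[c for c in ("canonical_name", "level", "group")
                                  if c in kept.columns])
        kept = kept.merge(meta, on="risk_id", how="left")
    # harmonized keys must remain unique
    dup = kept.duplicated(subset=KEY, keep=False)
    if dup.any():
        keys = kept.loc[dup, KEY].drop_duplicates().to_dict("records")
        raise IntegrityError(
            f"harmonization collapses distinct raw names onto duplicate keys: {keys}"
        )
    return HarmonizationResult(EstimateTable(kept, harmonized=True), unmapped)


#: Approximate default exclusion list.  The source study drops a small set of
#: interpersonal-violence-in-childhood risks and the combined alcohol-and-drug
#: aggregate; the full list is supplied by the user alongside the
#: harmonization map.
DEFAULT_EXCLUDED_RISK_IDS = (
    "childhood_sexual_abuse",
    "childhood_sexual_abuse_female",
    "childhood_sexual_abuse_male",
    "bullying_victimization",
    "childhood_sexual_abuse_and_bullying",
    "alcohol_and_drug_use",
)


@dataclass
class FilterRules:
    """Analysis-set filter: which risks enter the instability analysis."""

    drop_levels: tuple[int, ...] = (4,)
    exclude_risk_ids: tuple[str, ...] = DEFAULT_EXCLUDED_RISK_IDS
    min_iterations: int = 2


@dataclass
class FilterResult:
    """Filtered table plus the exclusion ledger (risk_id, reason, n_records)."""

    table: EstimateTable
    ledger: pd.DataFrame

    @property
    def n_excluded_records(self) -> int:
        return int(self.ledger["n_records"].sum()) if len(self.ledger) else 0


def filter_analysis_set(table: EstimateTable,
                        rules: Optional[FilterRules] = None) -> FilterResult:
    """Drop risks outside the analysis set, recording every removal.

    Removes risks published in fewer than ``min_iterations`` release
    iterations, risks at excluded hierarchy levels (level 4 by default), and
    explicitly named exclusions.  Every removed record is accounted for in
    the ledger: ``len(input) == len(output) + ledger.n_records.sum()``.
    """
    if not table.harmonized:
        raise IntegrityError("filter_analysis_set requires a harmonized table")
    rules = rules or FilterRules()
    df = table.df
    reasons: dict[str, str] = {}

    for rid in df.loc[df["risk_id"].isin(rules.exclude_risk_ids), "risk_id"].unique():
        reasons[rid] = "named-exclusion"
    if "level" in df.columns:
        lev_mask = df["level"].isin(rules.drop_levels)
        for rid in df.loc[lev_mask, "risk_id"].unique():
            reasons.setdefault(rid, "excluded-level")
    n_iter = df.groupby("risk_id")["iteration"].nunique()
    for rid in n_iter.index[n_iter < rules.min_iterations]:
        reasons.setdefault(rid, "single-iteration")

    excluded_mask = df["risk_id"].isin(reasons)
    counts = df.loc[excluded_mask].groupby("risk_id").size()
    ledger = pd.DataFrame(
        [
            {"risk_id": rid, "reason": reason, "n_records": int(counts.get(rid, 0))}
            for rid, reason in sorted(reasons.items())
        ],
        columns=["risk_id", "reason", "n_records"],
    )
    kept = EstimateTable(df[~excluded_mask], harmonized=True)
    return FilterResult(kept, ledger)
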