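"""Shared fixtures: a tiny risk hierarchy, harmonization map, and CSV builders."""

from __future__ import annotations

import csv
from pathlib import Path

import pytest

from revstab.estimates import (
    HarmonizationMap,
    RiskDescriptor,
    RiskGroup,
    RiskHierarchy,
)

ESTIMATE_COLUMNS = [
    "risk", "metric", "iteration", "year", "sex", "location",
    "cause_group", "value", "ui_lower", "ui_upper",
]


@pytest.fixture
def tiny_hierarchy() -> RiskHierarchy:
    """All-risk root, three level-1 groups, a dietary branch, one level-4 leaf."""
    B, M, E = (RiskGroup.BEHAVIORAL, RiskGroup.METABOLIC,
               RiskGroup.ENVIRONMENTAL_OCCUPATIONAL)
    return RiskHierarchy([
        RiskDescriptor("all_risks", "All risk factors", 0, None, RiskGroup.ALL_RISKS),
        RiskDescriptor("behavioral", "Behavioral risks", 1, "all_risks", B),
        RiskDescriptor("metabolic", "Metabolic risks", 1, "all_risks", M),
        RiskDescriptor("environmental", "Environmental/occupational risks", 1,
                       "all_risks", E),
        RiskDescriptor("dietary", "Dietary risks", 2, "behavioral", B),
        RiskDescriptor("diet_red_meat", "Diet high in red meat", 3, "dietary", B),
        RiskDescriptor("diet_sodium", "Diet high in sodium", 3, "dietary", B),
        RiskDescriptor("diet_processed_meat", "Diet high in processed meat", 3,
                       "dietary", B),
        RiskDescriptor("low_physical_activity", "Low physical activity", 2,
                       "behavioral", B),
        RiskDescriptor("high_bmi", "High body-mass index", 2, "metabolic", M),
        RiskDescriptor("air_pollution", "Air pollution", 2, "environmental", E),
        RiskDescriptor("occupational", "Occupational risks", 2, "environmental", E),
        RiskDescriptor("occ_carcinogens", "Occupational carcinogens", 3,
                       "occupational", E),
        RiskDescriptor("occ_asbestos", "Occupational exposure to asbestos", 4,
                       "occ_carcinogens", E),
        RiskDescriptor("childhood_sexual_abuse", "Childhood sexual abuse", 2,
                       "behavioral", B),
    ])


@pytest.fixture
def tiny_map(tiny_hierarchy) -> HarmonizationMap:
    """Identity-style map with one renamed spelling and one iteration-specific entry."""
    entries = [
        ("Diet high in red meat", None, "diet_red_meat"),
        ("Red meat consumption", None, "diet_red_meat"),  # old spelling
        ("Diet high in sodium", None, "diet_sodium"),
        ("Diet high in processed meat", None, "diet_processed_meat"),
        ("Low physical activity", None, "low_physical_activity"),
        ("High body-mass index", None, "high_bmi"),
        ("Air pollution", None, "air_pollution"),
        ("Occupational carcinogens", None, "occ_carcinogens"),
        ("Occupational exposure to asbestos", None, "occ_asbestos"),
        ("Childhood sexual abuse", None, "childhood_sexual_abuse"),
        # same raw name mapped differently for one early iteration
        ("Physical inactivity", 2010, "low_physical_activity"),
    ]
    return HarmonizationMap(entries, hierarchy=tiny_hierarchy)


def write_estimates_file(path: Path, rows: list[dict]) -> Path:
    """Write a canonical-schema estimates CSV from row dicts (missing cells blank)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=ESTIMATE_COLUMNS)
        writer.writeheader()
        for row in rows:
            writer.writerow({col: row.get(col, "") for col in ESTIMATE_COLUMNS})
    return path


def estimate_row(risk: str, iteration: int, year: int, value: float,
                 metric: str = "deaths", **kw) -> dict:
    row = {
        "risk": risk, "metric": metric, "iteration": iteration, "year": year,
        "sex": "both", "location": "global", "cause_group": "all", "value": value,
    }
    row.update(kw)
    return row


@pytest.fixture
def hierarchy_csv(tmp_path, tiny_hierarchy) -> Path:
    path = tmp_path / "hierarchy.csv"
    tiny_hierarchy.to_frame().to_csv(path, index=False)
    return path


@pytest.fixture
def harmonization_csv(tmp_path) -> Path:
    path = tmp_path / "map.csv"
    rows = [
        ("Diet high in red meat", "", "diet_red_meat"),
        ("Red meat consumption", "", "diet_red_meat"),
        ("Diet high in sodium", "", "diet_sodium"),
        ("Diet high in processed meat", "", "diet_processed_meat"),
        ("Low physical activity", "", "low_physical_activity"),
        ("High body-mass index", "", "high_bmi"),
        ("Air pollution", "", "air_pollution"),
        ("Occupational carcinogens", "", "occ_carcinogens"),
        ("Occupational exposure to asbestos", "", "occ_asbestos"),
        ("Childhood sexual abuse", "", "childhood_sexual_abuse"),
        ("Physical inactivity", "2010", "low_physical_activity"),
    ]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["raw_name", "iteration", "risk_id"])
        writer.writerows(rows)
    return path
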