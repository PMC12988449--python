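"""Synthetic multi-release estimate panels with known truth.

The generator emulates the revision process the instability analysis
assumes: a positive burden quantity with a smooth exponential trend,
re-estimated by successive release iterations, where each release applies a
systematic multiplicative shift (standing in for methodology and data
changes) and each published number carries multiplicative observation noise.
On the log scale,

    log V[r, i, y] = log A[r] + g[r] * (y - y0) + delta[r, i] + eps[r, i, y]

with ``delta ~ N(0, tau^2)`` per (risk, iteration) — independent per release
or a random walk across releases — and ``eps ~ N(0, sigma^2)`` iid per
record.  Published 95% intervals are multiplicative:
``[V * exp(-z * s_ui), V * exp(+z * s_ui)]``.

Because everything is lognormal, calibration targets exist in closed form:
the population CV of matched-year values (independent mode) is
``sqrt(exp(tau^2 + sigma^2) - 1)``, and the probability that a later
release's point falls inside an earlier release's interval is
``2 * Phi(z * s_ui / sqrt(2 * (tau^2 + sigma^2))) - 1``.

Magnitudes are arbitrary units; no attempt is made to imitate real per-risk
burden levels.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt, exp
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .alignment import DEFAULT_ITERATIONS
from .estimates import (
    EstimateTable,
    HarmonizationMap,
    RiskDescriptor,
    RiskGroup,
    RiskHierarchy,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate",
    "theoretical_cv",
    "theoretical_ui_within",
    "synthetic_hierarchy",
    "synthetic_harmonization_map",
]

_GROUP_CYCLE = (
    RiskGroup.BEHAVIORAL,
    RiskGroup.METABOLIC,
    RiskGroup.ENVIRONMENTAL_OCCUPATIONAL,
)

#: DALYs per death, a fixed synthetic conversion so the two metrics share the
#: per-iteration revision shift but live on realistic relative scales
DALY_PER_DEATH = 25.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic revision process.

    Defaults mirror the study structure: 66 risks followed across the eight
    release iterations 2010–2023, each iteration re-estimating all index
    years up to its own.  ``tau`` (per-release systematic shift SD, log
    scale) and ``sigma`` (per-record noise SD, log scale) default to
    0.3 / 0.1 — revision spread dominating observation noise.
    """

    n_risks: int = 66
    iterations: tuple[int, ...] = DEFAULT_ITERATIONS
    years_of: Optional[Mapping[int, Sequence[int]]] = None
    baseline_range: tuple[float, float] = (1e4, 1e7)  # deaths, log-uniform
    growth_range: tuple[float, float] = (-0.03, 0.03)  # per-year log slope
    tau: float = 0.3
    sigma: float = 0.1
    shift_mode: str = "independent"  # or "random_walk"
    s_ui: float = 0.2  # UI log-scale half-width multiplier
    z: float = 1.96
    metrics: tuple[str, ...] = ("deaths", "dalys")
    seed: int = 0

    def __post_init__(self):
        if self.tau < 0 or self.sigma < 0 or self.s_ui < 0:
            raise ValueError("tau, sigma and s_ui must be nonnegative")
        if self.z <= 0:
            raise ValueError("z must be positive")
        if self.shift_mode not in ("independent", "random_walk"):
            raise ValueError(f"unknown shift_mode {self.shift_mode!r}")
        if self.n_risks < 1:
            raise ValueError("n_risks must be positive")

    def years(self, iteration: int) -> list[int]:
        """Calendar years the given iteration estimates (default: all index years ≤ it)."""
        if self.years_of is not None:
            return sorted(self.years_of.get(iteration, []))
        return [y for y in self.iterations if y <= iteration]


@dataclass
class SyntheticTruth:
    """The generating parameters, retrievable for parameter-recovery tests."""

    risks: pd.DataFrame   # risk_id, baseline, growth
    shifts: pd.DataFrame  # risk_id, iteration, delta
    noise: pd.DataFrame   # risk_id, metric, iteration, year, eps


def _risk_id(i: int) -> str:
    return f"risk_{i + 1:03d}"


def synthetic_hierarchy(n_risks: int) -> RiskHierarchy:
    """A minimal 3-level hierarchy: all-risk root, 3 level-1 groups, leaf risks.

    Leaves sit at level 2 and cycle through the behavioral / metabolic /
    environmental-occupational groups, so group summaries are exercised.
    """
    descriptors = [
        RiskDescriptor("all_risks", "All risk factors", 0, None, RiskGroup.ALL_RISKS)
    ]
    for grp in _GROUP_CYCLE:
        descriptors.append(
            RiskDescriptor(f"group_{grp.value}", grp.value.replace("_", " ").title(),
                           1, "all_risks", grp)
        )
    for i in range(n_risks):
        grp = _GROUP_CYCLE[i % len(_GROUP_CYCLE)]
        descriptors.append(
            RiskDescriptor(_risk_id(i), f"Synthetic risk {i + 1:03d}", 2,
                           f"group_{grp.value}", grp)
        )
    return RiskHierarchy(descriptors)


def synthetic_harmonization_map(n_risks: int,
                                hierarchy: Optional[RiskHierarchy] = None,
                                ) -> HarmonizationMap:
    """Identity map from the generator's raw names to canonical identifiers."""
    entries = [(f"Synthetic risk {i + 1:03d}", None, _risk_id(i)) for i in range(n_risks)]
    return HarmonizationMap(entries, hierarchy=hierarchy)


def generate(config: SyntheticConfig) -> tuple[EstimateTable, SyntheticTruth]:
    """Draw one synthetic estimate table plus its generating truth.

    A single seeded generator drives all draws in a fixed order — baselines,
    then growth rates, then per-(risk, iteration) shifts, then per-record
    noise over the sorted record grid — so an identical seed yields a
    bit-identical table.  The per-iteration shift is shared between the
    deaths and DALYs series of a risk (methodology changes move both), while
    record-level noise is independent.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_risks
    iterations = list(config.iterations)
    all_years = [y for it in iterations for y in config.years(it)]
    if not all_years:
        raise ValueError("configuration yields no estimation years")
    y0 = min(all_years)

    lo, hi = config.baseline_range
    baseline = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    growth = rng.uniform(*config.growth_range, size=n)

    incr = rng.normal(0.0, config.tau, size=(n, len(iterations)))
    delta = np.cumsum(incr, axis=1) if config.shift_mode == "random_walk" else incr

    # record grid in deterministic order: risk, metric, iteration, year
    grid = [
        (ri, metric, ii, year)
        for ri in range(n)
        for metric in config.metrics
        for ii, it in enumerate(iterations)
        for year in config.years(it)
    ]
    eps = rng.normal(0.0, config.sigma, size=len(grid))

    rows = []
    zs = config.z * config.s_ui
    for (ri, metric, ii, year), e in zip(grid, eps):
        it = iterations[ii]
        scale = DALY_PER_DEATH if metric == "dalys" else 1.0
        log_v = (
            np.log(baseline[ri] * scale)
            + growth[ri] * (year - y0)
            + delta[ri, ii]
            + e
        )
        v = float(np.exp(log_v))
        rows.append(
            {
                "risk": f"Synthetic risk {ri + 1:03d}",
                "risk_id": _risk_id(ri),
                "metric": metric,
                "iteration": it,
                "year": year,
                "sex": "both",
                "location": "global",
                "cause_group": "all",
                "value": v,
                "ui_lower": v * exp(-zs),
                "ui_upper": v * exp(zs),
            }
        )
    df = pd.DataFrame(rows)

    hierarchy = synthetic_hierarchy(n)
    meta = hierarchy.to_frame()[["risk_id", "canonical_name", "level", "group"]]
    df = df.merge(meta, on="risk_id", how="left")
    table = EstimateTable(df, harmonized=True)

    truth = SyntheticTruth(
        risks=pd.DataFrame(
            {"risk_id": [_risk_id(i) for i in range(n)],
             "baseline": baseline, "growth": growth}
        ),
        shifts=pd.DataFrame(
            [
                {"risk_id": _risk_id(ri), "iteration": it, "delta": delta[ri, ii]}
                for ri in range(n)
                for ii, it in enumerate(iterations)
            ]
        ),
        noise=pd.DataFrame(
            [
                {"risk_id": _risk_id(ri), "metric": metric,
                 "iteration": iterations[ii], "year": year, "eps": e}
                for (ri, metric, ii, year), e in zip(grid, eps)
            ]
        ),
    )
    return table, truth


def theoretical_cv(tau: float, sigma: float) -> float:
    """Population CV of matched-year values in independent-shift mode.

    Matched-year values are lognormal with log-SD ``sqrt(tau^2 + sigma^2)``,
    whose CV is ``sqrt(exp(tau^2 + sigma^2) - 1)``.
    """
    if tau < 0 or sigma < 0:
        raise ValueError("tau and sigma must be nonnegative")
    return sqrt(exp(tau**2 + sigma**2) - 1.0)


def theoretical_ui_within(tau: float, sigma: float, s_ui: float, z: float = 1.96) -> float:
    """Probability a later independent-mode point falls inside an earlier UI.

    The log-difference of two independent draws for the same cell has SD
    ``sqrt(2 * (tau^2 + sigma^2))``; the interval half-width is ``z * s_ui``
    on the log scale, so the within-probability is
    ``2 * Phi(z * s_ui / sqrt(2 * (tau^2 + sigma^2))) - 1``.  The degenerate
    noiseless limit returns 1.
    """
    if tau < 0 or sigma < 0 or s_ui < 0:
        raise ValueError("tau, sigma and s_ui must be nonnegative")
    if z <= 0:
        raise ValueError("z must be positive")
    spread = sqrt(2.0 * (tau**2 + sigma**2))
    if spread == 0.0:
        return 1.0
    return float(2.0 * norm.cdf(z * s_ui / spread) - 1.0)
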