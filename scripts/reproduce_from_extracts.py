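#!/usr/bin/env python
"""Re-run the full instability analysis on user-supplied release extracts.

The per-iteration inputs behind the published instability tables are not
redistributable here; this wrapper accepts extracts the user has downloaded
from the estimate repository (converted to the canonical long CSV schema:
risk, metric, iteration, year, sex, location, cause_group, value, ui_lower,
ui_upper), together with a harmonization map and a risk-hierarchy CSV, and
re-emits the analogue report tables:

* instability_index_year.csv / instability_matched_year.csv — per-risk
  R:M / CV summary rows;
* rm_heatmap_deaths.csv — the risk x context R:M matrix;
* cv_distribution.csv — CV values behind the box-plot view;
* ui_coverage.csv — per-risk below/within/above counts against prior
  intervals;
* rank_trajectories.csv — per-iteration ranks for a chosen risk set.

Usage:
    python scripts/reproduce_from_extracts.py \
        --estimates extracts.csv --harmonization map.csv \
        --hierarchy hierarchy.csv --out results/reproduction \
        [--rank-risk-set diet_red_meat,diet_sodium,...]

No numeric checks are attached: input acquisition is external and partly
manual, so the output is for the user's own comparison.
"""

from __future__ import annotations

import argparse
from pathlib import Path

from revstab.report import RunConfig, run_pipeline


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--estimates", required=True)
    parser.add_argument("--harmonization", required=True)
    parser.add_argument("--hierarchy", required=True)
    parser.add_argument("--out", required=True)
    parser.add_argument("--rank-risk-set", default=None,
                        help="Comma-separated risk_ids to rank per iteration.")
    args = parser.parse_args()

    rank_set = (
        tuple(s.strip() for s in args.rank_risk_set.split(",") if s.strip())
        if args.rank_risk_set else None
    )
    config = RunConfig(
        estimates=args.estimates,
        harmonization=args.harmonization,
        hierarchy=args.hierarchy,
        out_dir=args.out,
        rank_risk_set=rank_set,
    )
    manifest = run_pipeline(config)
    print(f"wrote {len(manifest['outputs'])} report tables to {args.out}")


if __name__ == "__main__":
    main()
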