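#!/usr/bin/env python
"""Condition-level statistics over the chamber and well tables.

Reads the tables written by 02/03 (running them first if needed),
summarizes each metric per condition, runs pairwise Student/Welch
t-tests, and exports the bundle (HDF5 + CSVs) to results/run/.
"""

import runpy
import sys
from pathlib import Path

import pandas as pd

from hyphatrack import compare_conditions, summarize_condition
from hyphatrack.io import RunBundle, export_run, summaries_table, ttests_table

HERE = Path(__file__).resolve().parent
OUT = HERE.parent / "results"


def ensure(table: Path, script: str) -> None:
    if not table.exists():
        runpy.run_path(str(HERE / script), run_name="__main__")


def main() -> None:
    ensure(OUT / "mtpc_wells.csv", "03_mtpc_wells.py")
    wells = pd.read_csv(OUT / "mtpc_wells.csv")

    summaries, ttests = [], []
    for metric in ("lag_phase_h", "mu_h"):
        groups = {c: g[metric].dropna().to_numpy()
                  for c, g in wells.groupby("condition")}
        for cond, vals in groups.items():
            if len(vals):
                summaries.append(summarize_condition(vals, cond, metric))
        conds = sorted(groups)
        for i, a in enumerate(conds):
            for b in conds[i + 1:]:
                if len(groups[a]) >= 2 and len(groups[b]) >= 2:
                    ttests.append(compare_conditions(
                        groups[a], groups[b], metric=metric,
                        condition_a=a, condition_b=b))

    bundle = RunBundle(summaries=summaries, ttests=ttests)
    export_run(bundle, OUT / "run")
    print(summaries_table(summaries).round(3).to_string(index=False))
    print()
    print(ttests_table(ttests)[["metric", "condition_a", "condition_b",
                                "welch_p", "significant"]]
          .round(4).to_string(index=False))


if __name__ == "__main__":
    sys.exit(main())
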