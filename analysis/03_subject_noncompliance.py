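#!/usr/bin/env python
"""Subject-level non-compliance at the headline design cell.

Same sweep as analysis/02 but with never-takers arising subject by
subject inside intervention clusters; the covariate now has within- and
between-cluster components with the outcome's ICC.  Writes
results/figure4.csv (covariate included) and results/figure5.csv
(covariate omitted) and prints the as-treated efficiency dip, the one
qualitative feature that distinguishes the two levels.
"""

import argparse
import importlib.util
from pathlib import Path

from crtsim import reproduce_figure

ROOT = Path(__file__).resolve().parents[1]
_spec = importlib.util.spec_from_file_location(
    "cluster_sweep", Path(__file__).with_name("02_cluster_noncompliance.py")
)
_mod = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_mod)
sweep_table, maybe_plot = _mod.sweep_table, _mod.maybe_plot


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--reps", type=int, default=400)
    parser.add_argument("--seed", type=int, default=20191003)
    parser.add_argument("--workers", type=int, default=1)
    parser.add_argument("--plot", action="store_true")
    args = parser.parse_args()

    (ROOT / "results").mkdir(exist_ok=True)
    tables = {}
    for figure_id, label in ((4, "covariate included"), (5, "covariate omitted")):
        table = reproduce_figure(
            figure_id, reps=args.reps, base_seed=args.seed, workers=args.workers
        )
        tables[figure_id] = table
        path = ROOT / "results" / f"figure{figure_id}.csv"
        table.to_csv(path, index=False)
        print(f"\n=== subject-level non-compliance, {label} "
              f"({args.reps} replications) -> {path}")
        print(sweep_table(table).to_string())
        if args.plot:
            maybe_plot(table, figure_id)

    at_sd = tables[4].query("metric == 'sd_estimate' and approach == 'AT'")
    sd0 = float(at_sd.loc[at_sd["pbar"] == 0.0, "value"].iloc[0])
    sd3 = float(at_sd.loc[at_sd["pbar"] == 0.3, "value"].iloc[0])
    print(
        f"\nAs-treated SD dips from {sd0:.3f} at pbar=0 to {sd3:.3f} at "
        f"pbar=0.3: analysing intervention-arm never-takers as controls "
        f"turns part of the between-cluster comparison into a more "
        f"efficient within-cluster one, until the arms grow too unbalanced."
    )


if __name__ == "__main__":
    main()
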