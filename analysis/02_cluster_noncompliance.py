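#!/usr/bin/env python
"""Cluster-level non-compliance at the headline design cell.

Sweeps the average non-compliance probability 0..0.5 at ICC 0.05 and
cluster size 20 (79 clusters), analysing each simulated trial by ITT,
AT, PP and IV with and without the compliance-driving covariate.
Writes the four-metric tables results/figure2.csv (covariate included)
and results/figure3.csv (covariate omitted) and prints the headline
contrasts.  Use --plot to render quick-look panels under scratch/.
"""

import argparse
from pathlib import Path

from crtsim import reproduce_figure

ROOT = Path(__file__).resolve().parents[1]


def sweep_table(table):
    wide = table.pivot_table(
        index=["metric", "pbar"], columns="approach", values="value"
    )[["ITT", "AT", "PP", "IV"]]
    return wide.round(3)


def maybe_plot(table, figure_id):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharex=True)
    metrics = ["mean_estimate", "sd_estimate", "coverage", "power"]
    for ax, metric in zip(axes.ravel(), metrics):
        sub = table[table["metric"] == metric]
        for approach, grp in sub.groupby("approach"):
            ax.plot(grp["pbar"], grp["value"], marker="o", label=approach)
        ax.set_title(metric)
        ax.set_xlabel("average probability of non-compliance")
    axes[0, 0].legend()
    out = ROOT / "scratch" / "figures"
    out.mkdir(parents=True, exist_ok=True)
    fig.tight_layout()
    fig.savefig(out / f"figure{figure_id}.png", dpi=120)
    print(f"plot written to {out / f'figure{figure_id}.png'}")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--reps", type=int, default=400)
    parser.add_argument("--seed", type=int, default=20191003)
    parser.add_argument("--workers", type=int, default=1)
    parser.add_argument("--plot", action="store_true")
    args = parser.parse_args()

    (ROOT / "results").mkdir(exist_ok=True)
    for figure_id, label in ((2, "covariate included"), (3, "covariate omitted")):
        table = reproduce_figure(
            figure_id, reps=args.reps, base_seed=args.seed, workers=args.workers
        )
        path = ROOT / "results" / f"figure{figure_id}.csv"
        table.to_csv(path, index=False)
        print(f"\n=== cluster-level non-compliance, {label} "
              f"({args.reps} replications) -> {path}")
        print(sweep_table(table).to_string())
        if args.plot:
            maybe_plot(table, figure_id)

    print(
        "\nReading the tables: with the covariate in the model every approach "
        "tracks its own estimand (ITT's shrinks as 0.2*(1-pbar)) and coverage "
        "stays near 0.95; without it, AT and PP drift below 0.2 and their "
        "intervals undercover, while IV pays instead with a growing SD."
    )


if __name__ == "__main__":
    main()
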