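"""Scatter plots of class imbalance against each performance metric.

Recreates the benchmark's imbalance analysis as figures: for ordinal
conditions, imbalance vs MAMAE and vs plain MAE; for binary conditions,
imbalance vs BAcc and vs plain Acc; each panel annotated with Spearman's
rho.  The balanced metrics degrade with imbalance while the unbalanced
ones appear to improve — the metric-choice artifact the benchmark
quantifies.  Requires matplotlib; writes results/figures/imbalance.png.
"""

import argparse
from pathlib import Path

import pandas as pd
from scipy.stats import spearmanr

ROOT = Path(__file__).resolve().parents[1]

PANELS = [
    ("ordinal", "mamae", "MAMAE (balanced)"),
    ("ordinal", "mae", "MAE (unbalanced)"),
    ("binary", "bacc", "BAcc (balanced)"),
    ("binary", "acc", "Acc (unbalanced)"),
]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument(
        "--conditions", type=Path,
        default=ROOT / "results" / "benchmark" / "conditions.csv",
    )
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "figures")
    args = ap.parse_args()

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = pd.read_csv(args.conditions)
    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharex=True)
    for ax, (task, metric, label) in zip(axes.ravel(), PANELS):
        sub = df[df.task == task]
        rho = spearmanr(sub["imbalance"], sub[metric]).statistic
        ax.scatter(sub["imbalance"], sub[metric], s=18, alpha=0.7)
        ax.set_title(f"{label}  (Spearman rho = {rho:+.2f})", fontsize=10)
        ax.set_ylabel(metric.upper())
        print(f"{task:8s} imbalance vs {metric}: rho = {rho:+.3f}")
    for ax in axes[1]:
        ax.set_xlabel("class imbalance (majority - minority) / n")
    fig.tight_layout()
    args.out.mkdir(parents=True, exist_ok=True)
    fig.savefig(args.out / "imbalance.png", dpi=150)
    print(f"figure written to {args.out / 'imbalance.png'}")


if __name__ == "__main__":
    main()
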