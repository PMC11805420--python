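"""Cross-condition statistical battery over a completed benchmark run.

Reads results/benchmark/conditions.csv (from 02_run_benchmark.py) and
reports: Wilcoxon signed-rank comparison of the two algorithms per task,
Friedman tests of the forecast-horizon and mental-state effects, the
identity-line residuals of ordinal vs binary scale-normalized balanced
error, and the Spearman correlations between class imbalance and each
performance metric.  Writes results/stats/*.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from moodcast.stats import (
    compare_algorithms,
    friedman_effect,
    imbalance_correlations,
    task_equivalence_residuals,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument(
        "--conditions", type=Path,
        default=ROOT / "results" / "benchmark" / "conditions.csv",
    )
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "stats")
    args = ap.parse_args()

    df = pd.read_csv(args.conditions)
    args.out.mkdir(parents=True, exist_ok=True)
    rows = []

    for task, metric in (("ordinal", "mamae"), ("binary", "bacc")):
        sub = df[df.task == task]
        if sub.empty:
            continue
        if set(sub.algorithm) == {"gbt", "rnn"}:
            res = compare_algorithms(df, task, metric)
            rows.append({"test": f"{res.test}_{task}", "statistic": res.statistic,
                         "p_value": res.p_value})
        for factor in ("horizon", "item"):
            if sub[factor].nunique() > 1:
                res = friedman_effect(df, factor, task, metric)
                rows.append({"test": f"{res.test}_{task}", "statistic": res.statistic,
                             "p_value": res.p_value})

    if set(df.task) == {"ordinal", "binary"}:
        res = task_equivalence_residuals(df)
        rows.append({"test": res.test, "statistic": res.statistic, "p_value": None})
        res.table.to_csv(args.out / "task_equivalence.csv", index=False)
        print(f"ordinal vs binary mean residual (common 0-1 error scale): "
              f"{res.extra['mean_residual']:+.4f} (sd {res.extra['sd_residual']:.4f})")
        for c in imbalance_correlations(df):
            rows.append({"test": c.test, "statistic": c.statistic, "p_value": c.p_value})

    table = pd.DataFrame(rows)
    table.to_csv(args.out / "comparisons.csv", index=False)
    print(table.to_string(index=False))
    print(f"written to {args.out}")


if __name__ == "__main__":
    main()
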