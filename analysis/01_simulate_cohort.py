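"""Generate a synthetic digital-phenotyping cohort and write it to CSV.

Produces sensing.csv (one row per participant x day x 6-hour period) and
surveys.csv (one row per participant x survey date, 10 ordinal items) under
results/cohort/, plus a summary of realized label marginals against their
targets.  Pass --small for a desk-scale cohort, a YAML config via --config,
or rely on the full-study defaults (60 participants, 365 days).
"""

import argparse
from pathlib import Path

import pandas as pd

from moodcast import CohortConfig, generate_cohort
from moodcast.cohort import DEFAULT_ITEM_MARGINALS, write_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--config", type=Path, help="YAML/JSON cohort config")
    ap.add_argument("--small", action="store_true", help="20 participants x 120 days")
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "cohort")
    args = ap.parse_args()

    if args.config:
        cfg = CohortConfig.from_file(args.config)
    elif args.small:
        cfg = CohortConfig(n_participants=20, days_per_participant=120, seed=args.seed)
    else:
        cfg = CohortConfig(seed=args.seed)

    sensing, surveys = generate_cohort(cfg)
    write_cohort(sensing, surveys, args.out)

    n_ratings = len(surveys) * 10
    print(f"cohort: {cfg.n_participants} participants, {len(surveys)} surveys, "
          f"{n_ratings} rated items, {len(sensing)} sensing rows")
    rows = []
    for item, target in DEFAULT_ITEM_MARGINALS.items():
        props = surveys[item].value_counts(normalize=True).reindex([0, 1, 2, 3]).fillna(0)
        rows.append({"item": item,
                     **{f"target_{c}": target[c] for c in range(4)},
                     **{f"realized_{c}": round(props[c], 3) for c in range(4)}})
    summary = pd.DataFrame(rows)
    summary.to_csv(args.out / "marginals.csv", index=False)
    print(summary.to_string(index=False))
    print(f"written to {args.out}")


if __name__ == "__main__":
    main()
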