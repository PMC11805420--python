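"""End-to-end orchestration of the factorial forecasting benchmark.

The full default grid crosses 10 mental-state items x 3 forecast horizons
x 2 learning tasks x 2 algorithms = 120 model conditions, with one Monte
Carlo baseline per (item, horizon, task) = 60 baseline conditions shared
by the two algorithms.  Conditions execute independently with
deterministically derived per-condition seeds, and a manifest records
completion so an interrupted run resumes where it stopped.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import models as _models
from .cohort import CohortConfig, generate_cohort
from .items import ITEM_NAMES, binarize, class_imbalance, get_item
from .metrics import evaluate
from .pipeline import (
    HORIZONS,
    SplitSpec,
    build_examples,
    labels,
    time_split,
    write_split_manifest,
)
from .stats import (
    N_BENCHMARK_MODELS,
    compare_algorithms,
    friedman_effect,
    imbalance_correlations,
    monte_carlo_baseline,
    significance_call,
    task_equivalence_residuals,
)

logger = logging.getLogger(__name__)

TASKS = ("ordinal", "binary")
ALGORITHMS = ("gbt", "rnn")


@dataclass(frozen=True)
class BenchmarkConfig:
    cohort: CohortConfig = CohortConfig()
    items: tuple = ITEM_NAMES
    horizons: tuple = HORIZONS
    tasks: tuple = TASKS
    algorithms: tuple = ALGORITHMS
    tuning_trials: int = 10
    rnn_hidden: int = 128
    rnn_epochs: int = 150
    n_baseline_draws: int = 12000
    n_models_for_correction: int = N_BENCHMARK_MODELS
    fixed_binary_threshold: float | None = None  # 0.5 reproduces the naive protocol
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "BenchmarkConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        bad = set(raw) - set(cls.__dataclass_fields__)
        if bad:
            raise ValueError(f"malformed config: unknown keys {sorted(bad)}")
        if "cohort" in raw:
            raw["cohort"] = CohortConfig(**raw["cohort"])
        for key in ("items", "horizons", "tasks", "algorithms"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def build_grid(config: BenchmarkConfig) -> list[dict]:
    """The model-condition grid in a stable order with derived seeds."""
    grid = []
    idx = 0
    for item in config.items:
        for horizon in config.horizons:
            for task in config.tasks:
                for algorithm in config.algorithms:
                    seed = int(
                        np.random.SeedSequence(
                            entropy=config.seed, spawn_key=(idx,)
                        ).generate_state(1)[0]
                        % 2**31
                    )
                    grid.append(
                        {
                            "condition_id": f"{item.replace(' ', '-')}_h{horizon}_{task}_{algorithm}",
                            "item": item,
                            "horizon": horizon,
                            "task": task,
                            "algorithm": algorithm,
                            "seed": seed,
                        }
                    )
                    idx += 1
    return grid


def baseline_conditions(config: BenchmarkConfig) -> list[dict]:
    """One baseline per (item, horizon, task), shared across algorithms."""
    return [
        {"item": item, "horizon": horizon, "task": task}
        for item in config.items
        for horizon in config.horizons
        for task in config.tasks
    ]


@dataclass
class BenchmarkResult:
    config: BenchmarkConfig
    manifest: dict
    conditions: pd.DataFrame  # one row per model condition with all numbers
    comparisons: dict = field(default_factory=dict)
    prediction_sets: dict = field(default_factory=dict)

    @property
    def n_conditions(self) -> int:
        return len(self.manifest["conditions"])

    def report_markdown(self) -> str:
        lines = [
            "# Benchmark report",
            "",
            f"- model conditions: {self.n_conditions}",
            f"- baseline conditions: {self.manifest['n_baseline_conditions']}",
            f"- corrected alpha: {self.manifest['alpha_corrected']:.6g}",
            "",
            self.conditions.to_markdown(index=False),
        ]
        for name, comp in self.comparisons.items():
            if isinstance(comp, list):
                for c in comp:
                    lines.append(f"- {c.test}: statistic={c.statistic:.4g}, p={c.p_value:.4g}")
            else:
                lines.append(
                    f"- {comp.test}: statistic={comp.statistic:.4g}, p={comp.p_value:.4g}"
                )
        return "\n".join(lines)


def _condition_metrics(pred_set, baseline, call, cond, all_labels) -> dict:
    rep = evaluate(pred_set.y_true, pred_set.y_pred, cond["task"])
    return {
        "condition_id": cond["condition_id"],
        "item": cond["item"],
        "horizon": cond["horizon"],
        "task": cond["task"],
        "algorithm": cond["algorithm"],
        "mamae": rep.mamae,
        "mae": rep.mae,
        "acc": rep.acc,
        "bacc": rep.bacc,
        "nbe": rep.nbe,
        "imbalance": class_imbalance(all_labels),
        "test_metric": rep.mamae if cond["task"] == "ordinal" else rep.bacc,
        "baseline_mean": float(np.mean(baseline.samples)),
        "baseline_threshold": call.threshold,
        "significant": call.is_significant,
        "resolution_limited": call.resolution_limited,
        "n_test": len(pred_set.y_true),
    }


def run_benchmark(
    config: BenchmarkConfig,
    out_dir: str | Path | None = None,
    split_spec: SplitSpec = SplitSpec(),
) -> BenchmarkResult:
    """Generate data, train every grid condition, evaluate and test.

    With ``out_dir`` set, per-condition predictions and metrics are written
    as CSV/JSON and a manifest tracks completion; re-running with the same
    ``out_dir`` skips conditions whose artifacts already exist.
    """
    out = Path(out_dir) if out_dir is not None else None
    manifest_path = out / "manifest.json" if out else None
    manifest: dict = {"conditions": {}, "config_seed": config.seed}
    if manifest_path and manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())

    sensing, surveys = generate_cohort(config.cohort)
    assignment = time_split(surveys, split_spec)
    if out:
        out.mkdir(parents=True, exist_ok=True)
        write_split_manifest(assignment, out / "split_manifest.json")

    # cache of (horizon, item) -> raw DatasetSplit
    split_cache: dict = {}

    def get_split(horizon, item):
        key = (horizon, item)
        if key not in split_cache:
            split_cache[key] = build_examples(sensing, assignment, horizon, item)
        return split_cache[key]

    # baselines per (item, horizon, task)
    baselines: dict = {}
    for i, bc in enumerate(baseline_conditions(config)):
        split = get_split(bc["horizon"], bc["item"])
        ytr = labels(split.train)
        yte = labels(split.test)
        if bc["task"] == "binary":
            item = get_item(bc["item"])
            ytr, yte = binarize(ytr, item), binarize(yte, item)
        metric = "mamae" if bc["task"] == "ordinal" else "bacc"
        bseed = int(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(10_000 + i,))
            .generate_state(1)[0] % 2**31
        )
        baselines[(bc["item"], bc["horizon"], bc["task"])] = monte_carlo_baseline(
            ytr, yte, metric, n_draws=config.n_baseline_draws, seed=bseed, condition=bc
        )

    rows = []
    prediction_sets = {}
    grid = build_grid(config)
    for cond in grid:
        cid = cond["condition_id"]
        metrics_file = out / f"{cid}_metrics.json" if out else None
        if (
            manifest["conditions"].get(cid, {}).get("status") == "complete"
            and metrics_file is not None
            and metrics_file.exists()
        ):
            rows.append(json.loads(metrics_file.read_text()))
            logger.info("resume: skipping completed condition %s", cid)
            continue
        t0 = time.time()
        split = get_split(cond["horizon"], cond["item"])
        mc = _models.ModelConfig(
            algorithm=cond["algorithm"],
            task=cond["task"],
            item=cond["item"],
            horizon=cond["horizon"],
            tuning_trials=config.tuning_trials,
            seed=cond["seed"],
            rnn_hidden=config.rnn_hidden,
            rnn_epochs=config.rnn_epochs,
            fixed_binary_threshold=config.fixed_binary_threshold,
        )
        fitted = _models.train(split, mc)
        pred_set = fitted.predict(split.test)
        baseline = baselines[(cond["item"], cond["horizon"], cond["task"])]
        rep = evaluate(pred_set.y_true, pred_set.y_pred, cond["task"])
        model_value = rep.mamae if cond["task"] == "ordinal" else rep.bacc
        call = significance_call(
            baseline, model_value, n_models=config.n_models_for_correction
        )
        all_y = np.concatenate(
            [labels(split.train), labels(split.validation), labels(split.test)]
        )
        if cond["task"] == "binary":
            all_y = binarize(all_y, get_item(cond["item"]))
        row = _condition_metrics(pred_set, baseline, call, cond, all_y)
        rows.append(row)
        prediction_sets[cid] = pred_set
        elapsed = time.time() - t0
        manifest["conditions"][cid] = {"status": "complete", "seconds": round(elapsed, 2)}
        logger.info("condition %s done in %.1fs", cid, elapsed)
        if out:
            out.mkdir(parents=True, exist_ok=True)
            metrics_file.write_text(json.dumps(row, indent=2))
            pred_set.to_frame().to_csv(out / f"{cid}_predictions.csv", index=False)
            manifest["n_baseline_conditions"] = len(baselines)
            manifest["alpha_corrected"] = corrected_alpha(config)
            manifest_path.write_text(json.dumps(manifest, indent=2))

    manifest["n_baseline_conditions"] = len(baselines)
    manifest["alpha_corrected"] = corrected_alpha(config)
    conditions = pd.DataFrame(rows)

    comparisons: dict = {}

    def _try(name, fn, *args):
        # partial grids legitimately lack some cross-condition comparisons
        try:
            comparisons[name] = fn(*args)
        except ValueError as exc:
            logger.info("comparison %s skipped: %s", name, exc)

    for task in config.tasks:
        metric = "mamae" if task == "ordinal" else "bacc"
        if set(config.algorithms) == {"gbt", "rnn"}:
            _try(f"wilcoxon_{task}", compare_algorithms, conditions, task, metric)
        if len(config.horizons) > 1:
            _try(f"friedman_horizon_{task}", friedman_effect, conditions, "horizon", task, metric)
        if len(config.items) > 1:
            _try(f"friedman_item_{task}", friedman_effect, conditions, "item", task, metric)
    if set(config.tasks) == {"ordinal", "binary"}:
        _try("task_equivalence", task_equivalence_residuals, conditions)
        _try("imbalance_correlations", imbalance_correlations, conditions)

    if out:
        out.mkdir(parents=True, exist_ok=True)
        conditions.to_csv(out / "conditions.csv", index=False)
        manifest_path.write_text(json.dumps(manifest, indent=2))

    return BenchmarkResult(
        config=config,
        manifest=manifest,
        conditions=conditions,
        comparisons=comparisons,
        prediction_sets=prediction_sets,
    )


def corrected_alpha(config: BenchmarkConfig) -> float:
    """Per-model Bonferroni-corrected alpha for this benchmark family."""
    from .stats import FAMILY_ALPHA

    return FAMILY_ALPHA / config.n_models_for_correction
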