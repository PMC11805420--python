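"""Monte Carlo baselines, significance calls and cross-condition tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from moodcast.stats import (
    BaselineDistribution,
    compare_algorithms,
    friedman_effect,
    imbalance_correlations,
    monte_carlo_baseline,
    significance_call,
    task_equivalence_residuals,
)


class TestMonteCarloBaseline:
    def test_degenerate_training_labels_give_zero_variance(self):
        bl = monte_carlo_baseline([2] * 50, [0, 1, 2, 3] * 5, "mamae", n_draws=200, seed=0)
        assert np.ptp(bl.samples) == 0.0

    def test_uniform_binary_baseline_centred_at_half(self):
        train = [0, 1] * 50
        test = [0] * 50 + [1] * 50
        bl = monte_carlo_baseline(train, test, "bacc", n_draws=1000, seed=1)
        assert bl.samples.mean() == pytest.approx(0.5, abs=0.02)

    def test_same_seed_reproduces_samples(self):
        a = monte_carlo_baseline([0, 1, 2], [0, 1, 2, 3], "mamae", n_draws=100, seed=9)
        b = monte_carlo_baseline([0, 1, 2], [0, 1, 2, 3], "mamae", n_draws=100, seed=9)
        assert np.array_equal(a.samples, b.samples)

    def test_single_class_test_labels_reject_bacc(self):
        with pytest.raises(ValueError):
            monte_carlo_baseline([0, 1], [1, 1, 1], "bacc")

    def test_empty_labels_rejected(self):
        with pytest.raises(ValueError):
            monte_carlo_baseline([], [0, 1], "mamae")


class TestSignificanceCall:
    def _dist(self, samples, direction="lower"):
        return BaselineDistribution(
            condition={}, metric="mamae" if direction == "lower" else "bacc",
            samples=np.asarray(samples, dtype=float), n_draws=len(samples),
            better_direction=direction,
        )

    def test_bonferroni_corrected_alpha(self):
        call = significance_call(self._dist(np.linspace(0, 1, 12000)), 0.0)
        assert call.alpha_corrected == pytest.approx(0.05 / 120)
        assert f"{call.alpha_corrected:.1e}" == "4.2e-04"

    def test_model_at_threshold_not_significant(self):
        samples = np.linspace(0, 1, 12000)
        call = significance_call(self._dist(samples), 0.0)
        at = significance_call(self._dist(samples), call.threshold)
        assert not at.is_significant
        below = significance_call(self._dist(samples), call.threshold - 1e-9)
        assert below.is_significant

    def test_thousand_draws_is_resolution_limited(self):
        call = significance_call(self._dist(np.linspace(0, 1, 1000)), 0.5)
        assert call.resolution_limited
        assert call.threshold == 0.0  # extreme order statistic
        full = significance_call(self._dist(np.linspace(0, 1, 12000)), 0.5)
        assert not full.resolution_limited

    def test_upper_tail_for_higher_is_better(self):
        samples = np.linspace(0, 1, 12000)
        call = significance_call(self._dist(samples, "higher"), 0.9999)
        assert call.threshold > 0.99
        assert not significance_call(self._dist(samples, "higher"), 0.5).is_significant


def _condition_frame(values: dict) -> pd.DataFrame:
    """(item, horizon, algorithm) grid for one task with given metric values."""
    rows = []
    for (item, horizon, algo), v in values.items():
        rows.append(
            {"item": item, "horizon": horizon, "algorithm": algo, "task": "ordinal",
             "mamae": v}
        )
    return pd.DataFrame(rows)


class TestWilcoxon:
    def _frame(self, gbt_vals, rnn_vals):
        keys = list(itertools.product("ABCDEFGHIJ", (0, 1, 7)))
        vals = {}
        for k, g, r in zip(keys, gbt_vals, rnn_vals):
            vals[(*k, "gbt")] = g
            vals[(*k, "rnn")] = r
        return _condition_frame(vals)

    def test_identical_vectors_give_p_one(self):
        v = np.linspace(0.8, 1.2, 30)
        res = compare_algorithms(self._frame(v, v), "ordinal", "mamae")
        assert res.p_value == 1.0
        assert res.statistic == 0.0

    def test_uniform_advantage_is_significant(self):
        v = np.linspace(0.8, 1.2, 30)
        res = compare_algorithms(self._frame(v, v + 0.1), "ordinal", "mamae")
        assert res.p_value < 0.001

    def test_exact_p_matches_sign_flip_enumeration(self):
        rng = np.random.default_rng(4)
        g = rng.normal(1.0, 0.1, 10)
        r = g + rng.normal(0.02, 0.05, 10)
        keys = list(itertools.product("ABCDE", (0, 1)))
        vals = {}
        for k, gv, rv in zip(keys, g, r):
            vals[(*k, "gbt")] = gv
            vals[(*k, "rnn")] = rv
        res = compare_algorithms(_condition_frame(vals), "ordinal", "mamae")

        d = g - r
        ranks = sps.rankdata(np.abs(d))
        obs = ranks[d > 0].sum()
        total = ranks.sum()
        dist = []
        for signs in itertools.product([0, 1], repeat=len(d)):
            dist.append(sum(rk for rk, s in zip(ranks, signs) if s))
        dist = np.asarray(dist, dtype=float)
        p_exact = min(
            1.0,
            2 * min((dist <= obs).mean(), (dist >= obs).mean()),
        )
        assert res.p_value == pytest.approx(p_exact, abs=1e-8)

    def test_unpaired_conditions_rejected(self):
        frame = self._frame(np.ones(30), np.ones(30)).iloc[:-1]
        with pytest.raises(ValueError):
            compare_algorithms(frame, "ordinal", "mamae")


class TestFriedman:
    def _frame(self, data, factor="horizon"):
        rows = []
        for b, row in enumerate(data):
            for j, v in enumerate(row):
                rows.append(
                    {"item": f"I{b % 10}", "algorithm": ("gbt", "rnn")[b // 10],
                     "horizon": (0, 1, 7)[j], "task": "ordinal", "mamae": v}
                )
        return pd.DataFrame(rows)

    def test_identical_treatments_degenerate(self):
        data = np.tile(np.arange(20)[:, None], (1, 3)).astype(float)
        res = friedman_effect(self._frame(data), "horizon", "ordinal", "mamae")
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_uniformly_worst_treatment_matches_rank_oracle(self):
        rng = np.random.default_rng(0)
        data = rng.normal(0, 0.01, (20, 3))
        data[:, 2] += 1.0  # last horizon uniformly worst
        res = friedman_effect(self._frame(data), "horizon", "ordinal", "mamae")

        # brute-force Friedman statistic from rank arithmetic
        ranks = np.vstack([sps.rankdata(row) for row in data])
        n, k = ranks.shape
        rj = ranks.sum(axis=0)
        q = 12.0 / (n * k * (k + 1)) * (rj**2).sum() - 3 * n * (k + 1)
        assert res.statistic == pytest.approx(q, abs=1e-8)
        assert res.p_value < 0.001

    def test_null_statistic_close_to_chi_square(self):
        rng = np.random.default_rng(1)
        reps = 2000
        qs = np.empty(reps)
        for i in range(reps):
            data = rng.standard_normal((20, 3))
            ranks = np.vstack([sps.rankdata(row) for row in data])
            rj = ranks.sum(axis=0)
            qs[i] = 12.0 / (20 * 3 * 4) * (rj**2).sum() - 3 * 20 * 4
        assert qs.mean() == pytest.approx(2.0, abs=0.2)
        assert np.quantile(qs, 0.95) == pytest.approx(sps.chi2.ppf(0.95, 2), abs=0.8)

    def test_incomplete_blocks_rejected(self):
        data = np.ones((20, 3))
        frame = self._frame(data).iloc[:-1]
        with pytest.raises(ValueError):
            friedman_effect(frame, "horizon", "ordinal", "mamae")


class TestSpearman:
    def _frame(self):
        rng = np.random.default_rng(2)
        rows = []
        for task in ("ordinal", "binary"):
            for i in range(30):
                imb = rng.uniform(0, 0.8)
                rows.append(
                    {"task": task, "imbalance": imb,
                     "mamae": imb + rng.normal(0, 0.1),
                     "mae": -imb + rng.normal(0, 0.1),
                     "bacc": -imb + rng.normal(0, 0.1),
                     "acc": imb + rng.normal(0, 0.1)}
                )
        return pd.DataFrame(rows)

    def test_six_correlations_reported(self):
        out = imbalance_correlations(self._frame())
        assert len(out) == 6
        by_name = {r.test: r.statistic for r in out}
        assert by_name["spearman_ordinal_imbalance_vs_mamae"] > 0
        assert by_name["spearman_ordinal_imbalance_vs_mae"] < 0

    def test_tied_ranks_match_average_rank_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 3.0, 3.0, 5.0, 4.0, 6.0, 7.0])

        def avg_ranks(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sv[j] == sv[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2
                i = j
            return ranks

        rx, ry = avg_ranks(x), avg_ranks(y)
        rho_oracle = np.corrcoef(rx, ry)[0, 1]
        assert sps.spearmanr(x, y).statistic == pytest.approx(rho_oracle, abs=1e-8)

    def test_constant_vector_rejected(self):
        frame = self._frame()
        frame["imbalance"] = 0.5
        with pytest.raises(ValueError):
            imbalance_correlations(frame)


class TestTaskEquivalence:
    def _frame(self, ordinal_nbe, binary_nbe):
        rows = []
        keys = list(itertools.product("ABCDE", ("gbt", "rnn"), (0, 1, 7)))
        for (item, algo, h), o, b in zip(keys, ordinal_nbe, binary_nbe):
            rows.append({"item": item, "algorithm": algo, "horizon": h,
                         "task": "ordinal", "nbe": o})
            rows.append({"item": item, "algorithm": algo, "horizon": h,
                         "task": "binary", "nbe": b})
        return pd.DataFrame(rows)

    def test_identical_errors_give_zero_mean_residual(self):
        v = np.linspace(0.2, 0.5, 30)
        res = task_equivalence_residuals(self._frame(v, v))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_uniform_offset_recovered(self):
        v = np.linspace(0.2, 0.5, 30)
        res = task_equivalence_residuals(self._frame(v + 0.1, v))
        assert res.statistic == pytest.approx(0.1)

    def test_unmatched_pairs_rejected(self):
        v = np.linspace(0.2, 0.5, 30)
        frame = self._frame(v, v).iloc[:-1]
        with pytest.raises(ValueError):
            task_equivalence_residuals(frame)
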