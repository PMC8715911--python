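"""Distribution/responsiveness screening statistics against textbook formulas."""

import numpy as np
import pandas as pd
import pytest

from sdamaw.core_data import MetricMeta, MetricTable, StreamflowClass
from sdamaw.screening import (
    DOMINANCE_MAX,
    pct_dominance,
    responsiveness_stats,
    screen_metrics,
)

E, I, P = StreamflowClass.EPHEMERAL, StreamflowClass.INTERMITTENT, StreamflowClass.PERENNIAL


def welch_t_oracle(a, b):
    # textbook Welch statistic: (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b)
    a, b = np.asarray(a, float), np.asarray(b, float)
    return (a.mean() - b.mean()) / np.sqrt(
        a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b)
    )


def anova_f_oracle(groups):
    # textbook one-way ANOVA: between-group over within-group mean squares
    groups = [np.asarray(g, float) for g in groups]
    grand = np.concatenate(groups).mean()
    k = len(groups)
    n = sum(len(g) for g in groups)
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    return (ssb / (k - 1)) / (ssw / (n - k))


class TestPctDominance:
    @pytest.mark.parametrize(
        "values, expected",
        [([0, 0, 0, 1, 2], 60.0), ([7] * 9, 100.0), (list(range(20)), 5.0)],
    )
    def test_modal_frequency(self, values, expected):
        assert pct_dominance(values) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pct_dominance([])

    def test_lower_bound_is_uniform(self, rng):
        v = rng.normal(size=37)
        assert pct_dominance(v) >= 100.0 / 37


def _standardized(z):
    z = np.asarray(z, float)
    return (z - z.mean()) / z.std(ddof=1)


class TestResponsivenessStats:
    def test_identical_metric_gives_zero_statistics(self):
        values = [3.0, 3.0, 5.0, 5.0, 3.0, 3.0, 5.0, 5.0, 3.0, 5.0, 3.0, 5.0]
        truth = [E, E, E, E, I, I, I, I, P, P, P, P]
        flow = ["dry"] * 4 + ["dry", "dry", "flowing", "flowing"] + ["flowing"] * 4
        s = responsiveness_stats(values, truth, flow)
        assert s.F_PvIvE == pytest.approx(0.0, abs=1e-12)
        assert s.t_EvALI == pytest.approx(0.0, abs=1e-12)
        assert s.t_PvNP == pytest.approx(0.0, abs=1e-12)

    def test_separated_groups_give_large_t(self, rng):
        # E mean 0, at-least-intermittent mean 10, sd exactly 1, n = 10 per
        # group: Welch t = 10 / sqrt(1/10 + 1/10) = 22.36
        e_vals = _standardized(rng.normal(size=10))
        ali_vals = 10.0 + _standardized(rng.normal(size=10))
        values = np.concatenate([e_vals, ali_vals])
        truth = [E] * 10 + [I] * 5 + [P] * 5
        flow = ["dry"] * 10 + ["flowing"] * 10
        s = responsiveness_stats(values, truth, flow)
        assert abs(s.t_EvALI) == pytest.approx(10 / np.sqrt(0.2), rel=1e-9)
        assert abs(s.t_EvALI) == pytest.approx(22.36, abs=0.01)

    def test_matches_textbook_formulas(self, rng):
        for _ in range(25):
            n = rng.integers(4, 15, size=3)
            vals = [rng.normal(rng.uniform(0, 3), rng.uniform(0.5, 2), size=k) for k in n]
            values = np.concatenate(vals)
            truth = [E] * n[0] + [I] * n[1] + [P] * n[2]
            flow = list(rng.choice(["dry", "flowing"], size=n.sum()))
            s = responsiveness_stats(values, truth, flow)
            assert s.F_PvIvE == pytest.approx(anova_f_oracle(vals), abs=1e-10)
            assert s.t_EvALI == pytest.approx(
                welch_t_oracle(vals[0], np.concatenate(vals[1:])), abs=1e-10
            )
            assert s.t_PvNP == pytest.approx(
                welch_t_oracle(vals[2], np.concatenate(vals[:2])), abs=1e-10
            )

    def test_small_group_flagged_undefined(self):
        values = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        truth = [E, E, I, I, P, P]
        flow = ["dry"] * 6  # no flowing intermittent rows at all
        s = responsiveness_stats(values, truth, flow)
        assert np.isnan(s.t_PvIwet)


def _table(columns: dict) -> MetricTable:
    n = len(next(iter(columns.values())))
    idx = pd.MultiIndex.from_tuples(
        [(f"R{i}", 1) for i in range(n)], names=["reach_id", "visit_index"]
    )
    data = pd.DataFrame(columns, index=idx)
    meta = {c: MetricMeta("biological") for c in columns}
    return MetricTable(data, meta)


class TestScreenMetrics:
    def _setup(self, rng, n_per_class=30):
        truth_seq = [E] * n_per_class + [I] * n_per_class + [P] * n_per_class
        encoded = np.repeat([0.0, 5.0, 10.0], n_per_class) + rng.normal(
            0, 0.5, 3 * n_per_class
        )
        columns = {"encoded": encoded, "constant": np.full(3 * n_per_class, 7.0)}
        for j in range(10):
            columns[f"noise_{j}"] = rng.normal(size=3 * n_per_class)
        table = _table(columns)
        truth = {f"R{i}": c for i, c in enumerate(truth_seq)}
        flow = {key: ("dry" if truth[key[0]] is E else "flowing") for key in table.data.index}
        return table, truth, flow

    def test_class_encoding_metric_passes(self, rng):
        table, truth, flow = self._setup(rng)
        decisions = screen_metrics(table, truth, flow, seed=1, n_trees=100)
        assert decisions["encoded"].passed

    def test_constant_metric_fails_distribution(self, rng):
        table, truth, flow = self._setup(rng)
        decisions = screen_metrics(table, truth, flow, seed=1, n_trees=100)
        d = decisions["constant"]
        assert not d.passed_distribution and not d.passed
        assert d.stats.pct_dominance == 100.0 >= DOMINANCE_MAX

    def test_most_noise_fails_against_strong_competitor(self, rng):
        table, truth, flow = self._setup(rng)
        decisions = screen_metrics(table, truth, flow, seed=1, n_trees=100)
        noise_pass = sum(decisions[f"noise_{j}"].passed for j in range(10))
        # each pure-noise metric trips a |t|>2 / F>2 criterion only by chance
        assert noise_pass <= 5

    def test_top_quartile_share(self, rng):
        table, truth, flow = self._setup(rng)
        decisions = screen_metrics(table, truth, flow, seed=1, n_trees=100)
        credited = sum(
            d.stats.mda_quartile_rank >= 0.75 for d in decisions.values()
        )
        n = len(decisions)
        assert abs(credited - 0.25 * n) <= 1 + 0.25 * n * 0.5  # ties may widen slightly

    def test_signal_metrics_pass_at_thirty_per_class(self, rng):
        # standardized mean separation >= 2 between adjacent classes
        n = 30
        truth_seq = [E] * n + [I] * n + [P] * n
        columns = {
            f"signal_{j}": np.repeat([0.0, 2.5, 5.0], n) + rng.normal(0, 1, 3 * n)
            for j in range(4)
        }
        for j in range(8):
            columns[f"noise_{j}"] = rng.normal(size=3 * n)
        table = _table(columns)
        truth = {f"R{i}": c for i, c in enumerate(truth_seq)}
        flow = {key: "flowing" for key in table.data.index}
        decisions = screen_metrics(table, truth, flow, seed=2, n_trees=100)
        assert all(decisions[f"signal_{j}"].passed for j in range(4))
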