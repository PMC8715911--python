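"""Metric distribution and responsiveness screening.

Each candidate metric must pass one distribution criterion (the most common
value accounts for <95% of visits) and at least one responsiveness criterion:

* one-way ANOVA F > 2 across the three flow-duration classes,
* |Welch t| > 2 for any of four two-group contrasts (ephemeral vs at-least-
  intermittent; perennial vs non-perennial; perennial vs flowing-intermittent;
  ephemeral vs dry-intermittent), or
* permutation importance (mean decrease in accuracy) in the top quartile of
  all screened metrics in a random-forest model predicting the 3-way class.

Screening uses initial visits only; revisit rows must be withheld upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .core_data import MetricTable, StreamflowClass

__all__ = [
    "ScreeningStats",
    "ScreeningDecision",
    "pct_dominance",
    "responsiveness_stats",
    "screen_metrics",
    "DOMINANCE_MAX",
    "STATISTIC_MIN",
]

#: Distribution criterion: percent dominance of the most common value must be < this.
DOMINANCE_MAX = 95.0
#: Responsiveness criterion for F and |t| statistics.
STATISTIC_MIN = 2.0


@dataclass
class ScreeningStats:
    """Screening statistics for one metric. NaN marks an undefined statistic."""

    pct_dominance: float
    F_PvIvE: float
    t_EvALI: float
    t_PvNP: float
    t_PvIwet: float
    t_EvIdry: float
    mda: float = np.nan
    mda_quartile_rank: float = np.nan  # in (0, 1]; 1 = most important


@dataclass
class ScreeningDecision:
    passed_distribution: bool
    passed_responsiveness: bool
    reasons: list = field(default_factory=list)
    stats: Optional[ScreeningStats] = None

    @property
    def passed(self) -> bool:
        return self.passed_distribution and self.passed_responsiveness


def pct_dominance(values: Sequence[float]) -> float:
    """Percent of rows holding the most common value (ties share the max count)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("pct_dominance of an empty vector is undefined")
    _, counts = np.unique(arr, return_counts=True)
    return 100.0 * counts.max() / arr.size


def _welch_t(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample Welch t statistic; NaN when a group is too small or both constant."""
    if len(a) < 2 or len(b) < 2:
        return np.nan
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        return np.nan
    t, _ = stats.ttest_ind(a, b, equal_var=False)
    return float(t)


def _anova_f(groups) -> float:
    if any(len(g) < 2 for g in groups) or len(groups) < 2:
        return np.nan
    if all(np.var(g, ddof=1) == 0 for g in groups):
        return np.nan
    f, _ = stats.f_oneway(*groups)
    return float(f)


def responsiveness_stats(
    values: Sequence[float],
    truth: Sequence[StreamflowClass],
    flow_state: Sequence[str],
    mda: float = np.nan,
    mda_quartile_rank: float = np.nan,
) -> ScreeningStats:
    """Distribution and contrast statistics for one metric.

    ``truth`` gives the true class per row and ``flow_state`` ("dry"/"flowing")
    the condition observed at sampling, which defines the flowing-intermittent
    and dry-intermittent subsets. Statistics that cannot be computed (a group
    with fewer than two rows, or zero variance everywhere) come back NaN and
    count as criterion-not-met.
    """
    x = np.asarray(values, dtype=float)
    cls = np.asarray([StreamflowClass(c).value for c in truth])
    flow = np.asarray(list(flow_state))
    if not (len(x) == len(cls) == len(flow)):
        raise ValueError("values, truth and flow_state must be aligned")
    keep = ~np.isnan(x)
    x, cls, flow = x[keep], cls[keep], flow[keep]
    if x.size == 0:
        raise ValueError("no non-missing values to screen")

    e = x[cls == "Ephemeral"]
    i = x[cls == "Intermittent"]
    p = x[cls == "Perennial"]
    i_wet = x[(cls == "Intermittent") & (flow == "flowing")]
    i_dry = x[(cls == "Intermittent") & (flow == "dry")]

    return ScreeningStats(
        pct_dominance=pct_dominance(x),
        F_PvIvE=_anova_f([e, i, p]),
        t_EvALI=_welch_t(e, np.concatenate([i, p])),
        t_PvNP=_welch_t(p, np.concatenate([e, i])),
        t_PvIwet=_welch_t(p, i_wet),
        t_EvIdry=_welch_t(e, i_dry),
        mda=mda,
        mda_quartile_rank=mda_quartile_rank,
    )


def oob_permutation_importance(
    rf: RandomForestClassifier,
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Mean decrease in accuracy, permuting each feature over out-of-bag rows.

    For every tree, accuracy on its out-of-bag samples is compared with
    accuracy after shuffling one feature among those samples; the drop,
    averaged over trees, is the feature's importance. Computing on
    out-of-bag rather than training rows is what makes the measure
    meaningful for a forest that fits its training data perfectly.
    """
    rng = np.random.default_rng(seed)
    n, p = X.shape
    classes = np.asarray(rf.classes_)
    y_enc = np.searchsorted(classes, y)
    imp = np.zeros(p)
    n_used = 0
    for tree, samples in zip(rf.estimators_, rf.estimators_samples_):
        oob = np.setdiff1d(np.arange(n), samples)
        if len(oob) == 0:
            continue
        n_used += 1
        Xo = X[oob]
        yo = y_enc[oob]
        # one batched predict per tree: row block 0 is unpermuted, block j+1
        # has feature j shuffled
        blocks = [Xo]
        for j in range(p):
            Xp = Xo.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            blocks.append(Xp)
        preds = tree.predict(np.vstack(blocks)).astype(int).reshape(p + 1, len(oob))
        acc = (preds == yo).mean(axis=1)
        imp += acc[0] - acc[1:]
    if n_used == 0:
        raise ValueError("no out-of-bag samples; is the forest bootstrapped?")
    return imp / n_used


def forest_importance(
    data: pd.DataFrame,
    truth: Sequence[StreamflowClass],
    seed: int = 0,
    n_trees: int = 500,
) -> pd.Series:
    """Mean-decrease-in-accuracy importance of every column from one forest fit.

    A single random forest is fit on all metrics predicting the 3-way class;
    importance is the out-of-bag accuracy drop under per-feature permutation.
    """
    y = np.asarray([StreamflowClass(c).value for c in truth])
    X = data.to_numpy(dtype=float)
    if np.isnan(X).any():
        # median-impute for the importance forest only; screening statistics
        # elsewhere use the observed values
        med = np.nanmedian(X, axis=0)
        idx = np.where(np.isnan(X))
        X = X.copy()
        X[idx] = np.take(med, idx[1])
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    rf.fit(X, y)
    return pd.Series(oob_permutation_importance(rf, X, y, seed=seed), index=data.columns)


def screen_metrics(
    table: MetricTable,
    truth: Mapping[str, StreamflowClass],
    flow_state: Mapping[tuple, str],
    seed: int = 0,
    n_trees: int = 500,
) -> "dict[str, ScreeningDecision]":
    """Apply the distribution and responsiveness screens to every metric.

    ``truth`` maps reach_id to its class; ``flow_state`` maps
    (reach_id, visit_index) to "dry"/"flowing". Only initial-visit rows are
    used (enforced here). A metric passes iff its dominance is below 95% and
    at least one responsiveness criterion is met. The importance quartile is
    computed over all metrics entering screening, then intersected with the
    other criteria.
    """
    first = table.initial_visits()
    data = first.data
    if len(data) == 0:
        raise ValueError("no initial-visit rows to screen")
    cls = [truth[rid] for rid in data.index.get_level_values(0)]
    flow = [flow_state[key] for key in data.index]

    mda = forest_importance(data, cls, seed=seed, n_trees=n_trees)
    # rank-based quartile; ties share the better (higher) rank fraction
    ranks = stats.rankdata(mda.to_numpy(), method="max") / len(mda)
    rank_by_metric = pd.Series(ranks, index=mda.index)

    decisions = {}
    for col in data.columns:
        s = responsiveness_stats(
            data[col].to_numpy(),
            cls,
            flow,
            mda=float(mda[col]),
            mda_quartile_rank=float(rank_by_metric[col]),
        )
        reasons = []
        dist_ok = s.pct_dominance < DOMINANCE_MAX
        if not dist_ok:
            reasons.append(
                f"dominance {s.pct_dominance:.1f}% >= {DOMINANCE_MAX:.0f}%"
            )
        crits = {
            "F_PvIvE": (not np.isnan(s.F_PvIvE)) and s.F_PvIvE > STATISTIC_MIN,
            "t_EvALI": (not np.isnan(s.t_EvALI)) and abs(s.t_EvALI) > STATISTIC_MIN,
            "t_PvNP": (not np.isnan(s.t_PvNP)) and abs(s.t_PvNP) > STATISTIC_MIN,
            "t_PvIwet": (not np.isnan(s.t_PvIwet)) and abs(s.t_PvIwet) > STATISTIC_MIN,
            "t_EvIdry": (not np.isnan(s.t_EvIdry)) and abs(s.t_EvIdry) > STATISTIC_MIN,
            "mda_top_quartile": s.mda_quartile_rank >= 0.75,
        }
        resp_ok = any(crits.values())
        if resp_ok:
            reasons.extend(name for name, ok in crits.items() if ok)
        else:
            reasons.append("no responsiveness criterion met")
        decisions[col] = ScreeningDecision(
            passed_distribution=dist_ok,
            passed_responsiveness=resp_ok,
            reasons=reasons,
            stats=s,
        )
    return decisions


def passed_metrics(decisions: Mapping[str, ScreeningDecision]) -> list:
    return [m for m, d in decisions.items() if d.passed]
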