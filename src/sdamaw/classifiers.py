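"""Ensemble/tree classifiers, the vote-threshold decision rule, and threshold sweep.

The calibrated model is either a bagged random forest (1500 trees, sqrt(p)
candidate features per split) or a single pruned classification tree. A
forest emits, for each reach, the fraction of trees voting each flow-duration
class; a single tree emits a degenerate vote of 1 for its leaf class.

Votes are turned into one of five outcomes by a confidence threshold tau:
a class with at least tau of the votes wins outright; failing that, if the
combined intermittent + perennial votes reach tau the reach is "At least
intermittent"; otherwise "Need more information".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from .core_data import PredictedClass, StreamflowClass

__all__ = [
    "VoteVector",
    "ClassifierModel",
    "fit_classifier",
    "vote_threshold_classify",
    "threshold_sweep",
    "DEFAULT_TAU",
    "TAU_GRID",
]

#: Minimum vote share recommended for a confident classification.
DEFAULT_TAU = 0.5
#: Threshold sweep grid: 50% to 100% in 2.5% increments.
TAU_GRID = np.round(np.arange(0.50, 1.0001, 0.025), 4)

_CLASS_ORDER = ("Ephemeral", "Intermittent", "Perennial")


@dataclass(frozen=True)
class VoteVector:
    """Per-class vote fractions plus the decision threshold."""

    v_E: float
    v_I: float
    v_P: float
    tau: float = DEFAULT_TAU

    def __post_init__(self) -> None:
        total = self.v_E + self.v_I + self.v_P
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"votes must sum to 1, got {total}")
        if not 0.5 <= self.tau <= 1.0:
            raise ValueError(f"tau must be in [0.5, 1.0], got {self.tau}")

    def as_array(self) -> np.ndarray:
        return np.array([self.v_E, self.v_I, self.v_P])


@dataclass
class ClassifierModel:
    """A fitted forest or single-tree classifier over a fixed metric list."""

    kind: str  # "forest" | "single_tree"
    estimator: object
    metric_names: tuple
    seed: int
    n_trees: Optional[int] = None

    def predict_votes(self, X: Union[pd.DataFrame, np.ndarray]) -> np.ndarray:
        """Vote fractions, shape (n, 3) in (E, I, P) order, rows summing to 1."""
        if isinstance(X, pd.DataFrame):
            X = X[list(self.metric_names)].to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
        if np.isnan(X).any():
            raise ValueError("missing metric values; impute or exclude rows upstream")
        est = self.estimator
        col = {c: j for j, c in enumerate(_CLASS_ORDER)}
        votes = np.zeros((X.shape[0], 3))
        if self.kind == "forest":
            # literal per-tree vote fractions (sub-estimators predict class
            # indices into est.classes_)
            classes = np.asarray(est.classes_)
            counts = np.zeros((X.shape[0], len(classes)))
            for tree in est.estimators_:
                pred = tree.predict(X).astype(int)
                counts[np.arange(X.shape[0]), pred] += 1
            counts /= len(est.estimators_)
            for j, c in enumerate(classes):
                votes[:, col[c]] = counts[:, j]
        else:
            pred = est.predict(X)
            for i, c in enumerate(pred):
                votes[i, col[c]] = 1.0
        return votes

    def vote_vectors(self, X, tau: float = DEFAULT_TAU) -> list:
        return [VoteVector(*row, tau=tau) for row in self.predict_votes(X)]


def fit_classifier(
    data: pd.DataFrame,
    truth: Sequence[StreamflowClass],
    kind: str = "forest",
    seed: int = 0,
    n_trees: int = 1500,
    ccp_alpha: float = 0.01,
    min_samples_split: int = 20,
) -> ClassifierModel:
    """Fit the classification model on calibration initial-visit rows.

    ``kind="forest"`` fits a bagged forest with sqrt(p) candidate features per
    split and ``n_trees`` trees (the method uses 1500). ``kind="single_tree"``
    fits one impurity-based recursive-partitioning tree with cost-complexity
    pruning. Both are deterministic given ``seed``.
    """
    y = np.asarray([StreamflowClass(c).value for c in truth])
    if len(np.unique(y)) < 2:
        raise ValueError("truth is constant; cannot fit a classifier")
    X = data.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing metric values; impute or exclude rows upstream")
    if kind == "forest":
        est = RandomForestClassifier(
            n_estimators=n_trees,
            max_features="sqrt",
            random_state=seed,
            n_jobs=1,
        )
    elif kind == "single_tree":
        est = DecisionTreeClassifier(
            random_state=seed,
            ccp_alpha=ccp_alpha,
            min_samples_split=min_samples_split,
        )
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    est.fit(X, y)
    return ClassifierModel(
        kind=kind,
        estimator=est,
        metric_names=tuple(data.columns),
        seed=seed,
        n_trees=n_trees if kind == "forest" else None,
    )


def vote_threshold_classify(
    votes: Union[VoteVector, Sequence[float]],
    tau: Optional[float] = None,
) -> PredictedClass:
    """Apply the vote-threshold decision rule to one vote vector.

    If exactly one class holds at least tau of the votes, that class is
    returned. A tie at the threshold (possible only at tau = 0.5) resolves to
    At-least-intermittent when the tied classes are {I, P}, and to
    Need-more-information when ephemeral is involved. If no single class
    qualifies but the combined I + P vote reaches tau, the outcome is
    At-least-intermittent; in all other cases, Need-more-information.
    """
    if isinstance(votes, VoteVector):
        v = votes.as_array()
        t = votes.tau if tau is None else tau
    else:
        v = np.asarray(votes, dtype=float)
        t = DEFAULT_TAU if tau is None else tau
        VoteVector(*v, tau=t)  # validates
    qualifying = np.flatnonzero(v >= t)
    if len(qualifying) == 1:
        return PredictedClass(_CLASS_ORDER[qualifying[0]])
    if len(qualifying) >= 2:
        if set(qualifying) == {1, 2}:
            return PredictedClass.AT_LEAST_INTERMITTENT
        return PredictedClass.NEED_MORE_INFORMATION
    if v[1] + v[2] >= t:
        return PredictedClass.AT_LEAST_INTERMITTENT
    return PredictedClass.NEED_MORE_INFORMATION


def threshold_sweep(
    votes: np.ndarray,
    grid: Sequence[float] = TAU_GRID,
) -> pd.DataFrame:
    """Percent of reaches in each outcome at every threshold of the grid.

    ``votes`` has one (v_E, v_I, v_P) row per reach. Returns a DataFrame
    indexed by tau with one column per outcome, rows summing to 100.
    """
    votes = np.asarray(votes, dtype=float)
    if votes.ndim != 2 or votes.shape[1] != 3:
        raise ValueError("votes must be an (n, 3) array")
    outcomes = [c.value for c in PredictedClass]
    rows = []
    for t in grid:
        preds = [vote_threshold_classify(v, tau=float(t)).value for v in votes]
        counts = pd.Series(preds).value_counts()
        rows.append([100.0 * counts.get(o, 0) / len(preds) for o in outcomes])
    return pd.DataFrame(rows, index=pd.Index(np.asarray(grid), name="tau"), columns=outcomes)
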