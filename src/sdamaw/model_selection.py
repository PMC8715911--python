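"""Stratified splitting, Cohen's kappa, and recursive feature elimination.

The development dataset is split 80/20 into calibration and validation sets
at the reach level, stratified by (subregion, true class). Candidate metric
sets are then pruned by recursive feature elimination: starting from all
screened metrics, the least-important five are dropped per step until a
20-metric model remains, then one per step down to a single metric. Each
subset is scored by cross-validated Cohen's kappa, and the smallest subset
within 1% of the best kappa is selected (capped at 20 metrics).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .core_data import Reach, StreamflowClass
from .screening import oob_permutation_importance

__all__ = [
    "SplitAssignment",
    "RfeTrace",
    "stratified_split",
    "cohens_kappa",
    "rfe_select",
]


@dataclass
class SplitAssignment:
    """Reach-level calibration/validation assignment."""

    assignment: dict  # reach_id -> "calibration" | "validation"
    seed: int
    fraction: float

    @property
    def calibration(self) -> list:
        return sorted(r for r, g in self.assignment.items() if g == "calibration")

    @property
    def validation(self) -> list:
        return sorted(r for r, g in self.assignment.items() if g == "validation")


def stratified_split(
    reaches: Sequence[Reach], fraction: float = 0.8, seed: int = 0
) -> SplitAssignment:
    """Split reaches into calibration/validation, stratified by (subregion, class).

    Within each stratum, round(fraction * n) reaches go to calibration and the
    remainder to validation; a stratum of a single reach goes to calibration.
    Deterministic given the seed. Reaches (not visits) are the split unit.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    if len(reaches) == 0:
        raise ValueError("cannot split an empty reach list")
    rng = np.random.default_rng(seed)
    strata: dict = {}
    for r in reaches:
        strata.setdefault((r.subregion, r.true_class), []).append(r.reach_id)
    assignment = {}
    for key in sorted(strata, key=lambda k: (k[0], k[1].value)):
        ids = sorted(strata[key])
        if len(ids) == 1:
            assignment[ids[0]] = "calibration"
            continue
        n_cal = int(np.floor(fraction * len(ids) + 0.5))
        n_cal = min(max(n_cal, 1), len(ids))
        order = rng.permutation(len(ids))
        for pos, idx in enumerate(order):
            assignment[ids[idx]] = "calibration" if pos < n_cal else "validation"
    return SplitAssignment(assignment=assignment, seed=seed, fraction=fraction)


def cohens_kappa(predicted: Sequence, truth: Sequence) -> float:
    """Chance-corrected agreement: kappa = (p_o - p_e) / (1 - p_e).

    ``p_e`` is the expected agreement from the product of marginal label
    frequencies. When both vectors are the same constant, agreement is perfect
    and kappa is defined as 1.
    """
    a = np.asarray([getattr(v, "value", v) for v in predicted])
    b = np.asarray([getattr(v, "value", v) for v in truth])
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("predicted and truth must be equal-length 1-d vectors")
    if a.size == 0:
        raise ValueError("cannot compute kappa of empty vectors")
    labels = np.union1d(a, b)
    n = a.size
    p_o = float(np.mean(a == b))
    p_e = 0.0
    for lab in labels:
        p_e += np.mean(a == lab) * np.mean(b == lab)
    if p_e >= 1.0 - 1e-12:
        if p_o >= 1.0 - 1e-12:
            return 1.0
        raise ValueError("kappa undefined: chance agreement is 1 but vectors differ")
    return (p_o - p_e) / (1.0 - p_e)


@dataclass
class RfeTrace:
    """Record of one recursive-feature-elimination run."""

    steps: list  # [(size, tuple(metrics), kappa)] in schedule order
    selected_size: int
    selected_metrics: tuple

    @property
    def best_kappa(self) -> float:
        return max(k for _, _, k in self.steps)

    @property
    def selected_kappa(self) -> float:
        return next(k for s, _, k in self.steps if s == self.selected_size)


def elimination_schedule(p: int, coarse_step: int = 5, fine_below: int = 20) -> list:
    """Subset sizes visited by RFE: p, p-5, ... down to 20, then 19, ..., 1."""
    if p < 1:
        raise ValueError("need at least one candidate metric")
    sizes = []
    s = p
    while s > fine_below:
        sizes.append(s)
        s = max(s - coarse_step, fine_below)
    sizes.extend(range(min(p, fine_below), 0, -1))
    return sizes


def _cv_kappa(
    X: np.ndarray,
    y: np.ndarray,
    seed: int,
    n_trees: int,
    n_splits: int,
) -> float:
    """Cross-validated Cohen's kappa of a forest on (X, y)."""
    _, counts = np.unique(y, return_counts=True)
    k = min(n_splits, counts.min())
    if k < 2:
        raise ValueError("every class needs at least 2 calibration reaches")
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    preds = np.empty(len(y), dtype=object)
    for fold, (tr, te) in enumerate(cv.split(X, y)):
        rf = RandomForestClassifier(
            n_estimators=n_trees, random_state=seed + fold, n_jobs=1
        )
        rf.fit(X[tr], y[tr])
        preds[te] = rf.predict(X[te])
    return cohens_kappa(preds, y)


def rfe_select(
    data: pd.DataFrame,
    truth: Sequence[StreamflowClass],
    seed: int = 0,
    n_trees: int = 500,
    cv_splits: int = 5,
    tolerance: float = 0.01,
    max_size: int = 20,
    relative_tolerance: bool = True,
) -> RfeTrace:
    """Recursive feature elimination over a calibration metric table.

    ``data`` holds initial-visit calibration rows (columns = candidate metrics
    that passed screening); ``truth`` the class per row. At each scheduled
    size a forest is fit, scored by ``cv_splits``-fold cross-validated kappa,
    and the metrics with the lowest permutation importance (mean decrease in
    accuracy, recomputed every step) are dropped to reach the next size.

    The selected subset is the smallest whose kappa is within ``tolerance`` of
    the best (relative by default: kappa >= (1 - tolerance) * best). If that
    subset is larger than ``max_size``, the ``max_size`` subset is used.
    """
    y = np.asarray([StreamflowClass(c).value for c in truth])
    if len(np.unique(y)) < 2:
        raise ValueError("truth is degenerate (single class); cannot select metrics")
    if data.shape[0] != len(y):
        raise ValueError("data rows and truth must be aligned")
    if data.shape[1] < 1:
        raise ValueError("need at least one candidate metric")

    current = list(data.columns)
    schedule = elimination_schedule(len(current), fine_below=max_size)
    steps = []
    for step_idx, size in enumerate(schedule):
        if len(current) != size:
            raise AssertionError("schedule out of sync with elimination")
        X = data[current].to_numpy(dtype=float)
        kappa = _cv_kappa(X, y, seed=seed + 1000 * step_idx, n_trees=n_trees, n_splits=cv_splits)
        steps.append((size, tuple(current), float(kappa)))
        if size == 1:
            break
        next_size = schedule[step_idx + 1]
        rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
        rf.fit(X, y)
        imp = oob_permutation_importance(rf, X, y, seed=seed)
        order = np.argsort(imp, kind="stable")  # ascending: least important first
        drop = {current[i] for i in order[: size - next_size]}
        current = [m for m in current if m not in drop]

    best = max(k for _, _, k in steps)
    floor = best * (1.0 - tolerance) if relative_tolerance else best - tolerance
    eligible = [s for s, _, k in steps if k >= floor]
    selected_size = min(eligible)
    if selected_size > max_size:
        selected_size = max_size
    selected_metrics = next(m for s, m, _ in steps if s == selected_size)
    return RfeTrace(steps=steps, selected_size=selected_size, selected_metrics=selected_metrics)
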