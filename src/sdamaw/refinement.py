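"""Turning the fitted model into a field method.

Three steps convert a calibrated vote model into a paper form a practitioner
can apply without software:

1. continuous metrics are discretized into a few ordinal categories at cut
   points read off partial-dependence curves (the shipped method uses the
   published cut points: hydrophytes 0 | 1-2 | >=3; invertebrate abundance
   0 | 1-19 | >=20),
2. every admissible combination of the resulting categorical indicators is
   run through the model + vote threshold + single-indicator overrides to
   produce an exhaustive crosswalk (lookup) table, and
3. single indicators (live fish; algal cover >=10%) supersede Ephemeral or
   Need-more-information outcomes, upgrading them to At-least-intermittent.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .classifiers import ClassifierModel, DEFAULT_TAU, vote_threshold_classify
from .core_data import PredictedClass, StreamflowClass

__all__ = [
    "DiscretizationRule",
    "CrosswalkTable",
    "HYDROPHYTE_RULE",
    "INVERTEBRATE_RULE",
    "partial_dependence",
    "partial_dependence_discretize",
    "build_crosswalk_table",
    "apply_single_indicators",
    "evaluate_single_indicator",
]


@dataclass(frozen=True)
class DiscretizationRule:
    """Ordered cut points mapping a numeric metric onto ordinal categories.

    ``cuts`` are left-closed thresholds: a value falls in category ``i`` where
    i is the number of cuts it equals or exceeds. Categories are exhaustive
    over the metric's range.
    """

    metric: str
    cuts: tuple
    labels: tuple

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.cuts) + 1:
            raise ValueError("need exactly one more label than cut points")
        if any(b <= a for a, b in zip(self.cuts, self.cuts[1:])):
            raise ValueError("cut points must be strictly increasing")

    def apply(self, values):
        """Map numeric value(s) to category label(s)."""
        arr = np.atleast_1d(np.asarray(values, dtype=float))
        idx = np.searchsorted(np.asarray(self.cuts, dtype=float), arr, side="right")
        out = np.asarray(self.labels, dtype=object)[idx]
        return out[0] if np.isscalar(values) or np.ndim(values) == 0 else out

    def codes(self, values):
        """Ordinal codes (0..len(labels)-1) instead of labels."""
        arr = np.atleast_1d(np.asarray(values, dtype=float))
        return np.searchsorted(np.asarray(self.cuts, dtype=float), arr, side="right")


#: Published field-method rule: number of hydrophytic plant species.
HYDROPHYTE_RULE = DiscretizationRule(
    "hydrophytes_present_noflag", cuts=(1.0, 3.0), labels=("None", "Few_1_2", "Many_3plus")
)
#: Published field-method rule: total aquatic invertebrate abundance.
INVERTEBRATE_RULE = DiscretizationRule(
    "TotalAbundance", cuts=(1.0, 20.0), labels=("None", "Few_1_19", "Many_20plus")
)


def partial_dependence(
    model: ClassifierModel,
    data: pd.DataFrame,
    metric: str,
    grid: Optional[Sequence[float]] = None,
    n_grid: int = 50,
) -> pd.DataFrame:
    """Partial-dependence of class votes on one metric.

    For each grid value g the metric column is set to g over all rows of
    ``data`` and the model's mean vote per class recorded. Count-like metrics
    default to their observed unique values as the grid; continuous metrics
    to an ``n_grid``-point linear grid over the observed range.
    """
    if metric not in model.metric_names:
        raise ValueError(f"metric {metric!r} is not in the model")
    col = data[metric].to_numpy(dtype=float)
    if grid is None:
        uniq = np.unique(col[~np.isnan(col)])
        if len(uniq) <= n_grid and np.allclose(uniq, np.round(uniq)):
            grid = uniq
        else:
            grid = np.linspace(uniq.min(), uniq.max(), n_grid)
    X = data[list(model.metric_names)].copy()
    rows = []
    for g in grid:
        X[metric] = float(g)
        rows.append(model.predict_votes(X).mean(axis=0))
    return pd.DataFrame(
        rows, index=pd.Index(np.asarray(grid), name=metric),
        columns=["v_E", "v_I", "v_P"],
    )


def propose_cuts(curve: pd.DataFrame, min_jump: float = 0.05, max_cuts: int = 2) -> list:
    """Cut points segmenting a partial-dependence curve into near-constant pieces.

    The curve (grid x class-vote shares) is fit by the least-squares step
    function with up to ``max_cuts`` breaks; breaks whose between-segment
    vote-share difference (largest over classes) falls below ``min_jump``
    are merged away. A flat curve therefore yields no cuts. Cut points are
    left-closed: a cut at grid value g starts the next category at g,
    matching :class:`DiscretizationRule`.
    """
    grid = curve.index.to_numpy(dtype=float)
    Y = curve.to_numpy(dtype=float)
    n = len(grid)
    if n < 2:
        return []

    prefix = np.vstack([np.zeros(Y.shape[1]), np.cumsum(Y, axis=0)])
    prefix_sq = np.vstack([np.zeros(Y.shape[1]), np.cumsum(Y**2, axis=0)])

    def sse(a: int, b: int) -> float:  # rows [a, b)
        m = b - a
        s = prefix[b] - prefix[a]
        sq = prefix_sq[b] - prefix_sq[a]
        return float((sq - s**2 / m).sum())

    def seg_mean(a: int, b: int) -> np.ndarray:
        return (prefix[b] - prefix[a]) / (b - a)

    best_breaks: list = []
    if max_cuts >= 1:
        candidates = [([i], sse(0, i) + sse(i, n)) for i in range(1, n)]
        if max_cuts >= 2 and n >= 3:
            left = {i: sse(0, i) for i in range(1, n)}
            for i in range(1, n - 1):
                for j in range(i + 1, n):
                    candidates.append(([i, j], left[i] + sse(i, j) + sse(j, n)))
        best_breaks = min(candidates, key=lambda c: c[1])[0]

    # merge away breaks with a sub-tolerance level change
    while best_breaks:
        bounds = [0] + best_breaks + [n]
        diffs = [
            np.abs(seg_mean(bounds[k], bounds[k + 1]) - seg_mean(bounds[k + 1], bounds[k + 2])).max()
            for k in range(len(best_breaks))
        ]
        worst = int(np.argmin(diffs))
        if diffs[worst] >= min_jump:
            break
        best_breaks.pop(worst)
    return [float(grid[i]) for i in best_breaks]


def partial_dependence_discretize(
    model: ClassifierModel,
    data: pd.DataFrame,
    metric: str,
    default_rule: Optional[DiscretizationRule] = None,
    min_jump: float = 0.05,
    max_cuts: int = 2,
    grid: Optional[Sequence[float]] = None,
) -> DiscretizationRule:
    """Discretize a model metric from its partial-dependence curve.

    When ``default_rule`` is given (the published cut points), it is returned
    unchanged — the curve-based proposal exists to reproduce the development
    workflow on new data. Otherwise cut points are proposed at the largest
    curve jumps; a flat curve (all jumps below ``min_jump``) yields a
    single-category rule, i.e. no cut proposed.
    """
    if metric not in model.metric_names:
        raise ValueError(f"metric {metric!r} is not in the model")
    if default_rule is not None:
        return default_rule
    curve = partial_dependence(model, data, metric, grid=grid)
    cuts = propose_cuts(curve, min_jump=min_jump, max_cuts=max_cuts)
    if not cuts:
        return DiscretizationRule(metric, cuts=(), labels=("all",))
    labels = tuple(f"cat{i}" for i in range(len(cuts) + 1))
    return DiscretizationRule(metric, cuts=tuple(cuts), labels=labels)


def apply_single_indicators(
    base: PredictedClass, fish_present: bool, algal_cover_ge10: bool
) -> PredictedClass:
    """Upgrade Ephemeral / Need-more-information to At-least-intermittent.

    A single indicator (live fish, or algal cover of at least 10%) by itself
    demonstrates the reach is not ephemeral; it never changes Intermittent,
    Perennial, or At-least-intermittent outcomes.
    """
    if (fish_present or algal_cover_ge10) and base in (
        PredictedClass.EPHEMERAL,
        PredictedClass.NEED_MORE_INFORMATION,
    ):
        return PredictedClass.AT_LEAST_INTERMITTENT
    return base


def evaluate_single_indicator(
    flags: Sequence[bool],
    base_predictions: Sequence[PredictedClass],
    truth: Sequence[StreamflowClass],
) -> tuple:
    """Count misclassifications a candidate single indicator would fix or cause.

    A reach is overridden when the flag is present and the base outcome is
    Ephemeral or Need-more-information. Overrides of truly intermittent or
    perennial reaches are corrections; overrides of truly ephemeral reaches
    introduce misclassifications. Returns (n_corrected, n_introduced).
    """
    if not (len(flags) == len(base_predictions) == len(truth)):
        raise ValueError("flags, base_predictions and truth must be aligned")
    corrected = introduced = 0
    for f, b, t in zip(flags, base_predictions, truth):
        if not f or b not in (
            PredictedClass.EPHEMERAL,
            PredictedClass.NEED_MORE_INFORMATION,
        ):
            continue
        if StreamflowClass(t) is StreamflowClass.EPHEMERAL:
            introduced += 1
        else:
            corrected += 1
    return corrected, introduced


def beta_admissible(combo: Mapping[str, str]) -> bool:
    """Admissibility of an indicator combination under the field-form constraints.

    EPT taxa cannot be present without invertebrate evidence, and the
    algal-cover single indicator (>=10% cover) cannot fire when algae are
    absent. Applies only to the columns present in ``combo``.
    """
    if combo.get("ept") == "Present" and combo.get("invertebrates") == "None":
        return False
    if combo.get("algal_cover_ge10") in (True, "Present") and combo.get("algae") == "Absent":
        return False
    return True


class CrosswalkTable:
    """Exhaustive mapping from categorical indicator combinations to outcomes.

    ``table`` has one row per admissible combination of indicator levels plus
    the single-indicator flags, and a ``classification`` column. Lookup is
    total over admissible inputs and deterministic.
    """

    def __init__(self, table: pd.DataFrame, indicator_columns: Sequence[str]):
        self.indicator_columns = list(indicator_columns)
        key_cols = self.indicator_columns + ["fish_present", "algal_cover_ge10"]
        if table[key_cols].duplicated().any():
            raise ValueError("crosswalk combinations must be unique")
        self.table = table.reset_index(drop=True)
        self._lookup = {
            tuple(row[c] for c in key_cols): PredictedClass(row["classification"])
            for _, row in self.table.iterrows()
        }
        self._key_cols = key_cols

    def __len__(self) -> int:
        return len(self.table)

    def lookup(self, combo: Mapping) -> PredictedClass:
        key = tuple(combo[c] for c in self._key_cols)
        try:
            return self._lookup[key]
        except KeyError:
            raise KeyError(f"inadmissible or unknown indicator combination: {dict(combo)}")


def build_crosswalk_table(
    model: ClassifierModel,
    levels: Mapping[str, Sequence[str]],
    tau: float = DEFAULT_TAU,
    admissible: Callable[[Mapping[str, str]], bool] = beta_admissible,
) -> CrosswalkTable:
    """Enumerate every admissible indicator combination through the model.

    ``levels`` maps each model input (all categorical) to its ordered level
    labels; the model consumes ordinal codes in that order. Each combination,
    crossed with the two single-indicator flags, is classified by model votes
    + vote threshold + single-indicator override. Collapsing of don't-care
    rows for display is cosmetic and not done here.
    """
    names = list(model.metric_names)
    missing = [n for n in names if n not in levels]
    if missing:
        raise ValueError(f"no declared levels for model inputs: {missing}")
    combos = [
        dict(zip(names, values))
        for values in itertools.product(*(levels[n] for n in names))
    ]
    code = {n: {lab: i for i, lab in enumerate(levels[n])} for n in names}
    rows = []
    X = pd.DataFrame(
        [[code[n][c[n]] for n in names] for c in combos], columns=names, dtype=float
    )
    votes = model.predict_votes(X)
    for combo, v in zip(combos, votes):
        base = vote_threshold_classify(v, tau=tau)
        for fish, algal in itertools.product([False, True], repeat=2):
            full = dict(combo, fish_present=fish, algal_cover_ge10=algal)
            if not admissible(full):
                continue
            outcome = apply_single_indicators(base, fish, algal)
            rows.append(
                {**full, "v_E": v[0], "v_I": v[1], "v_P": v[2],
                 "classification": outcome.value}
            )
    return CrosswalkTable(pd.DataFrame(rows), indicator_columns=names)
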