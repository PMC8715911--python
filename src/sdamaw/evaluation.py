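"""Accuracy, repeatability, confusion and method-agreement reporting.

Seven accuracy measures summarize a set of classifications against the known
flow-duration classes:

========  ==========================================================
PvIvE     3-way accuracy (perennial vs intermittent vs ephemeral)
EvALI     ephemeral vs at-least-intermittent (binary)
PvIwet    perennial vs intermittent, restricted to flowing reaches
EvIdry    ephemeral vs intermittent, restricted to dry reaches
EnotP     ephemeral reaches correctly not classified perennial
PnotE     perennial reaches correctly not classified ephemeral
PvNP      perennial vs non-perennial (binary)
========  ==========================================================

Because the method can return hedged outcomes, every measure is computed
under an explicit scoring convention stating how At-least-intermittent (ALI)
and Need-more-information (NMI) outcomes are credited. Repeatability is the
share of revisited reaches receiving the identical label on both visits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core_data import PredictedClass, StreamflowClass

__all__ = [
    "ScoringConvention",
    "DEFAULT_CONVENTION",
    "PerformanceReport",
    "accuracy_measures",
    "repeatability",
    "confusion_table",
    "agreement_table",
]

MEASURES = ("PvIvE", "EvALI", "PvIwet", "EvIdry", "EnotP", "PnotE", "PvNP")


@dataclass(frozen=True)
class ScoringConvention:
    """How hedged outcomes are credited, per measure.

    ``ali_credit`` maps measure name to one of ``correct_for_I_and_P``
    (ALI counts correct whenever the true class is intermittent or
    perennial), ``incorrect``, or ``excluded`` (row dropped from the
    denominator). ``nmi_credit`` maps measure name to ``incorrect`` or
    ``excluded``. EnotP and PnotE are literal ("not classified as
    perennial/ephemeral") and ignore both settings.
    """

    ali_credit: Mapping[str, str] = field(
        default_factory=lambda: {
            "PvIvE": "incorrect",
            "EvALI": "correct_for_I_and_P",
            "PvIwet": "incorrect",
            "EvIdry": "correct_for_I_and_P",
            "EnotP": "correct_for_I_and_P",
            "PnotE": "correct_for_I_and_P",
            "PvNP": "correct_for_I_and_P",
        }
    )
    nmi_credit: Mapping[str, str] = field(
        default_factory=lambda: {m: "incorrect" for m in MEASURES}
    )

    def with_nmi(self, credit: str) -> "ScoringConvention":
        return replace(self, nmi_credit={m: credit for m in MEASURES})

    def describe(self) -> dict:
        return {"ali_credit": dict(self.ali_credit), "nmi_credit": dict(self.nmi_credit)}


DEFAULT_CONVENTION = ScoringConvention()


@dataclass
class PerformanceReport:
    """The seven accuracy measures (and optionally repeatability), with n."""

    measures: dict  # name -> (value | nan, n)
    convention: ScoringConvention
    repeatability: Optional[float] = None
    repeatability_n: int = 0

    def value(self, name: str) -> float:
        return self.measures[name][0]

    def n(self, name: str) -> int:
        return self.measures[name][1]

    def to_dict(self) -> dict:
        out = {name: {"value": v, "n": n} for name, (v, n) in self.measures.items()}
        if self.repeatability is not None or self.repeatability_n == 0:
            out["repeatability"] = {
                "value": self.repeatability,
                "n": self.repeatability_n,
            }
        out["convention"] = self.convention.describe()
        return out


def _score_rows(
    pred: Sequence[PredictedClass],
    truth: Sequence[StreamflowClass],
    measure: str,
    convention: ScoringConvention,
):
    """Per-row correctness for one measure; None marks an excluded row."""
    ali_rule = convention.ali_credit[measure]
    nmi_rule = convention.nmi_credit[measure]
    out = []
    for p, t in zip(pred, truth):
        p = PredictedClass(p)
        t = StreamflowClass(t)
        # literal measures: the only error is the named wrong call; hedged
        # outcomes are "not classified as P/E" and therefore correct
        if measure == "EnotP":
            out.append(p is not PredictedClass.PERENNIAL)
            continue
        if measure == "PnotE":
            out.append(p is not PredictedClass.EPHEMERAL)
            continue
        if p is PredictedClass.NEED_MORE_INFORMATION:
            out.append(None if nmi_rule == "excluded" else False)
            continue
        if p is PredictedClass.AT_LEAST_INTERMITTENT:
            if ali_rule == "excluded":
                out.append(None)
            elif ali_rule == "correct_for_I_and_P":
                out.append(t is not StreamflowClass.EPHEMERAL)
            else:
                out.append(False)
            continue
        # specific-class predictions
        if measure in ("PvIvE", "PvIwet", "EvIdry"):
            out.append(p.value == t.value)
        elif measure == "EvALI":
            out.append(
                (p is PredictedClass.EPHEMERAL) == (t is StreamflowClass.EPHEMERAL)
            )
        elif measure == "PvNP":
            out.append(
                (p is PredictedClass.PERENNIAL) == (t is StreamflowClass.PERENNIAL)
            )
        else:
            raise ValueError(f"unknown measure {measure!r}")
    return out


def accuracy_measures(
    predicted: Sequence[PredictedClass],
    truth: Sequence[StreamflowClass],
    flow_state: Sequence[str],
    convention: ScoringConvention = DEFAULT_CONVENTION,
) -> PerformanceReport:
    """Compute the seven accuracy measures under an explicit convention.

    ``flow_state`` ("dry"/"flowing") is required for the restricted measures:
    PvIwet scores truly-perennial plus flowing-intermittent rows; EvIdry
    scores dry rows of true class ephemeral or intermittent. EnotP/PnotE are
    scored only on ephemeral/perennial rows respectively. An empty
    restriction set reports NaN with n = 0.
    """
    pred = [PredictedClass(p) for p in predicted]
    tru = [StreamflowClass(t) for t in truth]
    flow = list(flow_state)
    if not (len(pred) == len(tru) == len(flow)):
        raise ValueError("predicted, truth and flow_state must be aligned")
    for f in flow:
        if f not in ("dry", "flowing"):
            raise ValueError(f"flow_state entries must be 'dry'/'flowing', got {f!r}")

    def restrict(measure):
        idx = []
        for k, (t, f) in enumerate(zip(tru, flow)):
            if measure == "PvIwet":
                if t is StreamflowClass.PERENNIAL or (
                    t is StreamflowClass.INTERMITTENT and f == "flowing"
                ):
                    idx.append(k)
            elif measure == "EvIdry":
                if f == "dry" and t in (
                    StreamflowClass.EPHEMERAL,
                    StreamflowClass.INTERMITTENT,
                ):
                    idx.append(k)
            elif measure == "EnotP":
                if t is StreamflowClass.EPHEMERAL:
                    idx.append(k)
            elif measure == "PnotE":
                if t is StreamflowClass.PERENNIAL:
                    idx.append(k)
            else:
                idx.append(k)
        return idx

    measures = {}
    for m in MEASURES:
        idx = restrict(m)
        scores = _score_rows([pred[k] for k in idx], [tru[k] for k in idx], m, convention)
        kept = [s for s in scores if s is not None]
        if not kept:
            measures[m] = (float("nan"), 0)
        else:
            measures[m] = (float(np.mean(kept)), len(kept))
    return PerformanceReport(measures=measures, convention=convention)


def repeatability(classifications_by_visit: Mapping[str, Sequence[PredictedClass]]):
    """Share of revisited reaches with identical labels on visits 1 and 2.

    ``classifications_by_visit`` maps reach_id to its per-visit predicted
    labels in visit order; reaches with fewer than two visits are ignored.
    Label equality is exact — ALI vs Intermittent counts as a mismatch.
    Returns (proportion | nan, n_revisited).
    """
    matches = []
    for rid, labels in classifications_by_visit.items():
        labels = [PredictedClass(v) for v in labels]
        if len(labels) < 2:
            continue
        matches.append(labels[0] == labels[1])
    if not matches:
        return float("nan"), 0
    return float(np.mean(matches)), len(matches)


def confusion_table(
    predicted: Sequence[PredictedClass],
    truth: Sequence[StreamflowClass],
    flow_state: Sequence[str],
) -> pd.DataFrame:
    """Cross-tabulation: 5 predicted-class rows x (true class, observed flow) columns."""
    pred = pd.Categorical(
        [PredictedClass(p).value for p in predicted],
        categories=[c.value for c in PredictedClass],
    )
    cols = pd.MultiIndex.from_arrays(
        [[StreamflowClass(t).value for t in truth], list(flow_state)],
        names=["true_class", "flow_state"],
    )
    table = pd.crosstab(pred, [cols.get_level_values(0), cols.get_level_values(1)],
                        dropna=False)
    table.index.name = "classification"
    return table


def agreement_table(pred_a: Sequence, pred_b: Sequence, name_a="method_a", name_b="method_b"):
    """Generic method-vs-method agreement cross-tabulation."""
    a = [getattr(v, "value", v) for v in pred_a]
    b = [getattr(v, "value", v) for v in pred_b]
    table = pd.crosstab(pd.Series(a, name=name_a), pd.Series(b, name=name_b))
    return table
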