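"""The beta field method: a verbatim, hard-coded classification table.

A single field visit records five indicator categories — hydrophytic plant
species (None / Few 1-2 / Many 3+), aquatic invertebrate abundance (None /
Few 1-19 / Many 20+), EPT taxa (absent/present), algae (absent/present) and
the single indicators (live fish; algal cover >=10%) — and the published
classification table maps every admissible combination to one of five
outcomes. The table ships as versioned CSV data inside the package, not
code, so corrections against the typeset publication are diff-reviewable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Optional, Union

import numpy as np
import pandas as pd

from .core_data import PredictedClass
from .refinement import HYDROPHYTE_RULE, INVERTEBRATE_RULE

__all__ = [
    "BetaInputs",
    "classify_beta",
    "beta_table",
    "enumerate_admissible_inputs",
    "HYDROPHYTE_LEVELS",
    "INVERTEBRATE_LEVELS",
    "ALGAL_COVER_LEVELS",
    "DISPLAY_LABELS",
    "TableVoteModel",
]

HYDROPHYTE_LEVELS = ("None", "Few_1_2", "Many_3plus")
INVERTEBRATE_LEVELS = ("None", "Few_1_19", "Many_20plus")
BINARY_LEVELS = ("Absent", "Present")
#: Field-form algal cover: not detected, below 10%, or at least 10% cover.
ALGAL_COVER_LEVELS = ("ND", "lt10", "ge10")

#: ASCII tokens used in data files -> display labels used on the field form.
DISPLAY_LABELS = {
    "None": "None",
    "Few_1_2": "Few (1-2)",
    "Many_3plus": "Many (3+)",
    "Few_1_19": "Few (1-19)",
    "Many_20plus": "Many (20+)",
    "Absent": "Absent",
    "Present": "Present",
    "ND": "Not detected",
    "lt10": "<10%",
    "ge10": ">=10%",
}


@dataclass(frozen=True)
class BetaInputs:
    """One visit's categorical indicator readings for the beta method."""

    hydrophytes: str
    invertebrates: str
    ept: str
    algae: str
    algal_cover: str = "ND"
    fish_present: bool = False

    def __post_init__(self) -> None:
        problems = []
        if self.hydrophytes not in HYDROPHYTE_LEVELS:
            problems.append(f"hydrophytes={self.hydrophytes!r} not in {HYDROPHYTE_LEVELS}")
        if self.invertebrates not in INVERTEBRATE_LEVELS:
            problems.append(
                f"invertebrates={self.invertebrates!r} not in {INVERTEBRATE_LEVELS}"
            )
        for name in ("ept", "algae"):
            if getattr(self, name) not in BINARY_LEVELS:
                problems.append(f"{name}={getattr(self, name)!r} not in {BINARY_LEVELS}")
        if self.algal_cover not in ALGAL_COVER_LEVELS:
            problems.append(f"algal_cover={self.algal_cover!r} not in {ALGAL_COVER_LEVELS}")
        if problems:
            raise ValueError("; ".join(problems))
        # cross-field invariants
        if self.invertebrates == "None" and self.ept == "Present":
            problems.append("ept=Present requires invertebrates != None")
        if self.algal_cover == "ge10" and self.algae != "Present":
            problems.append("algal_cover=ge10 requires algae=Present")
        if self.algae == "Absent" and self.algal_cover != "ND":
            problems.append("algae=Absent requires algal_cover=ND")
        if problems:
            raise ValueError("inconsistent indicator fields: " + "; ".join(problems))

    @property
    def single_indicator(self) -> bool:
        return self.fish_present or self.algal_cover == "ge10"

    @classmethod
    def from_counts(
        cls,
        hydrophyte_count: int,
        invertebrate_abundance: int,
        ept_present: bool,
        algal_cover: str,
        fish_present: bool = False,
    ) -> "BetaInputs":
        """Build inputs from raw counts/covers, applying the published cut points."""
        if algal_cover not in ALGAL_COVER_LEVELS:
            raise ValueError(f"algal_cover={algal_cover!r} not in {ALGAL_COVER_LEVELS}")
        return cls(
            hydrophytes=str(HYDROPHYTE_RULE.apply(hydrophyte_count)),
            invertebrates=str(INVERTEBRATE_RULE.apply(invertebrate_abundance)),
            ept="Present" if ept_present else "Absent",
            algae="Absent" if algal_cover == "ND" else "Present",
            algal_cover=algal_cover,
            fish_present=bool(fish_present),
        )


@lru_cache(maxsize=1)
def beta_table() -> pd.DataFrame:
    """The packaged classification table (one row per admissible combination)."""
    with resources.files("sdamaw").joinpath("data/beta_classification_table.csv").open() as f:
        table = pd.read_csv(f, dtype=str, keep_default_na=False)
    return table


@lru_cache(maxsize=1)
def _beta_lookup() -> dict:
    table = beta_table()
    return {
        (r.hydrophytes, r.invertebrates, r.ept, r.algae, r.single_indicator): PredictedClass(
            r.classification
        )
        for r in table.itertuples()
    }


def classify_beta(inputs: BetaInputs) -> PredictedClass:
    """Classify one visit with the beta method table."""
    key = (
        inputs.hydrophytes,
        inputs.invertebrates,
        inputs.ept,
        inputs.algae,
        "Present" if inputs.single_indicator else "Absent",
    )
    return _beta_lookup()[key]


def enumerate_admissible_inputs() -> list:
    """All admissible BetaInputs combinations (raw 3x3x2x2x2 space minus
    the combinations violating the cross-field invariants)."""
    out = []
    for h, i, e, a, single in itertools.product(
        HYDROPHYTE_LEVELS, INVERTEBRATE_LEVELS, BINARY_LEVELS, BINARY_LEVELS, (False, True)
    ):
        if i == "None" and e == "Present":
            continue
        if single:
            # realize the single indicator as fish presence, valid for any
            # algae state; algal-cover>=10% is the other (equivalent) route
            inputs = BetaInputs(h, i, e, a, algal_cover="ND" if a == "Absent" else "lt10",
                                fish_present=True)
        else:
            inputs = BetaInputs(h, i, e, a, algal_cover="ND" if a == "Absent" else "lt10",
                                fish_present=False)
        out.append(inputs)
    return out


class TableVoteModel:
    """A vote model constrained to reproduce the packaged table's outcomes.

    Emits, for each categorical combination, a vote vector whose
    vote-threshold outcome at tau = 0.6 equals the table row (specific
    classes as unanimous votes; At-least-intermittent as a 50/50 I-P split;
    Need-more-information as a sub-threshold 50/25/25 split). Used as the
    oracle for crosswalk/table equivalence.
    """

    TAU = 0.6
    metric_names = ("hydrophytes", "invertebrates", "ept", "algae")
    levels = {
        "hydrophytes": HYDROPHYTE_LEVELS,
        "invertebrates": INVERTEBRATE_LEVELS,
        "ept": BINARY_LEVELS,
        "algae": BINARY_LEVELS,
    }
    _VOTES = {
        PredictedClass.EPHEMERAL: (1.0, 0.0, 0.0),
        PredictedClass.INTERMITTENT: (0.0, 1.0, 0.0),
        PredictedClass.PERENNIAL: (0.0, 0.0, 1.0),
        PredictedClass.AT_LEAST_INTERMITTENT: (0.0, 0.5, 0.5),
        PredictedClass.NEED_MORE_INFORMATION: (0.5, 0.25, 0.25),
    }

    def predict_votes(self, X: Union[pd.DataFrame, np.ndarray]) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[list(self.metric_names)].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float).astype(int)
        lookup = _beta_lookup()
        votes = np.zeros((X.shape[0], 3))
        for row_idx, codes in enumerate(X):
            decoded = [
                self.levels[name][code] for name, code in zip(self.metric_names, codes)
            ]
            h, i, e, a = decoded
            if i == "None" and e == "Present":
                # inadmissible under the field-form constraints; emit an
                # abstention vote so downstream filtering can discard the row
                base = PredictedClass.NEED_MORE_INFORMATION
            else:
                base = lookup[(h, i, e, a, "Absent")]
            votes[row_idx] = self._VOTES[base]
        return votes
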