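"""Partial-dependence discretization, crosswalk generation, single indicators."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdamaw.beta_method import TableVoteModel, classify_beta, enumerate_admissible_inputs
from sdamaw.classifiers import fit_classifier
from sdamaw.core_data import PredictedClass, StreamflowClass
from sdamaw.refinement import (
    HYDROPHYTE_RULE,
    INVERTEBRATE_RULE,
    DiscretizationRule,
    apply_single_indicators,
    build_crosswalk_table,
    evaluate_single_indicator,
    partial_dependence,
    partial_dependence_discretize,
    propose_cuts,
)

E, I, P = StreamflowClass.EPHEMERAL, StreamflowClass.INTERMITTENT, StreamflowClass.PERENNIAL
ALI = PredictedClass.AT_LEAST_INTERMITTENT
NMI = PredictedClass.NEED_MORE_INFORMATION


class TestDiscretizationRule:
    @pytest.mark.parametrize(
        "value, label",
        [(0, "None"), (1, "Few_1_2"), (2, "Few_1_2"), (3, "Many_3plus"), (9, "Many_3plus")],
    )
    def test_hydrophyte_cut_points(self, value, label):
        assert HYDROPHYTE_RULE.apply(value) == label

    @pytest.mark.parametrize(
        "value, label",
        [(0, "None"), (1, "Few_1_19"), (19, "Few_1_19"), (20, "Many_20plus")],
    )
    def test_invertebrate_cut_points(self, value, label):
        assert INVERTEBRATE_RULE.apply(value) == label

    def test_cuts_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            DiscretizationRule("m", cuts=(3.0, 1.0), labels=("a", "b", "c"))


class TestPartialDependence:
    def _tree_model(self, rng, split_at=10.0):
        x = np.concatenate([rng.uniform(0, split_at - 0.5, 60),
                            rng.uniform(split_at + 0.5, 2 * split_at, 60)])
        truth = [E] * 60 + [P] * 60
        data = pd.DataFrame({"x": x})
        return fit_classifier(data, truth, kind="single_tree", seed=0), data

    def test_single_tree_split_recovered(self, rng):
        model, data = self._tree_model(rng)
        curve = partial_dependence(model, data, "x", grid=np.linspace(0, 20, 81))
        cuts = propose_cuts(curve, min_jump=0.05, max_cuts=2)
        assert len(cuts) == 1
        assert abs(cuts[0] - 10.0) <= 0.5  # within grid resolution of the split

    def test_ignored_feature_gives_flat_curve(self, rng):
        model, data = self._tree_model(rng)
        data = data.assign(irrelevant=rng.normal(size=len(data)))
        model2 = fit_classifier(
            data, [E] * 60 + [P] * 60, kind="single_tree", seed=0
        )
        rule = partial_dependence_discretize(model2, data, "irrelevant")
        assert rule.cuts == ()  # no jump above tolerance, no cut proposed

    def test_default_rule_shipped_verbatim(self, rng):
        model, data = self._tree_model(rng)
        rule = partial_dependence_discretize(
            model, data, "x", default_rule=HYDROPHYTE_RULE
        )
        assert rule is HYDROPHYTE_RULE

    def test_absent_metric_rejected(self, rng):
        model, data = self._tree_model(rng)
        with pytest.raises(ValueError, match="not in the model"):
            partial_dependence(model, data.assign(y=1.0), "y")


class TestSingleIndicators:
    @pytest.mark.parametrize(
        "base, fish, algal, expected",
        [
            (PredictedClass.EPHEMERAL, True, False, ALI),
            (NMI, False, True, ALI),
            (PredictedClass.PERENNIAL, True, True, PredictedClass.PERENNIAL),
            (PredictedClass.INTERMITTENT, False, False, PredictedClass.INTERMITTENT),
            (ALI, True, False, ALI),
        ],
    )
    def test_override_rule(self, base, fish, algal, expected):
        assert apply_single_indicators(base, fish, algal) is expected

    @given(
        base=st.sampled_from(list(PredictedClass)),
        fish=st.booleans(),
        algal=st.booleans(),
    )
    @settings(max_examples=100, deadline=None)
    def test_never_produces_ephemeral_or_downgrades(self, base, fish, algal):
        out = apply_single_indicators(base, fish, algal)
        if fish or algal:
            assert out is not PredictedClass.EPHEMERAL and out is not NMI
        if base in (PredictedClass.INTERMITTENT, PredictedClass.PERENNIAL, ALI):
            assert out is base

    def test_evaluate_counts_corrections_and_introductions(self):
        flags = [True, True, True, True, False]
        base = [PredictedClass.EPHEMERAL, PredictedClass.EPHEMERAL, NMI,
                PredictedClass.PERENNIAL, PredictedClass.EPHEMERAL]
        truth = [I, I, P, E, I]
        corrected, introduced = evaluate_single_indicator(flags, base, truth)
        assert (corrected, introduced) == (3, 0)

    def test_evaluate_introduced_misclassification(self):
        corrected, introduced = evaluate_single_indicator(
            [True], [PredictedClass.EPHEMERAL], [E]
        )
        assert (corrected, introduced) == (0, 1)

    def test_indicator_never_present(self):
        assert evaluate_single_indicator(
            [False, False], [PredictedClass.EPHEMERAL, NMI], [I, P]
        ) == (0, 0)


class TestCrosswalk:
    def _beta_crosswalk(self):
        model = TableVoteModel()
        return build_crosswalk_table(model, model.levels, tau=TableVoteModel.TAU)

    def test_enumeration_is_exhaustive_and_unique(self):
        cw = self._beta_crosswalk()
        # 3*3*2*2 = 36 categorical combos minus 6 with EPT present but no
        # invertebrates = 30; crossed with the (fish, algal cover) flags and
        # reduced by the algae/cover constraint: 15*2 + 15*4 = 90 rows
        assert len(cw) == 90
        key_cols = cw.indicator_columns + ["fish_present", "algal_cover_ge10"]
        assert not cw.table[key_cols].duplicated().any()

    def test_lookup_equals_model_pipeline_for_every_combination(self):
        cw = self._beta_crosswalk()
        for inputs in enumerate_admissible_inputs():
            combo = {
                "hydrophytes": inputs.hydrophytes,
                "invertebrates": inputs.invertebrates,
                "ept": inputs.ept,
                "algae": inputs.algae,
                "fish_present": inputs.fish_present,
                "algal_cover_ge10": inputs.algal_cover == "ge10",
            }
            assert cw.lookup(combo) is classify_beta(inputs)

    def test_single_indicator_rows_never_ephemeral_or_abstain(self):
        cw = self._beta_crosswalk()
        flagged = cw.table[cw.table["fish_present"] | cw.table["algal_cover_ge10"]]
        assert not flagged["classification"].isin(
            [PredictedClass.EPHEMERAL.value, NMI.value]
        ).any()

    def test_inadmissible_lookup_rejected(self):
        cw = self._beta_crosswalk()
        with pytest.raises(KeyError):
            cw.lookup(
                {
                    "hydrophytes": "None",
                    "invertebrates": "None",
                    "ept": "Present",  # EPT with no invertebrate evidence
                    "algae": "Absent",
                    "fish_present": False,
                    "algal_cover_ge10": False,
                }
            )
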