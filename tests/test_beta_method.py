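"""The packaged classification table against an independent transcription.

The expected outcomes below were transcribed directly from the typeset
classification table, resolving the blank-cell carry-over: a leading blank
repeats the value above, a trailing blank means the indicator does not
change the outcome ("don't care"). Don't-care rows are expanded here so
every admissible combination is asserted explicitly.
"""

import itertools

import pytest

from sdamaw.beta_method import (
    ALGAL_COVER_LEVELS,
    BetaInputs,
    beta_table,
    classify_beta,
    enumerate_admissible_inputs,
)
from sdamaw.core_data import PredictedClass

E = "Ephemeral"
I = "Intermittent"
P = "Perennial"
ALI = "At least intermittent"
NMI = "Need more information"

ANY = None  # don't-care (blank cell in the printed table)

# (hydrophytes, invertebrates, ept, algae, single) -> outcome, one tuple per
# printed row; None matches any level of that indicator.
PRINTED_ROWS = [
    ("None", "None", "Absent", "Absent", "Absent", E),
    ("None", "None", "Absent", "Absent", "Present", ALI),
    ("None", "None", "Absent", "Present", "Absent", NMI),
    ("None", "None", "Absent", "Present", "Present", ALI),
    ("None", "Few_1_19", "Absent", "Absent", "Absent", NMI),
    ("None", "Few_1_19", "Absent", "Absent", "Present", ALI),
    ("None", "Few_1_19", "Absent", "Present", "Absent", NMI),
    ("None", "Few_1_19", "Absent", "Present", "Present", ALI),
    ("None", "Few_1_19", "Present", ANY, ANY, ALI),
    ("None", "Many_20plus", "Absent", "Absent", "Absent", NMI),
    ("None", "Many_20plus", "Absent", "Absent", "Present", ALI),
    ("None", "Many_20plus", "Absent", "Present", "Absent", NMI),
    ("None", "Many_20plus", "Absent", "Present", "Present", ALI),
    ("None", "Many_20plus", "Present", ANY, ANY, ALI),
    ("Few_1_2", "None", "Absent", "Absent", "Absent", NMI),
    ("Few_1_2", "None", "Absent", "Absent", "Present", ALI),
    ("Few_1_2", "None", "Absent", "Present", ANY, ALI),
    ("Few_1_2", "Few_1_19", "Absent", "Absent", ANY, I),
    ("Few_1_2", "Few_1_19", "Absent", "Present", ANY, ALI),
    ("Few_1_2", "Few_1_19", "Present", ANY, ANY, ALI),
    ("Few_1_2", "Many_20plus", "Absent", "Absent", ANY, I),
    ("Few_1_2", "Many_20plus", "Absent", "Present", ANY, ALI),
    ("Few_1_2", "Many_20plus", "Present", "Absent", ANY, ALI),
    ("Few_1_2", "Many_20plus", "Present", "Present", ANY, I),
    ("Many_3plus", "None", "Absent", "Absent", "Absent", NMI),
    ("Many_3plus", "None", "Absent", "Absent", "Present", ALI),
    ("Many_3plus", "None", "Absent", "Present", ANY, ALI),
    ("Many_3plus", "Few_1_19", "Absent", ANY, ANY, ALI),
    ("Many_3plus", "Few_1_19", "Present", ANY, ANY, P),
    ("Many_3plus", "Many_20plus", "Absent", ANY, ANY, ALI),
    ("Many_3plus", "Many_20plus", "Present", ANY, ANY, P),
]


def expand_printed_rows():
    """Expand don't-care cells into explicit admissible combinations."""
    levels = {
        0: ("None", "Few_1_2", "Many_3plus"),
        1: ("None", "Few_1_19", "Many_20plus"),
        2: ("Absent", "Present"),
        3: ("Absent", "Present"),
        4: ("Absent", "Present"),
    }
    expanded = {}
    for row in PRINTED_ROWS:
        *cells, outcome = row
        options = [levels[k] if c is ANY else (c,) for k, c in enumerate(cells)]
        for combo in itertools.product(*options):
            if combo[1] == "None" and combo[2] == "Present":
                continue  # inadmissible: EPT without invertebrates
            assert combo not in expanded or expanded[combo] == outcome, (
                f"overlapping printed rows disagree at {combo}"
            )
            expanded[combo] = outcome
    return expanded


class TestBetaTableSnapshot:
    def test_expansion_covers_all_sixty_admissible_combinations(self):
        assert len(expand_printed_rows()) == 60

    def test_packaged_table_matches_printed_rows_exactly(self):
        expected = expand_printed_rows()
        table = beta_table()
        assert len(table) == 60
        for r in table.itertuples():
            combo = (r.hydrophytes, r.invertebrates, r.ept, r.algae, r.single_indicator)
            assert r.classification == expected[combo], f"mismatch at {combo}"

    def test_classify_beta_agrees_for_every_admissible_input(self):
        expected = expand_printed_rows()
        for inputs in enumerate_admissible_inputs():
            combo = (
                inputs.hydrophytes,
                inputs.invertebrates,
                inputs.ept,
                inputs.algae,
                "Present" if inputs.single_indicator else "Absent",
            )
            assert classify_beta(inputs).value == expected[combo]


class TestBetaInputs:
    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            (dict(hydrophytes="None", invertebrates="None", ept="Absent",
                  algae="Absent"), "Ephemeral"),
            (dict(hydrophytes="Many_3plus", invertebrates="Many_20plus",
                  ept="Present", algae="Present", algal_cover="lt10"), "Perennial"),
            (dict(hydrophytes="Few_1_2", invertebrates="Few_1_19", ept="Absent",
                  algae="Absent"), "Intermittent"),
            (dict(hydrophytes="None", invertebrates="None", ept="Absent",
                  algae="Absent", fish_present=True), "At least intermittent"),
            (dict(hydrophytes="None", invertebrates="None", ept="Absent",
                  algae="Present", algal_cover="lt10"), "Need more information"),
        ],
    )
    def test_published_examples(self, kwargs, expected):
        assert classify_beta(BetaInputs(**kwargs)).value == expected

    def test_invariant_violations_name_fields(self):
        with pytest.raises(ValueError, match="ept"):
            BetaInputs("None", "None", "Present", "Absent")
        with pytest.raises(ValueError, match="algal_cover"):
            BetaInputs("None", "Few_1_19", "Absent", "Absent", algal_cover="ge10")

    def test_from_counts_applies_cut_points(self):
        b = BetaInputs.from_counts(2, 19, ept_present=False, algal_cover="ND")
        assert (b.hydrophytes, b.invertebrates) == ("Few_1_2", "Few_1_19")
        b = BetaInputs.from_counts(3, 20, ept_present=True, algal_cover="ge10")
        assert (b.hydrophytes, b.invertebrates) == ("Many_3plus", "Many_20plus")
        assert b.algae == "Present" and b.single_indicator

    def test_algal_cover_single_indicator_route(self):
        b = BetaInputs("None", "None", "Absent", "Present", algal_cover="ge10")
        assert b.single_indicator
        assert classify_beta(b) is PredictedClass.AT_LEAST_INTERMITTENT

    def test_monotonic_upgrades_never_reach_ephemeral(self):
        # only the all-absent, no-single-indicator row is Ephemeral: adding
        # hydrophytes or EPT evidence always moves away from it
        for inputs in enumerate_admissible_inputs():
            if classify_beta(inputs) is PredictedClass.EPHEMERAL:
                assert inputs.hydrophytes == "None"
                assert inputs.invertebrates == "None"
                assert inputs.ept == "Absent"
                assert inputs.algae == "Absent"
                assert not inputs.single_indicator

    def test_cover_levels_documented(self):
        assert ALGAL_COVER_LEVELS == ("ND", "lt10", "ge10")
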