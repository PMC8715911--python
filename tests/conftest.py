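import numpy as np
import pytest

from sdamaw.core_data import PredictedClass, StreamflowClass

# Printed confusion counts for the initial reach visits: predicted class rows
# against (true class, observed flow) columns. Used to reconstruct aligned
# prediction/truth/flow vectors for evaluation tests.
TABLE7_INITIAL = {
    # (true_class, flow_state): {predicted: count}
    ("Ephemeral", "dry"): {"Ephemeral": 24, "Intermittent": 0, "At least intermittent": 0,
                           "Perennial": 1, "Need more information": 3},
    ("Ephemeral", "flowing"): {"Ephemeral": 0, "Intermittent": 0, "At least intermittent": 0,
                               "Perennial": 0, "Need more information": 2},
    ("Intermittent", "dry"): {"Ephemeral": 7, "Intermittent": 2, "At least intermittent": 2,
                              "Perennial": 1, "Need more information": 2},
    ("Intermittent", "flowing"): {"Ephemeral": 1, "Intermittent": 7, "At least intermittent": 6,
                                  "Perennial": 4, "Need more information": 2},
    ("Perennial", "flowing"): {"Ephemeral": 0, "Intermittent": 4, "At least intermittent": 7,
                               "Perennial": 14, "Need more information": 0},
}


def table7_vectors():
    """Aligned (predicted, truth, flow_state) vectors from the printed counts."""
    preds, truths, flows = [], [], []
    for (t, f), row in TABLE7_INITIAL.items():
        for p, n in row.items():
            preds.extend([PredictedClass(p)] * n)
            truths.extend([StreamflowClass(t)] * n)
            flows.extend([f] * n)
    return preds, truths, flows


@pytest.fixture
def table7_fixture():
    return table7_vectors()


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
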