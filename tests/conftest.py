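import numpy as np
import pytest

from pointattn import presets
from pointattn.training import evaluate


@pytest.fixture(scope="session")
def toy_runs():
    """Three independently seeded trainings of the desk-scale classifier
    on the 4-class shape task (400 train / 100 test, N=256, k=20).

    Shared by the learning-margin and robustness checks so the expensive
    trainings happen once per session.
    """
    runs = []
    for seed in (0, 1, 2):
        model, train_set, test_set = presets.train_toy_classifier(seed=seed)
        report = evaluate(test_set, model)
        runs.append({"seed": seed, "model": model, "test_set": test_set,
                     "report": report})
    return runs
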