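import numpy as np
import pandas as pd
import pytest

import masslmm as m


@pytest.fixture(scope="session")
def design_trials():
    """Full reference design, two participants."""
    return m.generate_design(36, 2, seed=11)


@pytest.fixture(scope="session")
def augmented_trials(design_trials):
    return m.augment_trials(design_trials)


@pytest.fixture(scope="session")
def small_trials():
    """Minimal balanced within-participant factorial for engine tests."""
    rows = [
        {"participant_id": f"P{p:02d}", "condition": lv}
        for p in range(8)
        for lv in ("a", "b", "c")
        for _ in range(12)
    ]
    trials = pd.DataFrame(rows)
    rng = np.random.default_rng(5)
    trials["cov"] = rng.normal(size=len(trials))
    return trials


@pytest.fixture(scope="session")
def small_spec():
    return m.ModelSpec(fixed=("condition", "cov"), interest=("condition",))
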