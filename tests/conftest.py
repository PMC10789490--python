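import numpy as np
import pandas as pd
import pytest

from costbayes import ExperimentDesign, ModelSpec, simulate_subject


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_design():
    return ExperimentDesign(n_blocks=3, n_passive=40, n_active=60)


@pytest.fixture(scope="session")
def precision_subject():
    """One experiment-scale synthetic subject from the precision m=0 model."""
    return simulate_subject(ModelSpec.precision(0, 1.0, 2.0), seed=7)


def make_block_table(stimuli, responses, n_passive, p=0.7, subject_id="s1",
                     block_index=1):
    """Assemble a single-block trial table from raw arrays (responses align
    with the active trials; None entries become missing)."""
    stimuli = np.asarray(stimuli, dtype=int)
    n = stimuli.size
    resp = np.full(n, np.nan)
    for i, r in enumerate(responses):
        if r is not None:
            resp[n_passive + i] = float(r)
    return pd.DataFrame({
        "subject_id": subject_id,
        "block_index": block_index,
        "p": p,
        "trial_index": np.arange(1, n + 1),
        "phase": ["passive"] * n_passive + ["active"] * (n - n_passive),
        "stimulus": stimuli,
        "response": resp,
    })
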