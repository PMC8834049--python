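import numpy as np
import pytest

from sstr2dia import fixtures


@pytest.fixture(scope="session")
def ssa_frame():
    return fixtures.ssa_cohort_frame()


@pytest.fixture(scope="session")
def mucosa_frame():
    return fixtures.mucosa_cohort_frame()


@pytest.fixture(scope="session")
def ssa_scores(ssa_frame):
    """(dia, volante, irs, labels) arrays from the SSA-treated cohort."""
    labels = (ssa_frame["response_binary"] == "positive").astype(int).to_numpy()
    return (
        ssa_frame["dia_score"].to_numpy(float),
        ssa_frame["volante"].to_numpy(float),
        ssa_frame["irs"].to_numpy(float),
        labels,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20220202)
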