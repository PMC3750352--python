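import numpy as np
import pandas as pd
import pytest

from relhaz import SurvivalDataset, tiny_fixture


@pytest.fixture
def six_subject():
    """The deterministic 6-subject fixture with offsets."""
    return tiny_fixture()


@pytest.fixture
def six_subject_no_offset():
    d = tiny_fixture()
    return d.with_offset(np.zeros(d.n))


@pytest.fixture
def symmetric_ties():
    """Invariant under relabeling z <-> 1 - z, so the Cox coefficient is 0."""
    return SurvivalDataset(
        time=np.array([1.0, 1.0, 2.0, 2.0]),
        event=np.array([1, 1, 1, 1]),
        covariates=pd.DataFrame({"z": [1.0, 0.0, 1.0, 0.0]}),
    )


def make_dataset(time, event, X, offset=None, strata=None, group=None):
    X = np.asarray(X, dtype=float)
    cols = {f"x{j}": X[:, j] for j in range(X.shape[1])}
    return SurvivalDataset(
        time=np.asarray(time, dtype=float),
        event=np.asarray(event),
        covariates=pd.DataFrame(cols),
        offset=offset,
        strata=strata,
        group=group,
    )
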