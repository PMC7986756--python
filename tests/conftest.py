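import numpy as np
import pytest

from marginalize import ScenarioSpec, simulate
from marginalize.datasets import BinaryDataset, SurvivalDataset


@pytest.fixture(scope="session")
def tte_rct_data():
    """One replication of the randomized time-to-event scenario with both a
    treatment and a covariate effect (n=1000)."""
    return simulate(ScenarioSpec.from_label("tte", "(1,1)", n=1000, seed=11))


@pytest.fixture(scope="session")
def binary_obs_data():
    """One replication of the confounded binary-outcome scenario (n=1000)."""
    return simulate(ScenarioSpec.from_label("binary", "(1,1)*", n=1000, seed=11))


@pytest.fixture
def toy_survival():
    """Six records, no ties: small enough to enumerate risk sets by hand."""
    return SurvivalDataset(
        time=np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0]),
        event=np.array([1, 1, 0, 1, 1, 0]),
        exposure=np.array([1, 0, 1, 0, 1, 0]),
        covariates=np.zeros((6, 0)),
    )


def two_by_two(a: int, b: int, c: int, d: int) -> BinaryDataset:
    """Binary dataset with cell counts a=(X=1,Y=1), b=(X=1,Y=0),
    c=(X=0,Y=1), d=(X=0,Y=0)."""
    y = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
    x = np.concatenate([np.ones(a + b), np.zeros(c + d)])
    return BinaryDataset(y.astype(int), x.astype(int), np.zeros((a + b + c + d, 1)))
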