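import numpy as np
import pytest

from mesens import MeasurementErrorCoxAdjuster, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def cohort():
    """A moderate synthetic cohort under the default generating design."""
    return simulate_cohort(SimulationConfig(n=1200), seed=42)


@pytest.fixture(scope="session")
def xy(cohort):
    return cohort[["q1", "q2"]].to_numpy(), cohort[["time", "event"]].to_numpy()


@pytest.fixture(scope="session")
def fitted(xy):
    """Default-prior adjuster fitted once at reduced chain lengths."""
    X, y = xy
    est = MeasurementErrorCoxAdjuster(n_samples=3000, burn_in=800, tuning=800,
                                      random_state=7)
    return est.fit(X, y)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
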