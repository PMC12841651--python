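import pandas as pd
import pytest

from dropscore.simulate import CohortSimulator


@pytest.fixture(scope="session")
def simulator() -> CohortSimulator:
    return CohortSimulator()


@pytest.fixture(scope="session")
def default_cohort(simulator) -> pd.DataFrame:
    """The default seeded synthetic cohort (n=500, seed=42)."""
    return simulator.sample(n=500, seed=42)


@pytest.fixture(scope="session")
def large_cohort(simulator) -> pd.DataFrame:
    """A larger seeded cohort for discrimination / calibration checks."""
    return simulator.sample(n=5000, seed=11)
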