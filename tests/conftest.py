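import numpy as np
import pytest

from cochmap import FrequencyPlaceMap, PerfusionModel, SimulationConfig
from cochmap.permutation import ReductionTimeTable


@pytest.fixture(scope="session")
def fmap():
    return FrequencyPlaceMap()


@pytest.fixture(scope="session")
def model():
    return PerfusionModel()


@pytest.fixture(scope="session")
def toy_table():
    """3 operated vs 4 control ears at one frequency: the worked example whose
    one-sided exact p is 1/35 (operated clearly earlier)."""
    return ReductionTimeTable(
        ear_ids=("o1", "o2", "o3", "c1", "c2", "c3", "c4"),
        groups=("operated",) * 3 + ("control",) * 4,
        freqs_khz=(4.0,),
        t50=np.array([[1.0], [2.0], [3.0], [8.0], [9.0], [10.0], [11.0]]),
    )


@pytest.fixture(scope="session")
def study_table():
    """A deterministic 5 + 8 ear table with the study's frequencies."""
    rng = np.random.default_rng(42)
    t50 = rng.normal(20.0, 2.0, (13, 5))
    t50[:5] -= 4.0  # operated ears reduce earlier
    return ReductionTimeTable(
        ear_ids=tuple(f"op{i}" for i in range(5)) + tuple(f"ct{i}" for i in range(8)),
        groups=("operated",) * 5 + ("control",) * 8,
        freqs_khz=(2.0, 4.0, 6.0, 8.0, 12.0),
        t50=t50,
    )


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig()
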