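import numpy as np
import pytest

from kinspec import AbsorbanceTimeCurve, KineticSeriesSet, SimulationConfig
from kinspec.simulate import generate_kinetic_dataset


@pytest.fixture(scope="session")
def noise_free_config() -> SimulationConfig:
    return SimulationConfig(noise_sd=0.0, replicates=1)


@pytest.fixture(scope="session")
def noise_free_set(noise_free_config) -> KineticSeriesSet:
    return generate_kinetic_dataset(noise_free_config)


@pytest.fixture(scope="session")
def default_set() -> KineticSeriesSet:
    """Seeded dataset at the generator's default design and noise level."""
    return generate_kinetic_dataset(SimulationConfig(seed=7))


def make_curve(times, absorbances, conc=None, sample_id="s") -> AbsorbanceTimeCurve:
    return AbsorbanceTimeCurve(
        sample_id=sample_id,
        times=np.asarray(times, dtype=float),
        absorbances=np.asarray(absorbances, dtype=float),
        concentration=conc,
    )


@pytest.fixture
def linear_curve():
    """A(t) = 0.002 t on the study's 300 s grid."""
    t = np.arange(0.0, 2401.0, 300.0)
    return make_curve(t, 0.002 * t, conc=5.0)
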