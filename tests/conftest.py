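import numpy as np
import pytest

from dielspec import (
    DebyeParameters,
    FrequencyGrid,
    Pole,
    TissuePart,
    load_heart_models,
    vna1_grid,
    vna2_grid,
)


@pytest.fixture(scope="session")
def heart_models():
    """The 24 packaged per-(heart, part) three-pole Debye models."""
    return load_heart_models()


@pytest.fixture(scope="session")
def grid81():
    return vna1_grid()


@pytest.fixture(scope="session")
def grid_vna2():
    return vna2_grid()


@pytest.fixture
def a1_endocardium(heart_models) -> DebyeParameters:
    return heart_models[("A1", TissuePart.ENDOCARDIUM)]


def random_debye(rng: np.random.Generator, n_poles: int = 3) -> DebyeParameters:
    """A random physically valid n-pole Debye parameter set at tissue scale."""
    poles = tuple(
        Pole(float(rng.uniform(1.0, 400.0)), float(10.0 ** rng.uniform(-12.5, -8.5)))
        for _ in range(n_poles)
    )
    return DebyeParameters(
        eps_inf=float(rng.uniform(1.0, 20.0)),
        sigma_s=float(rng.uniform(0.0, 2.0)),
        poles=poles,
    )


@pytest.fixture
def log_grid_20():
    return FrequencyGrid(np.logspace(8.7, 10.3, 20))
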