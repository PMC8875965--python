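import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from asblm.membrane import default_membrane_params
from asblm.speciation import MediumComposition, speciate_medium


@pytest.fixture(scope="session")
def membrane_params():
    return default_membrane_params()


@pytest.fixture(scope="session")
def background_medium():
    """Plant hydroponic background medium, 0.2 mM Ca, pH 7, no As."""
    return MediumComposition.background_plant(ca_mM=0.2)


@pytest.fixture(scope="session")
def background_spec(background_medium):
    return speciate_medium(background_medium)


def random_medium(rng: np.random.Generator) -> MediumComposition:
    """A random charge-balanced freshwater-like medium for property tests."""
    totals = {
        "Ca": rng.uniform(0, 20e-3),
        "Mg": rng.uniform(0, 2e-3),
        "K": rng.uniform(0, 2e-3),
        "Na": rng.uniform(0, 20e-3),
        "NO3": rng.uniform(0, 2e-3),
        "SO4": rng.uniform(0, 2e-3),
        "P_total": rng.uniform(0, 0.5e-3),
        "As_total": rng.uniform(0, 1e-4),
    }
    medium = MediumComposition(
        label="random", pH=rng.uniform(4.5, 9.0), totals=totals)
    return medium.with_charge_balance()
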