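import numpy as np
import pytest

from ragut.simulate import SimulationDesign, simulate_cohort


def small_design(seed: int = 11, **overrides) -> SimulationDesign:
    """A scaled-down study design for fast unit tests: same structure,
    fewer subjects and features."""
    params = dict(
        n_hc=10, n_ra=10, n_hqt=5, n_lef=5,
        n_species=60, n_genera=12, n_pathways=20, n_kos=120,
        n_spiked_up=10, n_spiked_down=6, rng_seed=seed,
    )
    params.update(overrides)
    return SimulationDesign(**params)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(small_design(seed=11))


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size synthetic study (22 HC + 22 RA, 110 samples, 200 species)."""
    return simulate_cohort(SimulationDesign(rng_seed=3))
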