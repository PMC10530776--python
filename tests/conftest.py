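import pytest

from ionslab import (
    BeamSpec,
    Layer,
    Material,
    Phantom,
    helium,
    run_simulation,
)


@pytest.fixture(scope="session")
def water() -> Material:
    return Material.from_percents("Water", {"H": 66.6, "O": 33.3}, 10.02, 1.0)


@pytest.fixture(scope="session")
def water_phantom(water) -> Phantom:
    return Phantom("water-slab", (Layer(water, 80.0),))


@pytest.fixture(scope="session")
def water_run(water_phantom):
    """354 MeV helium, 2000 ions, into a stopping-thickness water slab."""
    return run_simulation(BeamSpec(helium(354.0), n_ions=2000, seed=7),
                          water_phantom)
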