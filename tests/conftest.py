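import pytest

from pacolloid import materials


@pytest.fixture(scope="session")
def registry():
    return materials.load_registry()


@pytest.fixture(scope="session")
def silica(registry):
    return registry["silica"]


@pytest.fixture(scope="session")
def alumina(registry):
    return registry["alumina"]


@pytest.fixture(scope="session")
def default_geometry():
    return materials.default_geometry()


@pytest.fixture(scope="session")
def coarse_geometry():
    """Reference phantom on a coarse 26-cell grid for fast pipeline tests."""
    return materials.MediumGeometry(grid_spacing_cm=0.2)


@pytest.fixture(scope="session")
def medium_geometry():
    """Reference phantom on a 52-cell grid: a compromise between fidelity
    and runtime for fluence-profile tests."""
    return materials.MediumGeometry(grid_spacing_cm=0.1)
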