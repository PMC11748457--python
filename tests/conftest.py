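import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from scenariosdm.stack import EnvStack, GridGeometry
from scenariosdm.synthetic import default_landscape, default_niche

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def landscape():
    """Mid-size reference landscape shared by read-only tests."""
    return default_landscape(7, 50, 50)


@pytest.fixture(scope="session")
def niche(landscape):
    return default_niche(landscape)


@pytest.fixture()
def tiny_geometry():
    return GridGeometry(n_rows=5, n_cols=5, cell_size_km=10.0, origin=(100.0, 30.0))


def make_stack(grids: dict, cell_size_km=10.0, origin=(100.0, 30.0), categorical=()):
    """Hand-built stack from named 2-D arrays (test helper)."""
    first = next(iter(grids.values()))
    geom = GridGeometry(first.shape[0], first.shape[1], cell_size_km, origin)
    stack = EnvStack(geometry=geom)
    for name, grid in grids.items():
        stack.add_layer(name, np.asarray(grid, dtype=float), categorical=name in categorical)
    return stack
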