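import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    from dissoflow.synthetic import default_registry

    return default_registry()


@pytest.fixture(scope="session")
def theophylline_spec(registry):
    """Single-substance single-temperature study design (32 points)."""
    from dissoflow.synthetic import GeneratorSpec

    theo = {"theophylline_monohydrate": registry["theophylline_monohydrate"]}
    return GeneratorSpec(substances=theo, temperatures_C=(37.0,), seed=1)


@pytest.fixture(scope="session")
def channel_solution():
    """One converged mid-Re channel solve shared across solver tests."""
    from dissoflow.channel import make_grid, solve_scalar_transport
    from dissoflow.hydrodynamics import ChannelGeometry, FlowState
    from dissoflow.substances import water_properties

    geometry = ChannelGeometry()
    flow = FlowState.from_reynolds(300.0, geometry, 37.0)
    density = water_properties(37.0).density
    grid = make_grid(geometry, nx=400, ny=120, first_spacing_um=0.5)
    field = solve_scalar_transport(
        geometry, flow, D=8e-10, idr=1e-3, grid=grid, density=density
    )
    return geometry, flow, field
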