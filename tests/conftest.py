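import numpy as np
import pytest

from thromboflow.fields import FlowField, ModelParameters, StructuredGrid2D
from thromboflow.synthetic import demo_channel, demo_gap_channel


@pytest.fixture
def params():
    return ModelParameters()


@pytest.fixture
def grid():
    return StructuredGrid2D(nx=8, ny=6, dx=0.01, dy=0.005)


@pytest.fixture
def uniform_flow(grid):
    return FlowField(u=np.full(grid.shape, 1.0), v=np.zeros(grid.shape),
                     mu=np.full(grid.shape, 3.5e-3))


@pytest.fixture(scope="session")
def desk_demo():
    """Small desk-scale recirculating channel (grid, flow, regions)."""
    return demo_channel(32, 16)


@pytest.fixture(scope="session")
def gap_demo():
    """Pump-clearance-scale channel with stresses in the hundreds of Pa."""
    return demo_gap_channel()
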