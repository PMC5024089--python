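import pytest

from aspireprint import Capillary, MachineConfig, TZLPolicy
from aspireprint.fixtures import default_palette, table_inks


@pytest.fixture(scope="session")
def palette():
    return default_palette()


@pytest.fixture()
def machine():
    """Default printer: 85 mm x 0.5 mm capillary, a reservoir per documented ink."""
    reservoirs = {
        ink_id: (120.0 + 15.0 * i, -25.0, 4.0)
        for i, ink_id in enumerate(table_inks())
    }
    return MachineConfig(
        capillary=Capillary(length=85.0, inner_diameter=0.5),
        reservoirs=reservoirs,
        tzl=TZLPolicy(pre_extrusion_um=0.0, plunger_speed=50.0),
    )
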