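import numpy as np
import pytest

from omzsed import synthetic
from omzsed.synthetic import SyntheticCoreSpec


@pytest.fixture
def basic_spec():
    """A mid-transect OMZ-center-like station with an SMTZ at 260 cmbsf."""
    return SyntheticCoreSpec(
        station_id="TEST/6",
        water_depth=530.0,
        bottom_water_temp=11.0,
        bottom_water_o2=2.5,
        sulfate_gradient=27.0 / 260.0,
        porosity=0.75,
        smtz_depth=260.0,
        seed=42,
    )


@pytest.fixture
def noiseless_spec(basic_spec):
    from dataclasses import replace
    zero = {k: 0.0 for k in basic_spec.noise_sd}
    return replace(basic_spec, noise_sd=zero)


@pytest.fixture
def grid_depths():
    return np.arange(7.5, 300.0, 15.0)
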