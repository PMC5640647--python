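import numpy as np
import pytest

import magflow as mf


@pytest.fixture(scope="session")
def unstained_control():
    """Packaged dye-negative control (25 000 events, registry seed)."""
    return mf.generate_scenario(mf.load_scenario("unstained_control"))


@pytest.fixture(scope="session")
def thresholds(unstained_control):
    """Quadrant cuts at the 99.5th nearest-rank percentile of the control."""
    return mf.estimate_thresholds(unstained_control, control_id="unstained_control")


@pytest.fixture(scope="session")
def growing_magnetic():
    return mf.generate_scenario(mf.load_scenario("growing_magnetic"))


@pytest.fixture(scope="session")
def ethanol_killed():
    return mf.generate_scenario(mf.load_scenario("ethanol_killed"))


@pytest.fixture
def small_table():
    """Tiny hand-constructed 5-channel table for plumbing tests."""
    data = np.array(
        [
            [100.0, 50.0, 10.0, 5.0, 200.0],
            [120.0, 60.0, 12.0, 6.0, 220.0],
            [80.0, 40.0, 8.0, 4.0, 180.0],
        ]
    )
    return mf.EventTable(data)
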