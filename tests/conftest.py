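import pytest

from fatiguebattery import (
    assemble_battery,
    default_params,
    simulate_session,
)


@pytest.fixture(scope="session")
def battery():
    return assemble_battery(seed=7)


@pytest.fixture(scope="session")
def short_battery():
    """Full 12-block structure with 60 s blocks, for fast simulation tests."""
    return assemble_battery(seed=7, block_duration_s=60)


@pytest.fixture(scope="session")
def one_session(battery):
    return simulate_session(default_params(seed=11), battery, participant_id="P01")
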