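import dataclasses

import pytest

from biionic import (
    CHANNEL_PRESETS,
    BoltzmannParams,
    PermeabilitySet,
    SimChannelSpec,
    get_solution,
)


def fast_gating_channel(ratios, label="test", **kw):
    """Channel with near-instantaneous gating, fully open at all voltages."""
    return SimChannelSpec(
        label=label,
        perms=PermeabilitySet(ratios=ratios),
        gating=BoltzmannParams(V_half=-500.0, k_slope=8.0),
        tau_act=1e-3,
        tau_deact=1e-3,
        **kw,
    )


@pytest.fixture
def high_na_pipette():
    return get_solution("high-na-pipette")


@pytest.fixture
def ca10_bath():
    return get_solution("ca10-nmdg-bath")


@pytest.fixture
def cavmr():
    return dataclasses.replace(CHANNEL_PRESETS["cavmr-g240a"], seed=0)


@pytest.fixture
def navpp():
    return dataclasses.replace(CHANNEL_PRESETS["navpp-t232a"], seed=0)
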