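import numpy as np
import pytest

from elkvdp import (
    GatingScheme,
    RateLaw,
    State,
    Transition,
    vdp_six_state,
)


@pytest.fixture(scope="session")
def scheme():
    """The shipped 6-state VDP scheme with default parameters."""
    return vdp_six_state()


def make_two_state(a: float = 100.0, b: float = 50.0) -> GatingScheme:
    """Closed <-> open two-state scheme with voltage-independent rates."""
    return GatingScheme(
        states=[State("C"), State("O", conducting=True)],
        transitions=[
            Transition("C", "O", RateLaw(a), "opening"),
            Transition("O", "C", RateLaw(b), "closing"),
        ],
        name="two-state",
    )


@pytest.fixture
def two_state():
    return make_two_state()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
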