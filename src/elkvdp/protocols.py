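"""Builders for the voltage protocols used throughout the VDP analyses.

All protocols hold at -100 mV, step to a family of test potentials, and
measure instantaneous tail currents back at -100 mV, mirroring standard
KCNH-channel stimulus design.  Durations are in seconds, voltages in mV.
"""

from __future__ import annotations

import numpy as np

from .gating import VoltageProtocol

__all__ = [
    "iv_family",
    "gv_family",
    "duration_family",
    "recovery_protocol",
    "DEFAULT_TEST_VOLTAGES",
]

DEFAULT_TEST_VOLTAGES = tuple(np.arange(-120.0, 121.0, 20.0))


def iv_family(
    test_voltages=DEFAULT_TEST_VOLTAGES,
    hold: float = -100.0,
    t_hold: float = 0.05,
    t_test: float = 0.5,
    t_tail: float = 0.15,
    dt: float = 1e-4,
) -> VoltageProtocol:
    """Long-step I-V family; the +120 mV sweep resolves biexponential activation."""
    return VoltageProtocol(
        epochs=[(hold, t_hold), (0.0, t_test), (hold, t_tail)],
        dt=dt,
        variable_epoch=1,
        variable_field="voltage",
        variable_values=list(test_voltages),
    )


def gv_family(
    prepulse: bool = False,
    test_voltages=DEFAULT_TEST_VOLTAGES,
    hold: float = -100.0,
    prepulse_voltage: float = 60.0,
    prepulse_duration: float = 0.5,
    t_hold: float = 0.05,
    t_test: float = 0.1,
    t_tail: float = 0.15,
    dt: float = 1e-4,
) -> VoltageProtocol:
    """Tail-current G-V family, optionally after a potentiating prepulse."""
    epochs = [(hold, t_hold)]
    if prepulse:
        epochs += [(prepulse_voltage, prepulse_duration), (hold, 0.01)]
    var_index = len(epochs)
    epochs += [(0.0, t_test), (hold, t_tail)]
    return VoltageProtocol(
        epochs=epochs,
        dt=dt,
        variable_epoch=var_index,
        variable_field="voltage",
        variable_values=list(test_voltages),
    )


def duration_family(
    durations=(0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0),
    hold: float = -100.0,
    pulse_voltage: float = 60.0,
    t_hold: float = 0.05,
    t_tail: float = 0.15,
    dt: float = 1e-4,
) -> VoltageProtocol:
    """+60 mV pulses of increasing duration; tails track potentiation build-up."""
    return VoltageProtocol(
        epochs=[(hold, t_hold), (pulse_voltage, 0.1), (hold, t_tail)],
        dt=dt,
        variable_epoch=1,
        variable_field="duration",
        variable_values=list(durations),
    )


def recovery_protocol(
    recovery_duration: float,
    test_voltages=DEFAULT_TEST_VOLTAGES,
    hold: float = -100.0,
    prepulse_voltage: float = 60.0,
    prepulse_duration: float = 0.5,
    t_test: float = 0.1,
    t_tail: float = 0.15,
    dt: float = 1e-4,
) -> VoltageProtocol:
    """Potentiate, recover at the holding voltage for a variable time, then
    run a tail G-V family to read out how much potentiation remains."""
    epochs = [(hold, 0.05), (prepulse_voltage, prepulse_duration)]
    if recovery_duration > 0:
        epochs.append((hold, recovery_duration))
    var_index = len(epochs)
    epochs += [(0.0, t_test), (hold, t_tail)]
    return VoltageProtocol(
        epochs=epochs,
        dt=dt,
        variable_epoch=var_index,
        variable_field="voltage",
        variable_values=list(test_voltages),
    )
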