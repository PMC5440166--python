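"""Continuous-time Markov gating schemes under piecewise-constant voltage.

A channel is modelled as a reversible continuous-time Markov chain whose
transition rates may depend exponentially on membrane potential,

    k(V) = k0 * exp(k1 * V),

with ``k0`` the rate at 0 mV (s^-1) and ``k1`` the voltage sensitivity
(mV^-1, zero for voltage-independent steps).  Voltage protocols are ordered
lists of constant-voltage epochs, so state occupancies propagate exactly by
per-epoch matrix exponentials of the generator (Q) matrix -- there is no ODE
truncation error.  Macroscopic current follows the usual ohmic convention
I = g * P_open * (V - E_rev).

Units: time in seconds, rates in s^-1, voltage in mV, current in arbitrary
units (the conductance scale lumps channel count and unitary conductance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from scipy.linalg import expm, null_space

from .exceptions import ConfigError, InvalidInputError

__all__ = [
    "RateLaw",
    "State",
    "Transition",
    "GatingScheme",
    "VoltageProtocol",
    "OccupancyTrace",
    "CurrentTrace",
    "rate_at_voltage",
    "build_generator",
    "equilibrium_distribution",
    "propagate",
    "simulate_current",
    "run_protocol_family",
]


@dataclass(frozen=True)
class RateLaw:
    """Exponentially voltage-dependent rate constant k(V) = k0*exp(k1*V)."""

    k0: float
    k1: float = 0.0

    def __post_init__(self):
        if not math.isfinite(self.k0) or self.k0 < 0:
            raise InvalidInputError(f"k0 must be finite and >= 0, got {self.k0}")
        if not math.isfinite(self.k1):
            raise InvalidInputError(f"k1 must be finite, got {self.k1}")

    def rate(self, v: float) -> float:
        """Rate constant (s^-1) at membrane potential ``v`` (mV)."""
        if not math.isfinite(v):
            raise InvalidInputError(f"voltage must be finite, got {v}")
        return self.k0 * math.exp(self.k1 * v)


def rate_at_voltage(law: RateLaw, v: float) -> float:
    """Evaluate a :class:`RateLaw` at voltage ``v`` (mV)."""
    return law.rate(v)


@dataclass(frozen=True)
class State:
    """A kinetic state: name, whether it conducts, and its gating mode."""

    name: str
    conducting: bool = False
    mode: str = "normal"  # "normal" | "potentiated"


@dataclass(frozen=True)
class Transition:
    """Directed edge ``source -> target`` governed by a :class:`RateLaw`."""

    source: str
    target: str
    law: RateLaw
    label: str = ""


@dataclass
class GatingScheme:
    """A reversible gating scheme: states, transitions and a conductance scale.

    ``conductance`` lumps channel count and unitary conductance (current is in
    arbitrary units); ``e_rev`` is the reversal potential in mV.
    """

    states: list[State]
    transitions: list[Transition]
    conductance: float = 1.0
    e_rev: float = 0.0
    name: str = ""

    def __post_init__(self):
        names = [s.name for s in self.states]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate state names")
        self._index = {n: i for i, n in enumerate(names)}
        seen: set[tuple[str, str]] = set()
        edge_map: dict[tuple[str, str], Transition] = {}
        for tr in self.transitions:
            if tr.source not in self._index or tr.target not in self._index:
                raise ConfigError(f"transition {tr.source}->{tr.target} names unknown state")
            if tr.source == tr.target:
                raise ConfigError(f"self-loop on {tr.source}")
            key = (tr.source, tr.target)
            if key in seen:
                raise ConfigError(f"duplicate transition edge {tr.source}->{tr.target}")
            seen.add(key)
            edge_map[key] = tr
        for (a, b) in seen:
            if (b, a) not in seen:
                raise ConfigError(
                    f"transition {a}->{b} has no reverse edge; the scheme must be reversible"
                )
        g = nx.Graph((a, b) for a, b in seen)
        g.add_nodes_from(names)
        if len(names) > 1 and not nx.is_connected(g):
            raise ConfigError("gating scheme graph is not connected")
        self._edge_map = edge_map
        self._graph = g

    # -- basic accessors ---------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def state_names(self) -> list[str]:
        return [s.name for s in self.states]

    @property
    def conducting_mask(self) -> np.ndarray:
        return np.array([s.conducting for s in self.states], dtype=bool)

    def state_index(self, name: str) -> int:
        return self._index[name]

    def rate(self, source: str, target: str, v: float) -> float:
        return self._edge_map[(source, target)].law.rate(v)

    def with_rate(self, label: str, k0: float, k1: float | None = None) -> "GatingScheme":
        """Return a copy with the rate law of transition ``label`` replaced."""
        hit = False
        new = []
        for tr in self.transitions:
            if tr.label == label:
                law = RateLaw(k0, tr.law.k1 if k1 is None else k1)
                new.append(replace(tr, law=law))
                hit = True
            else:
                new.append(tr)
        if not hit:
            raise ConfigError(f"no transition labelled {label!r}")
        return GatingScheme(self.states, new, self.conductance, self.e_rev, self.name)

    # -- thermodynamics ----------------------------------------------------
    def cycles(self) -> list[list[str]]:
        """Independent undirected cycles of the scheme graph."""
        return nx.cycle_basis(self._graph)

    def cycle_flux_ratios(self, v: float) -> list[float]:
        """Product of forward/reverse rate ratios around each independent cycle.

        Detailed balance requires every product to equal 1 at every voltage.
        """
        out = []
        for cyc in self.cycles():
            prod = 1.0
            for a, b in zip(cyc, cyc[1:] + cyc[:1]):
                prod *= self.rate(a, b, v) / self.rate(b, a, v)
            out.append(prod)
        return out


def build_generator(scheme: GatingScheme, v: float) -> np.ndarray:
    """Q-matrix of the scheme at voltage ``v``: dp/dt = Q p.

    Off-diagonal entry ``(j, i)`` is the i->j rate; columns sum to zero.
    """
    n = scheme.n_states
    q = np.zeros((n, n))
    for tr in scheme.transitions:
        i = scheme.state_index(tr.source)
        j = scheme.state_index(tr.target)
        q[j, i] += tr.law.rate(v)
    q[np.diag_indices(n)] -= q.sum(axis=0)
    return q


def equilibrium_distribution(scheme: GatingScheme, v: float) -> np.ndarray:
    """Stationary distribution (normalised null vector of Q) at voltage ``v``."""
    q = build_generator(scheme, v)
    ns = null_space(q)
    if ns.shape[1] == 0:
        raise InvalidInputError("generator has no null space (numerical failure)")
    p = ns[:, 0]
    p = p / p.sum()
    if p.min() < -1e-9:
        raise InvalidInputError("stationary distribution has negative entries")
    return np.clip(p, 0.0, None) / np.clip(p, 0.0, None).sum()


# ---------------------------------------------------------------------------
# Voltage protocols
# ---------------------------------------------------------------------------

@dataclass
class VoltageProtocol:
    """Ordered piecewise-constant voltage epochs plus an optional family axis.

    ``epochs`` is a list of ``(voltage_mV, duration_s)`` pairs.  A protocol
    family varies one epoch along ``variable_values`` in either its voltage or
    its duration; a variable *duration* of exactly zero drops that epoch for
    the corresponding family member.
    """

    epochs: list[tuple[float, float]]
    dt: float = 1e-4
    variable_epoch: int | None = None
    variable_field: str = "voltage"  # "voltage" | "duration"
    variable_values: list[float] = field(default_factory=list)

    def __post_init__(self):
        if not self.epochs:
            raise ConfigError("protocol has no epochs")
        for v, dur in self.epochs:
            if not math.isfinite(v):
                raise ConfigError("epoch voltage must be finite")
            if not (dur > 0):
                raise ConfigError(f"epoch durations must be > 0, got {dur}")
        if not (self.dt > 0):
            raise ConfigError("sampling interval must be > 0")
        if self.dt > min(d for _, d in self.epochs) + 1e-15:
            raise ConfigError("sampling interval exceeds the shortest epoch")
        if self.variable_epoch is not None:
            if self.variable_field not in ("voltage", "duration"):
                raise ConfigError(f"unknown variable field {self.variable_field!r}")
            if not (0 <= self.variable_epoch < len(self.epochs)):
                raise ConfigError("variable epoch index out of range")
            if not self.variable_values:
                raise ConfigError("protocol family has an empty variable axis")
            if self.variable_field == "duration" and any(d < 0 for d in self.variable_values):
                raise ConfigError("variable durations must be >= 0")

    @property
    def holding_voltage(self) -> float:
        return self.epochs[0][0]

    @property
    def total_duration(self) -> float:
        return sum(d for _, d in self.epochs)

    def epoch_start(self, index: int) -> float:
        return sum(d for _, d in self.epochs[:index])

    def expand(self) -> list[tuple[float, "VoltageProtocol"]]:
        """Concrete (family value, protocol) pairs for a protocol family."""
        if self.variable_epoch is None:
            raise ConfigError("protocol has no variable axis to expand")
        members = []
        for val in self.variable_values:
            epochs = list(self.epochs)
            i = self.variable_epoch
            if self.variable_field == "voltage":
                epochs[i] = (val, epochs[i][1])
            else:
                if val == 0:
                    epochs = epochs[:i] + epochs[i + 1:]
                else:
                    epochs[i] = (epochs[i][0], val)
            members.append((val, VoltageProtocol(epochs, dt=self.dt)))
        return members


# ---------------------------------------------------------------------------
# Traces
# ---------------------------------------------------------------------------

@dataclass
class OccupancyTrace:
    """State probabilities on a time grid with the applied voltage."""

    time: np.ndarray            # (n,)
    occupancy: np.ndarray       # (n, n_states)
    voltage: np.ndarray         # (n,)
    state_names: list[str]
    conducting: np.ndarray      # bool mask over states

    @property
    def open_probability(self) -> np.ndarray:
        return self.occupancy[:, self.conducting].sum(axis=1)

    def conservation_error(self) -> float:
        return float(np.abs(self.occupancy.sum(axis=1) - 1.0).max())


@dataclass
class CurrentTrace:
    """Macroscopic current on a time grid; ``meta`` carries provenance."""

    time: np.ndarray
    current: np.ndarray
    voltage: np.ndarray
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Propagation
# ---------------------------------------------------------------------------

def propagate(
    scheme: GatingScheme,
    protocol: VoltageProtocol,
    p0: np.ndarray | None = None,
) -> OccupancyTrace:
    """Propagate state occupancies through a concrete protocol.

    Within each constant-voltage epoch the solution is the exact matrix
    exponential ``p(t) = expm(Q(V) t) @ p_start`` evaluated on the sampling
    grid.  ``p0`` defaults to the equilibrium distribution at the holding
    (first-epoch) voltage.
    """
    if protocol.variable_epoch is not None:
        raise InvalidInputError("expand() the protocol family before propagating")
    if p0 is None:
        p = equilibrium_distribution(scheme, protocol.holding_voltage)
    else:
        p = np.asarray(p0, dtype=float)
        if p.shape != (scheme.n_states,):
            raise InvalidInputError(
                f"p0 has shape {p.shape}, expected ({scheme.n_states},)"
            )
        if p.min() < -1e-12 or abs(p.sum() - 1.0) > 1e-8:
            raise InvalidInputError("p0 is not a probability distribution")
        p = np.clip(p, 0.0, None)
        p = p / p.sum()

    dt = protocol.dt
    times, occs, volts = [], [], []
    t_offset = 0.0
    for v, dur in protocol.epochs:
        q = build_generator(scheme, v)
        step = expm(q * dt)
        n_steps = int(math.floor(dur / dt + 1e-9))
        cur = p
        for k in range(n_steps):
            times.append(t_offset + k * dt)
            occs.append(cur)
            volts.append(v)
            cur = step @ cur
        # exact jump to the epoch boundary (duration need not divide dt)
        p = expm(q * dur) @ p
        t_offset += dur
    times.append(t_offset)
    occs.append(p)
    volts.append(protocol.epochs[-1][0])

    return OccupancyTrace(
        time=np.asarray(times),
        occupancy=np.vstack(occs),
        voltage=np.asarray(volts),
        state_names=scheme.state_names,
        conducting=scheme.conducting_mask,
    )


def simulate_current(occ: OccupancyTrace, scheme: GatingScheme) -> CurrentTrace:
    """Macroscopic current I = g * P_open * (V - E_rev) from an occupancy trace."""
    if occ.occupancy.shape[1] != scheme.n_states or occ.state_names != scheme.state_names:
        raise InvalidInputError("occupancy trace does not match the scheme's states")
    i = scheme.conductance * occ.open_probability * (occ.voltage - scheme.e_rev)
    return CurrentTrace(
        time=occ.time.copy(),
        current=i,
        voltage=occ.voltage.copy(),
        meta={"scheme": scheme.name, "e_rev": scheme.e_rev},
    )


def run_protocol_family(
    scheme: GatingScheme, protocol: VoltageProtocol
) -> list[CurrentTrace]:
    """Simulate every member of a protocol family.

    Each sweep starts from the equilibrium distribution at the holding
    voltage.  Trace metadata records the family value, the test voltage and
    the start time/voltage of the epoch following the variable one (the tail
    epoch), which downstream tail-current analyses consume.
    """
    members = protocol.expand()
    p0 = equilibrium_distribution(scheme, protocol.holding_voltage)
    traces = []
    for val, concrete in members:
        occ = propagate(scheme, concrete, p0)
        tr = simulate_current(occ, scheme)
        i_var = protocol.variable_epoch
        if protocol.variable_field == "voltage":
            test_v = val
            test_dur = protocol.epochs[i_var][1]
            tail_index = i_var + 1
        else:
            test_v = protocol.epochs[i_var][0]
            test_dur = val
            tail_index = i_var + 1 if val > 0 else i_var
        tr.meta.update(
            family_value=val,
            test_voltage=test_v,
            test_duration=test_dur,
        )
        if tail_index < len(concrete.epochs):
            tr.meta["tail_start"] = concrete.epoch_start(tail_index)
            tr.meta["tail_voltage"] = concrete.epochs[tail_index][0]
        traces.append(tr)
    return traces
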