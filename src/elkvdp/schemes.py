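"""The shipped 6-state voltage-dependent-potentiation (VDP) gating scheme.

Two three-state tiers share one voltage-dependent activation step:

    normal:       C1  <-a/b->  C2  <-gamma/delta->  O1
    potentiated:  C1p <-a/b->  C2p <-omicron/kappa-> O2

with a(V) = 80*exp(0.025 V) s^-1 and b(V) = 600*exp(-0.025 V) s^-1 in both
tiers, gamma = 60 / delta = 200 s^-1 for the normal closed-open step and
omicron = 5000 / kappa = 70 s^-1 for the much more favourable potentiated
one.  The slow mode shift links the open states (O1 -> O2, epsilon = 35
s^-1).  Because the potentiated opening equilibrium is ~240-fold more
favourable than the normal one, detailed balance forces the closed-tier mode
link to be correspondingly unfavourable, which is exactly what makes the mode
shift voltage dependent: channels only reach the potentiated mode efficiently
through the open state, i.e. at depolarised voltages.

The mode-reverse rates are not constrained by the forward parameter set; the
package defaults (``eps_r`` = 2 s^-1, ``c1p_to_c1`` = 7.2 s^-1) are chosen so
that recovery from potentiation at -100 mV relaxes with tau ~= 136 ms, and the
C1 -> C1p rate is then fixed by detailed balance around the six-state cycle.
Both are overridable.
"""

from __future__ import annotations

import importlib.resources

import yaml

from .exceptions import ConfigError
from .gating import GatingScheme, RateLaw, State, Transition

__all__ = ["vdp_six_state", "potentiated_locked", "load_scheme", "load_protocols"]


def vdp_six_state(
    alpha0: float = 80.0,
    alpha_k1: float = 0.025,
    beta0: float = 600.0,
    beta_k1: float = -0.025,
    gamma: float = 60.0,
    delta: float = 200.0,
    omicron: float = 5000.0,
    kappa: float = 70.0,
    eps: float = 35.0,
    eps_r: float = 2.0,
    c1p_to_c1: float = 7.2,
    conductance: float = 1.0,
    e_rev: float = 0.0,
) -> GatingScheme:
    """Build the canonical 6-state VDP scheme.

    The closed-tier mode link C1 -> C1p is computed from detailed balance,
    K(C1->C1p) = (gamma/delta) * (eps/eps_r) * (kappa/omicron),
    so every cycle product of equilibrium constants is exactly 1.
    """
    k_mode_closed = (gamma / delta) * (eps / eps_r) * (kappa / omicron)
    c1_to_c1p = k_mode_closed * c1p_to_c1
    alpha = RateLaw(alpha0, alpha_k1)
    beta = RateLaw(beta0, beta_k1)
    states = [
        State("C1"), State("C2"), State("O1", conducting=True),
        State("C1p", mode="potentiated"),
        State("C2p", mode="potentiated"),
        State("O2", conducting=True, mode="potentiated"),
    ]
    transitions = [
        Transition("C1", "C2", alpha, "alpha_n"),
        Transition("C2", "C1", beta, "beta_n"),
        Transition("C2", "O1", RateLaw(gamma), "gamma"),
        Transition("O1", "C2", RateLaw(delta), "delta"),
        Transition("C1p", "C2p", alpha, "alpha_p"),
        Transition("C2p", "C1p", beta, "beta_p"),
        Transition("C2p", "O2", RateLaw(omicron), "omicron"),
        Transition("O2", "C2p", RateLaw(kappa), "kappa"),
        Transition("O1", "O2", RateLaw(eps), "eps"),
        Transition("O2", "O1", RateLaw(eps_r), "eps_r"),
        Transition("C1", "C1p", RateLaw(c1_to_c1p), "mode_closed_fwd"),
        Transition("C1p", "C1", RateLaw(c1p_to_c1), "mode_closed_rev"),
    ]
    return GatingScheme(states, transitions, conductance, e_rev, name="vdp6")


def potentiated_locked(**kwargs) -> GatingScheme:
    """Scheme variant emulating excised patches that have lost VDP.

    The mode-reverse rates are set to ~0 so the equilibrium (and hence every
    sweep's initial condition) sits in the potentiated tier and the channel no
    longer shifts between modes on experimental timescales.
    """
    kwargs.setdefault("eps_r", 1e-6)
    kwargs.setdefault("c1p_to_c1", 1e-6)
    scheme = vdp_six_state(**kwargs)
    scheme.name = "vdp6-potentiated-locked"
    return scheme


# ---------------------------------------------------------------------------
# YAML scheme / protocol configuration
# ---------------------------------------------------------------------------

def _parse_scheme(doc: dict) -> GatingScheme:
    try:
        states = [
            State(s["name"], bool(s.get("conducting", False)), s.get("mode", "normal"))
            for s in doc["states"]
        ]
        transitions = [
            Transition(
                t["from"], t["to"],
                RateLaw(float(t["k0"]), float(t.get("k1", 0.0))),
                t.get("label", ""),
            )
            for t in doc["transitions"]
        ]
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"malformed scheme config: {exc}") from exc
    return GatingScheme(
        states,
        transitions,
        conductance=float(doc.get("conductance", 1.0)),
        e_rev=float(doc.get("e_rev", 0.0)),
        name=str(doc.get("name", "")),
    )


def load_scheme(path=None) -> GatingScheme:
    """Load a gating scheme from a YAML config (default: the shipped model)."""
    if path is None:
        text = (
            importlib.resources.files("elkvdp") / "data" / "vdp6.yaml"
        ).read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "scheme" not in doc:
        raise ConfigError("config must be a mapping with a 'scheme' section")
    return _parse_scheme(doc["scheme"])


def load_protocols(path=None) -> dict:
    """Load named protocol definitions from the same YAML format."""
    from .gating import VoltageProtocol

    if path is None:
        text = (
            importlib.resources.files("elkvdp") / "data" / "vdp6.yaml"
        ).read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    out = {}
    for name, spec in (doc.get("protocols") or {}).items():
        try:
            epochs = [(float(e["voltage"]), float(e["duration"])) for e in spec["epochs"]]
            proto = VoltageProtocol(
                epochs,
                dt=float(spec.get("dt", 1e-4)),
                variable_epoch=spec.get("variable_epoch"),
                variable_field=spec.get("variable_field", "voltage"),
                variable_values=[float(v) for v in spec.get("variable_values", [])],
            )
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"malformed protocol {name!r}: {exc}") from exc
        out[name] = proto
    return out
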