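"""Seeded synthetic-data generators standing in for the study's recordings.

Every analysis stage in the package has a generator here whose noiseless
output the corresponding fitter must invert exactly (the generator/analyzer
adjointness property the test suite enforces).  Defaults encode the study
conditions: the shipped 6-state gating scheme, the 5-point Co2+ ladder
(10-1000 uM), Langmuir parameters Eff_max = 0.71 / K1/2 = 66.1 uM (no ATP)
and 0.46 / 48.0 uM (with ATP/Mg2+), a Boltzmann slope factor of 12 mV,
recovery time constants of 136/293 ms, fluorescence relaxation of 261 ms, and
camera frames every 100 ms with 50 ms exposures.

Noise models are deliberately plain: additive Gaussian on currents and G-V
amplitudes, multiplicative Gaussian on fluorescence (photon-flux
proportional).  Identical seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigError
from .gating import CurrentTrace, run_protocol_family
from . import protocols as _protocols
from .ephys import RecoveryCourse, boltzmann, GVCurve
from .schemes import potentiated_locked, vdp_six_state
from .tmfret import (
    EmissionSpectrum,
    QuenchingKinetics,
    QuenchingMeasurement,
    QuenchingTitration,
    fret_from_rates,
    langmuir,
)

__all__ = [
    "NoiseSpec",
    "PRESETS",
    "DEFAULT_CONCENTRATION_LADDER",
    "gen_current_dataset",
    "gen_titration",
    "gen_fluor_timecourse",
    "gen_gv_dataset",
    "gen_recovery_course",
    "gen_spectrum",
]

DEFAULT_CONCENTRATION_LADDER = (10.0, 30.0, 100.0, 300.0, 1000.0)  # uM


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model, magnitude and seed for a synthetic dataset.

    ``sigma`` is in units of the signal for the additive model and a
    fraction of the signal for the multiplicative one.
    """

    model: str = "additive-gaussian"  # or "multiplicative-gaussian"
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.model not in ("additive-gaussian", "multiplicative-gaussian"):
            raise ConfigError(f"unknown noise model {self.model!r}")
        if self.sigma < 0:
            raise ConfigError("noise sigma must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.sigma == 0:
            return np.asarray(values, dtype=float)
        noise = rng.normal(0.0, self.sigma, size=np.shape(values))
        if self.model == "additive-gaussian":
            return values + noise
        return values * (1.0 + noise)


# ---------------------------------------------------------------------------
# Current-trace families
# ---------------------------------------------------------------------------

# Scenario presets: "cell-attached" keeps the full VDP-competent scheme;
# "excised" locks the channels in the potentiated mode (PI(4,5)P2 loss).
PRESETS = {
    "cell-attached": vdp_six_state,
    "excised": potentiated_locked,
}

_PROTOCOLS = {
    "iv": _protocols.iv_family,
    "gv_naive": lambda: _protocols.gv_family(prepulse=False),
    "gv_prepulse": lambda: _protocols.gv_family(prepulse=True),
    "duration": _protocols.duration_family,
}


def gen_current_dataset(
    preset: str = "cell-attached",
    protocol: str = "duration",
    noise: NoiseSpec | None = None,
) -> list[CurrentTrace]:
    """Noisy current-trace family from a scenario preset.

    The noiseless core is the exact matrix-exponential simulation; additive
    Gaussian noise (sigma in current units) is drawn from one RNG stream,
    one substream draw per sweep in family order.
    """
    if preset not in PRESETS:
        raise ConfigError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    if protocol not in _PROTOCOLS:
        raise ConfigError(
            f"unknown protocol {protocol!r}; choose from {sorted(_PROTOCOLS)}"
        )
    noise = noise or NoiseSpec()
    scheme = PRESETS[preset]()
    traces = run_protocol_family(scheme, _PROTOCOLS[protocol]())
    rng = noise.rng()
    for tr in traces:
        tr.current = noise.apply(tr.current, rng)
        tr.meta.update(preset=preset, protocol=protocol,
                       noise_model=noise.model, noise_sigma=noise.sigma,
                       seed=noise.seed)
    return traces


# ---------------------------------------------------------------------------
# Quenching titrations
# ---------------------------------------------------------------------------

def gen_titration(
    eff_max: float = 0.71,
    k_half_uM: float = 66.1,
    ladder=DEFAULT_CONCENTRATION_LADDER,
    noise: NoiseSpec | None = None,
    k_ph: float = 1.0,
    f_nohh_at_saturation: float = 0.9,
    fl_no_metal: float = 1000.0,
    label: str = "dihistidine",
) -> tuple[QuenchingTitration, QuenchingTitration]:
    """Synthetic Co2+ titration pair (test + no-dihistidine control).

    Fluorescence is generated through the kinetic competition model so that
    the control-corrected efficiencies follow the Langmuir curve exactly at
    sigma = 0: k_HH(c) = k_ph*E(c)/(1 - E(c)) with E(c) the Langmuir
    efficiency, and a collisional (linear in concentration) nonspecific rate
    k_no(c) scaled so the control fluorescence drops to
    ``f_nohh_at_saturation`` at the top of the ladder.

    Each titration emulates one patch: its no-metal baseline is a single
    measurement (one noise draw, shared across the ladder), while the
    metal-quenched fluorescence gets an independent draw per concentration.
    """
    ladder = np.asarray(ladder, dtype=float)
    if np.any(np.diff(ladder) <= 0) or ladder.min() <= 0:
        raise ConfigError("concentration ladder must be positive and ascending")
    if not (0 < eff_max < 1):
        raise ConfigError("eff_max must lie in (0, 1)")
    noise = noise or NoiseSpec("multiplicative-gaussian", 0.0, 0)
    k_sv = k_ph * (1.0 / f_nohh_at_saturation - 1.0) / ladder.max()
    rng = noise.rng()
    base_test = float(np.clip(noise.apply(np.array(fl_no_metal), rng), 1e-9, None))
    base_ctrl = float(np.clip(noise.apply(np.array(fl_no_metal), rng), 1e-9, None))
    test_ms, ctrl_ms = [], []
    for c in ladder:
        e = float(langmuir(c, eff_max, k_half_uM))
        k_hh = k_ph * e / (1.0 - e)
        k_no = k_sv * c
        _, f_hh, f_nohh = fret_from_rates(QuenchingKinetics(k_ph, k_hh, k_no))
        fl = noise.apply(
            np.array([fl_no_metal * f_hh, fl_no_metal * f_nohh]), rng
        )
        fl = np.clip(fl, 1e-9, None)
        test_ms.append(QuenchingMeasurement(c, fl_metal=fl[0], fl_no_metal=base_test))
        ctrl_ms.append(QuenchingMeasurement(c, fl_metal=fl[1], fl_no_metal=base_ctrl))
    return (
        QuenchingTitration(label, test_ms),
        QuenchingTitration("no-dihistidine control", ctrl_ms),
    )


# ---------------------------------------------------------------------------
# Fluorescence time courses
# ---------------------------------------------------------------------------

def gen_fluor_timecourse(
    tau_s: float = 0.261,
    t_depol_start: float = 0.5,
    t_depol_end: float = 2.5,
    total_s: float = 4.0,
    f_rest: float = 1.0,
    f_depol: float = 0.8,
    tau_recovery_s: float | None = 0.1375,
    frame_interval_s: float = 0.1,
    exposure_s: float = 0.05,
    noise: NoiseSpec | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Camera-sampled donor fluorescence during a depolarising step.

    The underlying fluorescence relaxes mono-exponentially towards a
    voltage-dependent level (``tau_s`` on depolarisation, ``tau_recovery_s``
    after repolarisation); each frame integrates the signal over the exposure
    window, which scales amplitudes but leaves the time constants intact.
    Returns (frame start times, frame-averaged fluorescence).
    """
    if tau_s <= 0:
        raise ConfigError("tau must be > 0")
    tau_rec = tau_recovery_s if tau_recovery_s is not None else tau_s
    if tau_rec <= 0:
        raise ConfigError("recovery tau must be > 0")
    noise = noise or NoiseSpec("multiplicative-gaussian", 0.0, 0)

    def level(t: np.ndarray) -> np.ndarray:
        out = np.full_like(t, f_rest, dtype=float)
        dep = (t >= t_depol_start) & (t < t_depol_end)
        out[dep] = f_depol + (f_rest - f_depol) * np.exp(
            -(t[dep] - t_depol_start) / tau_s
        )
        f_at_end = f_depol + (f_rest - f_depol) * np.exp(
            -(t_depol_end - t_depol_start) / tau_s
        )
        rec = t >= t_depol_end
        out[rec] = f_rest + (f_at_end - f_rest) * np.exp(-(t[rec] - t_depol_end) / tau_rec)
        return out

    frames = np.arange(0.0, total_s - exposure_s + 1e-12, frame_interval_s)
    # exposure integration by fine quadrature inside each frame window
    sub = np.linspace(0.0, exposure_s, 21)
    values = np.array([np.trapezoid(level(t0 + sub), sub) / exposure_s for t0 in frames])
    values = noise.apply(values, noise.rng())
    return frames, values


# ---------------------------------------------------------------------------
# G-V datasets, recovery courses, spectra
# ---------------------------------------------------------------------------

def gen_gv_dataset(
    v_half: float = -52.5,
    v_slope: float = 12.0,
    i_max: float = 1.0,
    i_min: float = 0.0,
    voltages=None,
    noise: NoiseSpec | None = None,
) -> GVCurve:
    """Boltzmann-distributed tail-current G-V data.

    Additive noise sigma is interpreted as a fraction of Imax (the usual way
    instrumentation noise is quoted for normalised tail currents).
    """
    if v_slope <= 0:
        raise ConfigError("slope factor must be > 0")
    if voltages is None:
        voltages = np.arange(-120.0, 41.0, 10.0)
    voltages = np.asarray(voltages, dtype=float)
    amps = boltzmann(voltages, i_min, i_max, v_half, v_slope)
    if noise is not None and noise.sigma > 0:
        scaled = NoiseSpec(noise.model, noise.sigma * abs(i_max), noise.seed) \
            if noise.model == "additive-gaussian" else noise
        amps = scaled.apply(amps, scaled.rng())
    return GVCurve(voltages, amps, tail_voltage=-100.0)


def gen_recovery_course(
    tau_s: float = 0.136,
    durations=(0.0, 0.05, 0.1, 0.2, 0.3, 0.5),
    y0: float = -55.0,
    y_inf: float = 0.0,
    kind: str = "v_half",
    noise: NoiseSpec | None = None,
) -> RecoveryCourse:
    """Exponential recovery course y(t) = y_inf + (y0 - y_inf)*exp(-t/tau)."""
    if tau_s <= 0:
        raise ConfigError("tau must be > 0")
    t = np.asarray(durations, dtype=float)
    y = y_inf + (y0 - y_inf) * np.exp(-t / tau_s)
    if noise is not None and noise.sigma > 0:
        y = noise.apply(y, noise.rng())
    return RecoveryCourse(t, y, kind=kind)


def gen_spectrum(
    center_nm: float = 480.0,
    width_nm: float = 30.0,
    amplitude: float = 100.0,
    background: float = 5.0,
    wavelengths=None,
    background_region: tuple[float, float] = (580.0, 620.0),
    noise: NoiseSpec | None = None,
) -> EmissionSpectrum:
    """Gaussian emission band on a constant background."""
    if wavelengths is None:
        wavelengths = np.arange(400.0, 621.0, 2.0)
    wl = np.asarray(wavelengths, dtype=float)
    y = background + amplitude * np.exp(-0.5 * ((wl - center_nm) / width_nm) ** 2)
    if noise is not None and noise.sigma > 0:
        y = noise.apply(y, noise.rng())
    return EmissionSpectrum(wl, y, background_region=background_region)
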