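"""Transition-metal-ion FRET (tmFRET) analysis.

tmFRET reports short (10-20 A) intramolecular distances from the quenching of
a donor fluorophore (here the noncanonical amino acid L-Anap) by a bound
transition-metal acceptor (Co2+ coordinated by an engineered dihistidine).
The module implements:

* donor-fluorescence normalisation, F = fl(metal)/fl(no metal);
* two efficiency estimators -- the "simple" one, E = 1 - F_HH/F_noHH, valid
  when the nonspecific fluorescence loss does not involve energy transfer,
  and the "corrected" one derived from kinetic competition between photon
  emission (k_ph), transfer to the dihistidine-bound metal (k_HH) and
  nonspecific relaxation (k_no):

      E = (F_noHH - F_HH) / (F_HH * F_noHH + F_noHH - F_HH)

  which returns exactly k_HH/(k_ph + k_HH) when both F values arise from the
  competition scheme;
* the rate-constant forward model used as the estimator's oracle;
* Langmuir (single-site) fits of apparent efficiency vs metal concentration;
* Forster-equation conversion of efficiency to distance, R = R0*(1/E - 1)^(1/6);
* background-subtracted emission-spectrum peak localisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .exceptions import FitError, InvalidInputError, UnreliableFitWarning

__all__ = [
    "QuenchingMeasurement",
    "QuenchingTitration",
    "FretEfficiency",
    "QuenchingKinetics",
    "LangmuirFit",
    "DistanceResult",
    "EmissionSpectrum",
    "PeakResult",
    "DEFAULT_R0",
    "normalize_fluorescence",
    "fret_eff_simple",
    "fret_eff_corrected",
    "fret_from_rates",
    "apparent_efficiencies",
    "langmuir",
    "fit_langmuir",
    "forster_distance",
    "spectrum_peak",
]

DEFAULT_R0 = 12.0  # Angstrom, L-Anap / Co2+-dihistidine pair


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass
class QuenchingMeasurement:
    """Donor fluorescence with and without metal at one concentration (uM)."""

    conc_uM: float
    fl_metal: float
    fl_no_metal: float

    def __post_init__(self):
        if self.conc_uM < 0:
            raise InvalidInputError("metal concentration must be >= 0")
        if self.fl_metal < 0 or self.fl_no_metal < 0:
            raise InvalidInputError("fluorescence values must be >= 0")


@dataclass
class QuenchingTitration:
    """A labelled series of quenching measurements at ascending concentrations."""

    label: str
    measurements: list[QuenchingMeasurement]

    def __post_init__(self):
        conc = self.concentrations
        if conc.size and np.any(np.diff(conc) <= 0):
            raise InvalidInputError("concentrations must be strictly increasing")

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([m.conc_uM for m in self.measurements])

    @property
    def normalized(self) -> np.ndarray:
        return np.array([normalize_fluorescence(m) for m in self.measurements])


@dataclass
class FretEfficiency:
    """A FRET efficiency in [0, 1] with the estimator used to obtain it."""

    value: float
    method: str  # "simple" | "corrected"
    f_hh: float | None = None
    f_nohh: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.value <= 1.0):
            raise InvalidInputError(f"efficiency {self.value} outside [0, 1]")


@dataclass(frozen=True)
class QuenchingKinetics:
    """Excited-state relaxation rate constants (relative units).

    ``k_ph``: photon emission; ``k_hh``: energy transfer to the
    dihistidine-bound metal; ``k_no``: summed nonspecific relaxation.
    """

    k_ph: float
    k_hh: float = 0.0
    k_no: float = 0.0

    def __post_init__(self):
        if self.k_ph <= 0:
            raise InvalidInputError("k_ph must be > 0")
        if self.k_hh < 0 or self.k_no < 0:
            raise InvalidInputError("rate constants must be >= 0")


@dataclass
class LangmuirFit:
    """Single-site binding fit of apparent efficiency vs metal concentration."""

    eff_max: float
    k_half_uM: float
    stderr: dict = field(default_factory=dict)
    reliable: bool = True
    k_half_identifiable: bool = True


@dataclass
class DistanceResult:
    """Donor-acceptor distance from the Forster equation."""

    r: float            # Angstrom
    r0: float           # Angstrom
    efficiency: float


@dataclass
class EmissionSpectrum:
    """Fluorescence emission spectrum with an optional background region."""

    wavelength_nm: np.ndarray
    intensity: np.ndarray
    background_region: tuple[float, float] | None = None

    def __post_init__(self):
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavelength_nm.size != self.intensity.size:
            raise InvalidInputError("wavelength and intensity differ in length")
        if np.any(np.diff(self.wavelength_nm) <= 0):
            raise InvalidInputError("wavelengths must be strictly increasing")


@dataclass
class PeakResult:
    wavelength_nm: float
    intensity: float
    flagged: bool = False


# ---------------------------------------------------------------------------
# Efficiency estimators
# ---------------------------------------------------------------------------

def normalize_fluorescence(m: QuenchingMeasurement) -> float:
    """F = fl(metal) / fl(no metal); warns above 1.05 (anti-quenching artifact)."""
    if m.fl_no_metal == 0:
        raise InvalidInputError("fl_no_metal is zero; cannot normalize")
    f = m.fl_metal / m.fl_no_metal
    if f > 1.05:
        warnings.warn(
            f"normalized fluorescence {f:.3f} > 1.05 at {m.conc_uM} uM "
            "(anti-quenching artifact?)",
            UnreliableFitWarning,
        )
    return f


def _check_f(f_hh: float, f_nohh: float) -> None:
    if f_nohh <= 0:
        raise InvalidInputError("F_noHH must be > 0")
    if f_nohh > 1.05:
        raise InvalidInputError(f"F_noHH = {f_nohh} exceeds 1.05")
    if f_hh < 0:
        raise InvalidInputError("F_HH must be >= 0")


def fret_eff_simple(f_hh: float, f_nohh: float) -> FretEfficiency:
    """E = 1 - F_HH/F_noHH (nonspecific loss without energy transfer)."""
    _check_f(f_hh, f_nohh)
    raw = 1.0 - f_hh / f_nohh
    if raw < 0:
        warnings.warn(
            f"negative simple efficiency {raw:.4f} clipped to 0", UnreliableFitWarning
        )
        raw = 0.0
    return FretEfficiency(value=raw, method="simple", f_hh=f_hh, f_nohh=f_nohh)


def fret_eff_corrected(f_hh: float, f_nohh: float) -> FretEfficiency:
    """Kinetic-competition corrected efficiency.

    E = (F_noHH - F_HH) / (F_HH*F_noHH + F_noHH - F_HH); reduces to the simple
    estimator when F_noHH = 1 and is exact when the nonspecific loss is an
    extra excited-state relaxation pathway (collisional quenching or FRET to
    an endogenous metal site).
    """
    _check_f(f_hh, f_nohh)
    denom = f_hh * f_nohh + f_nohh - f_hh
    if denom <= 0:
        raise InvalidInputError(
            f"corrected-efficiency denominator {denom} <= 0 (F_HH={f_hh}, F_noHH={f_nohh})"
        )
    raw = (f_nohh - f_hh) / denom
    if raw < 0:
        warnings.warn(
            f"negative corrected efficiency {raw:.4f} clipped to 0",
            UnreliableFitWarning,
        )
        raw = 0.0
    return FretEfficiency(value=raw, method="corrected", f_hh=f_hh, f_nohh=f_nohh)


def fret_from_rates(k: QuenchingKinetics) -> tuple[float, float, float]:
    """Forward model: (E, F_HH, F_noHH) from the competition rate constants.

    E = k_HH/(k_ph + k_HH);  F_noHH = k_ph/(k_ph + k_no);
    F_HH = k_ph/(k_ph + k_HH + k_no).  Serves as the independent oracle for
    :func:`fret_eff_corrected`.
    """
    eff = k.k_hh / (k.k_ph + k.k_hh)
    f_nohh = k.k_ph / (k.k_ph + k.k_no)
    f_hh = k.k_ph / (k.k_ph + k.k_hh + k.k_no)
    return eff, f_hh, f_nohh


# ---------------------------------------------------------------------------
# Langmuir binding fits
# ---------------------------------------------------------------------------

def langmuir(conc, eff_max, k_half):
    """Apparent efficiency = Eff_max * [M] / (K1/2 + [M])."""
    conc = np.asarray(conc, dtype=float)
    return eff_max * conc / (k_half + conc)


def apparent_efficiencies(
    titration: QuenchingTitration,
    control: QuenchingTitration,
    method: str = "corrected",
) -> np.ndarray:
    """Per-concentration efficiencies of a test titration against its control.

    The no-dihistidine control supplies F_noHH; controls measured on a
    different concentration grid are linearly interpolated.  Normalized
    fluorescence is allowed up to the anti-quenching tolerance of 1.05 (a
    symmetric noise excursion above 1 carries information; truncating at 1
    would bias the efficiencies); rarer excursions beyond 1.05 are clipped.
    """
    if method not in ("corrected", "simple"):
        raise InvalidInputError(f"unknown efficiency method {method!r}")
    est = fret_eff_corrected if method == "corrected" else fret_eff_simple
    c_ctrl = control.concentrations
    f_ctrl = np.minimum(control.normalized, 1.05)
    out = []
    for m in titration.measurements:
        f_hh = min(normalize_fluorescence(m), 1.05)
        f_nohh = float(np.interp(m.conc_uM, c_ctrl, f_ctrl))
        out.append(est(f_hh, f_nohh).value)
    return np.asarray(out)


def fit_langmuir(
    titration: QuenchingTitration,
    control: QuenchingTitration,
    method: str = "corrected",
) -> LangmuirFit:
    """Fit the Langmuir isotherm to control-corrected efficiencies.

    The fit is flagged unreliable when the titration does not reach ~5x the
    fitted K1/2 (no saturation coverage), and K1/2 is marked unidentifiable
    when there is essentially no quenching signal.
    """
    conc = titration.concentrations
    if conc.size < 4:
        raise InvalidInputError("need at least 4 concentrations for a Langmuir fit")
    eff = apparent_efficiencies(titration, control, method=method)
    if eff.max() < 0.01:
        return LangmuirFit(
            eff_max=float(eff.max()), k_half_uM=float("nan"),
            reliable=False, k_half_identifiable=False,
        )
    half = 0.5 * eff.max()
    k0 = float(conc[np.argmin(np.abs(eff - half))]) or float(np.median(conc))
    try:
        popt, pcov = curve_fit(
            langmuir, conc, eff, p0=[eff.max(), k0],
            bounds=([0.0, 1e-9], [1.5, np.inf]), maxfev=20000,
            xtol=1e-13, ftol=1e-13,
        )
    except RuntimeError as exc:
        raise FitError(f"Langmuir fit did not converge: {exc}") from exc
    perr = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    fit = LangmuirFit(
        eff_max=float(popt[0]), k_half_uM=float(popt[1]),
        stderr={"eff_max": float(perr[0]), "k_half_uM": float(perr[1])},
    )
    if conc.max() < 5.0 * fit.k_half_uM:
        fit.reliable = False
        warnings.warn(
            "titration does not reach 5x K1/2; Langmuir fit flagged unreliable",
            UnreliableFitWarning,
        )
    return fit


# ---------------------------------------------------------------------------
# Distances and spectra
# ---------------------------------------------------------------------------

def forster_distance(eff: float | FretEfficiency, r0: float = DEFAULT_R0) -> DistanceResult:
    """R = R0 * (1/E - 1)^(1/6) for 0 < E < 1."""
    e = eff.value if isinstance(eff, FretEfficiency) else float(eff)
    if r0 <= 0:
        raise InvalidInputError("R0 must be > 0")
    if not (0.0 < e < 1.0):
        raise InvalidInputError(
            f"efficiency must lie strictly between 0 and 1, got {e}"
        )
    r = r0 * (1.0 / e - 1.0) ** (1.0 / 6.0)
    return DistanceResult(r=float(r), r0=float(r0), efficiency=e)


def spectrum_peak(s: EmissionSpectrum) -> PeakResult:
    """Background-subtracted emission peak via quadratic interpolation.

    The background is the mean intensity over the annotated wavelength
    region (if any).  A flat spectrum is flagged rather than rejected.
    """
    wl, y = s.wavelength_nm, s.intensity.astype(float)
    if wl.size < 10:
        raise InvalidInputError("need at least 10 wavelength samples")
    if s.background_region is not None:
        lo, hi = s.background_region
        mask = (wl >= lo) & (wl <= hi)
        if mask.any():
            y = y - y[mask].mean()
    if np.ptp(y) <= 1e-12 * max(1.0, np.abs(y).max()):
        return PeakResult(wavelength_nm=float("nan"), intensity=0.0, flagged=True)
    i = int(np.argmax(y))
    if 0 < i < wl.size - 1:
        # vertex of the parabola through the max sample and its neighbours
        x0, x1, x2 = wl[i - 1:i + 2]
        y0, y1, y2 = y[i - 1:i + 2]
        denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
        a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
        b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
        if a < 0:
            xv = -b / (2 * a)
            # evaluate the Lagrange parabola at its vertex
            yv = (
                y0 * (xv - x1) * (xv - x2) / ((x0 - x1) * (x0 - x2))
                + y1 * (xv - x0) * (xv - x2) / ((x1 - x0) * (x1 - x2))
                + y2 * (xv - x0) * (xv - x1) / ((x2 - x0) * (x2 - x1))
            )
            return PeakResult(wavelength_nm=float(xv), intensity=float(yv))
    return PeakResult(wavelength_nm=float(wl[i]), intensity=float(y[i]))
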