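"""Electrophysiological analyses quantifying voltage-dependent potentiation.

The analyses here are applied identically to simulated and loaded traces:

* mono/biexponential fits of current relaxations,
* instantaneous tail-current measurement by back-extrapolation,
* tail-current conductance-voltage (G-V) curves and Boltzmann fits,
* activation energetics, dG = R*T*V1/2/Vs, and the prepulse ddG that
  quantifies potentiation,
* exponential fits of recovery-from-potentiation time courses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, least_squares

from .exceptions import FitError, InvalidInputError, UnreliableFitWarning
from .gating import CurrentTrace

__all__ = [
    "ExpFitResult",
    "GVCurve",
    "BoltzmannFit",
    "EnergyResult",
    "PotentiationSummary",
    "RecoveryCourse",
    "RecoveryFit",
    "GAS_CONSTANT",
    "DEFAULT_TEMPERATURE",
    "boltzmann",
    "fit_exponential",
    "fit_exponential_xy",
    "measure_tail",
    "build_gv",
    "fit_boltzmann",
    "delta_g",
    "prepulse_ddg",
    "fit_recovery_course",
]

GAS_CONSTANT = 8.314  # J mol^-1 K^-1
DEFAULT_TEMPERATURE = 295.0  # K, room-temperature recordings (22-24 C)


# ---------------------------------------------------------------------------
# Exponential fitting
# ---------------------------------------------------------------------------

@dataclass
class ExpFitResult:
    """Multi-exponential fit y(t) = offset + sum_i a_i * exp(-(t-t0)/tau_i).

    Components are canonically ordered tau1 <= tau2; ``t0`` is the start of
    the fit window so the parameterisation is translation invariant.
    """

    n_components: int
    amplitudes: tuple[float, ...]
    taus: tuple[float, ...]
    offset: float
    t0: float
    window: tuple[float, float]
    residual_norm: float
    degenerate: bool = False

    def value_at(self, t: float | np.ndarray) -> float | np.ndarray:
        """Evaluate the fitted model at absolute time ``t`` (extrapolates)."""
        dt = np.asarray(t) - self.t0
        out = self.offset + sum(
            a * np.exp(-dt / tau) for a, tau in zip(self.amplitudes, self.taus)
        )
        return float(out) if np.isscalar(t) else out


def _initial_tau_sets(span: float, n: int) -> list[tuple[float, ...]]:
    if n == 1:
        return [(span / 3,), (span / 10,), (span / 30,)]
    if n == 2:
        return [
            (span / 100, span / 3),
            (span / 300, span / 10),
            (span / 30, span / 2),
            (span / 1000, span / 20),
        ]
    return [
        (span / 1000, span / 30, span / 3),
        (span / 300, span / 30, span / 5),
        (span / 100, span / 10, span / 2),
    ]


def fit_exponential_xy(t: np.ndarray, y: np.ndarray, n: int = 1) -> ExpFitResult:
    """Least-squares exponential fit on raw (t, y) arrays.

    Initial time constants are seeded from log-spaced fractions of the window
    length; for each seed the offset and amplitudes are first solved linearly
    (the model is linear given the taus) and the best refined nonlinear fit
    is kept.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if n not in (1, 2, 3):
        raise InvalidInputError("n must be 1, 2 or 3")
    if t.size < 10:
        raise InvalidInputError(f"fit window too short: {t.size} samples (need >= 10)")
    t0 = float(t[0])
    ts = t - t0
    span = float(ts[-1])
    if span <= 0:
        raise InvalidInputError("fit window has zero duration")

    scale = float(np.ptp(y))
    if scale == 0.0:
        return ExpFitResult(
            n_components=n,
            amplitudes=(0.0,) * n,
            taus=(span / 3,) * n,
            offset=float(y[0]),
            t0=t0,
            window=(t0, float(t[-1])),
            residual_norm=0.0,
            degenerate=True,
        )

    def unpack(x):
        c = x[0]
        amps = x[1:1 + n]
        taus = np.exp(x[1 + n:])
        return c, amps, taus

    def resid(x):
        c, amps, taus = unpack(x)
        model = c + sum(a * np.exp(-ts / tau) for a, tau in zip(amps, taus))
        return model - y

    def jac(x):
        _, amps, taus = unpack(x)
        cols = [np.ones_like(ts)]
        cols += [np.exp(-ts / tau) for tau in taus]
        # d/d(log tau): a * exp(-t/tau) * (t/tau)
        cols += [
            a * np.exp(-ts / tau) * (ts / tau) for a, tau in zip(amps, taus)
        ]
        return np.column_stack(cols)

    best = None
    for taus0 in _initial_tau_sets(span, n):
        design = np.column_stack(
            [np.ones_like(ts)] + [np.exp(-ts / tau) for tau in taus0]
        )
        lin, *_ = np.linalg.lstsq(design, y, rcond=None)
        x0 = np.concatenate([lin, np.log(taus0)])
        try:
            res = least_squares(
                resid, x0, jac=jac, method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=600,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitError("exponential fit failed to converge")

    c, amps, taus = unpack(best.x)
    order = np.argsort(taus)
    amps = tuple(float(a) for a in np.asarray(amps)[order])
    taus = tuple(float(x) for x in np.asarray(taus)[order])
    degenerate = max(abs(a) for a in amps) < 1e-8 * max(scale, 1.0)
    return ExpFitResult(
        n_components=n,
        amplitudes=amps,
        taus=taus,
        offset=float(c),
        t0=t0,
        window=(t0, float(t[-1])),
        residual_norm=float(np.sqrt(2 * best.cost)),
        degenerate=degenerate,
    )


def fit_exponential(
    trace: CurrentTrace, window: tuple[float, float], n: int = 1
) -> ExpFitResult:
    """Fit ``n`` exponentials to a current trace over ``window`` (seconds)."""
    if n not in (1, 2):
        raise InvalidInputError("n must be 1 or 2")
    w0, w1 = window
    if w1 <= w0:
        raise InvalidInputError("fit window must have positive duration")
    mask = (trace.time >= w0 - 1e-12) & (trace.time <= w1 + 1e-12)
    if mask.sum() < 10:
        raise InvalidInputError("fit window contains fewer than 10 samples")
    return fit_exponential_xy(trace.time[mask], trace.current[mask], n=n)


# ---------------------------------------------------------------------------
# Tail currents and G-V curves
# ---------------------------------------------------------------------------

def measure_tail(
    trace: CurrentTrace,
    tail_start: float | None = None,
    fit_window: float = 0.06,
    n: int = 3,
    skip: int = 1,
) -> float:
    """Instantaneous tail-current amplitude at the tail-step onset.

    The first ``skip`` samples after the step are excluded (the capacitive-
    transient convention for real recordings), an ``n``-exponential is fitted
    over ``fit_window`` seconds of tail, and the fit is back-extrapolated to
    ``tail_start``.  The sign of the current is preserved.
    """
    if tail_start is None:
        tail_start = trace.meta.get("tail_start")
        if tail_start is None:
            raise InvalidInputError("tail_start not given and absent from metadata")
    sel = np.flatnonzero(trace.time >= tail_start - 1e-12)
    if sel.size <= skip + 10:
        raise InvalidInputError("no tail epoch after tail_start")
    sel = sel[skip:]
    t = trace.time[sel]
    y = trace.current[sel]
    keep = t <= tail_start + fit_window
    if keep.sum() >= 10:
        t, y = t[keep], y[keep]
    fit = fit_exponential_xy(t, y, n=n)
    return float(fit.value_at(tail_start))


@dataclass
class GVCurve:
    """Tail-current conductance-voltage data at a fixed tail voltage."""

    voltages: np.ndarray
    amplitudes: np.ndarray
    tail_voltage: float
    normalized: bool = False

    def __post_init__(self):
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.voltages.size != self.amplitudes.size:
            raise InvalidInputError("voltages and amplitudes differ in length")
        if np.any(np.diff(self.voltages) <= 0):
            raise InvalidInputError("voltages must be strictly increasing")

    def normalize(self) -> "GVCurve":
        m = np.abs(self.amplitudes).max()
        if m == 0:
            raise InvalidInputError("cannot normalize an all-zero G-V curve")
        return GVCurve(self.voltages, self.amplitudes / m, self.tail_voltage, True)


def build_gv(
    traces: list[CurrentTrace],
    normalize: bool = False,
    use_magnitude: bool = True,
    **tail_kwargs,
) -> GVCurve:
    """Build a G-V curve from a family of tail-current traces.

    Each trace must carry ``test_voltage``, ``tail_start`` and ``tail_voltage``
    metadata (as produced by :func:`elkvdp.gating.run_protocol_family`).
    """
    if not traces:
        raise InvalidInputError("empty trace family")
    tail_vs = {round(tr.meta.get("tail_voltage", np.nan), 6) for tr in traces}
    if len(tail_vs) != 1 or any(map(math.isnan, tail_vs)):
        raise InvalidInputError(f"inconsistent or missing tail voltages: {tail_vs}")
    pairs = []
    for tr in traces:
        amp = measure_tail(tr, tr.meta["tail_start"], **tail_kwargs)
        pairs.append((tr.meta["test_voltage"], amp))
    pairs.sort(key=lambda p: p[0])
    v = np.array([p[0] for p in pairs])
    a = np.array([p[1] for p in pairs])
    if use_magnitude:
        a = np.abs(a)
    gv = GVCurve(v, a, tail_voltage=tail_vs.pop())
    return gv.normalize() if normalize else gv


# ---------------------------------------------------------------------------
# Boltzmann fits and energetics
# ---------------------------------------------------------------------------

def boltzmann(v, i_min, i_max, v_half, v_slope):
    """I = Imin + (Imax - Imin) / (1 + exp[(V1/2 - V)/Vs])."""
    return i_min + (i_max - i_min) / (1.0 + np.exp((v_half - v) / v_slope))


@dataclass
class BoltzmannFit:
    """Sigmoid parameterisation of a G-V curve with standard errors."""

    i_min: float
    i_max: float
    v_half: float
    v_slope: float
    stderr: dict = field(default_factory=dict)
    extrapolated: bool = False
    reliable: bool = True

    def predict(self, v):
        return boltzmann(np.asarray(v, dtype=float), self.i_min, self.i_max,
                         self.v_half, self.v_slope)


def fit_boltzmann(gv: GVCurve) -> BoltzmannFit:
    """Least-squares Boltzmann fit of a G-V curve.

    A midpoint outside the sampled voltage range is flagged ``extrapolated``;
    more than 50 mV outside, the fit is flagged unreliable.
    """
    v, y = gv.voltages, gv.amplitudes
    if v.size < 5:
        raise InvalidInputError("need at least 5 G-V points to fit a Boltzmann")
    y_min, y_max = float(y.min()), float(y.max())
    half = 0.5 * (y_min + y_max)
    v0 = float(v[np.argmin(np.abs(y - half))])
    p0 = [y_min, y_max, v0, 10.0]
    lo = [-np.inf, -np.inf, -np.inf, 1e-3]
    hi = [np.inf, np.inf, np.inf, np.inf]
    try:
        popt, pcov = curve_fit(
            boltzmann, v, y, p0=p0, bounds=(lo, hi), maxfev=20000, xtol=1e-15,
            ftol=1e-15, gtol=1e-15,
        )
    except RuntimeError as exc:
        raise FitError(f"Boltzmann fit did not converge: {exc}") from exc
    perr = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    fit = BoltzmannFit(
        i_min=float(popt[0]), i_max=float(popt[1]),
        v_half=float(popt[2]), v_slope=float(popt[3]),
        stderr={k: float(e) for k, e in zip(("i_min", "i_max", "v_half", "v_slope"), perr)},
    )
    if not (v.min() <= fit.v_half <= v.max()):
        fit.extrapolated = True
        overshoot = max(v.min() - fit.v_half, fit.v_half - v.max())
        if overshoot > 50.0:
            fit.reliable = False
            warnings.warn(
                f"fitted V1/2 = {fit.v_half:.1f} mV lies {overshoot:.0f} mV outside "
                "the sampled range; fit flagged unreliable",
                UnreliableFitWarning,
            )
    return fit


@dataclass
class EnergyResult:
    """Gibbs free energy of activation at 0 mV from a Boltzmann fit."""

    delta_g: float  # J/mol
    temperature: float  # K
    gas_constant: float = GAS_CONSTANT


def delta_g(fit: BoltzmannFit, temperature: float = DEFAULT_TEMPERATURE) -> EnergyResult:
    """dG = R*T*V1/2/Vs (V1/2 and Vs in mV, ratio dimensionless)."""
    if fit.v_slope <= 0:
        raise InvalidInputError("slope factor Vs must be > 0")
    dg = GAS_CONSTANT * temperature * fit.v_half / fit.v_slope
    return EnergyResult(delta_g=float(dg), temperature=temperature)


@dataclass
class PotentiationSummary:
    """How much a depolarising prepulse potentiates the channel."""

    dv_half: float            # mV
    ddg_prepulse: float       # J/mol
    fold_change: float | None = None
    tau_deactivation_before: float | None = None  # s
    tau_deactivation_after: float | None = None   # s

    def __post_init__(self):
        if self.fold_change is not None and self.fold_change <= 0:
            raise InvalidInputError("fold change must be > 0")


def prepulse_ddg(
    before: BoltzmannFit,
    after: BoltzmannFit,
    temperature: float = DEFAULT_TEMPERATURE,
    fold_change: float | None = None,
    tau_before: float | None = None,
    tau_after: float | None = None,
) -> PotentiationSummary:
    """ddG(prepulse) = dG(after prepulse) - dG(before prepulse)."""
    dg_before = delta_g(before, temperature).delta_g
    dg_after = delta_g(after, temperature).delta_g
    return PotentiationSummary(
        dv_half=after.v_half - before.v_half,
        ddg_prepulse=dg_after - dg_before,
        fold_change=fold_change,
        tau_deactivation_before=tau_before,
        tau_deactivation_after=tau_after,
    )


# ---------------------------------------------------------------------------
# Recovery from potentiation
# ---------------------------------------------------------------------------

@dataclass
class RecoveryCourse:
    """An observable (V1/2 or peak tail amplitude) vs recovery-pulse duration."""

    durations: np.ndarray  # s, strictly increasing, >= 0
    values: np.ndarray
    kind: str = "v_half"   # "v_half" | "tail_amplitude"

    def __post_init__(self):
        self.durations = np.asarray(self.durations, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.durations.size == 0:
            raise InvalidInputError("recovery course is empty")
        if self.durations.size != self.values.size:
            raise InvalidInputError("durations and values differ in length")
        if self.durations.min() < 0 or np.any(np.diff(self.durations) <= 0):
            raise InvalidInputError("durations must be >= 0 and strictly increasing")


@dataclass
class RecoveryFit:
    """Single-exponential relaxation fitted to a recovery course."""

    tau: float       # s
    y0: float        # value at zero recovery time
    y_inf: float     # fully recovered value
    flagged: bool = False


def fit_recovery_course(course: RecoveryCourse) -> RecoveryFit:
    """Fit y(t) = y_inf + (y0 - y_inf) * exp(-t/tau) to a recovery course.

    A course that is non-monotone beyond what the fit residuals can explain
    is flagged rather than rejected.
    """
    t, y = course.durations, course.values
    if t.size < 4:
        raise InvalidInputError("need at least 4 recovery durations")
    span = float(t[-1] - t[0]) or 1.0

    def model(t, y_inf, dy, log_tau):
        return y_inf + dy * np.exp(-t / np.exp(log_tau))

    best = None
    for tau0 in (span / 10, span / 3, span):
        try:
            popt, _ = curve_fit(
                model, t, y, p0=[y[-1], y[0] - y[-1], np.log(tau0)],
                maxfev=20000, xtol=1e-13, ftol=1e-13,
            )
        except RuntimeError:
            continue
        cost = float(np.sum((model(t, *popt) - y) ** 2))
        if best is None or cost < best[0]:
            best = (cost, popt)
    if best is None:
        raise FitError("recovery-course fit did not converge")
    cost, popt = best
    y_inf, dy, log_tau = popt
    tau = float(np.exp(log_tau))
    resid = model(t, *popt) - y
    amp = abs(dy) if dy != 0 else max(abs(y).max(), 1.0)
    flagged = bool(np.abs(resid).max() > 0.5 * amp)
    return RecoveryFit(tau=tau, y0=float(y_inf + dy), y_inf=float(y_inf), flagged=flagged)
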