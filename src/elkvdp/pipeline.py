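"""End-to-end orchestration: scheme-level VDP summaries, recovery courses,
titration analysis and the reproducible full pipeline run."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .exceptions import ConfigError
from .ephys import (
    BoltzmannFit,
    PotentiationSummary,
    RecoveryCourse,
    build_gv,
    fit_boltzmann,
    fit_exponential,
    fit_recovery_course,
    measure_tail,
    prepulse_ddg,
)
from .gating import GatingScheme, run_protocol_family
from .protocols import duration_family, gv_family, recovery_protocol
from .schemes import load_scheme, vdp_six_state
from .synth import NoiseSpec, gen_titration
from .tmfret import fit_langmuir, forster_distance

log = logging.getLogger("elkvdp")

__all__ = [
    "RunConfig",
    "ResultBundle",
    "vdp_summary_from_scheme",
    "recovery_course_from_scheme",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# Scheme-level analyses
# ---------------------------------------------------------------------------

def vdp_summary_from_scheme(
    scheme: GatingScheme | None = None,
    temperature: float = 295.0,
    normalize: bool = False,
) -> tuple[PotentiationSummary, BoltzmannFit, BoltzmannFit]:
    """Full naive-vs-prepulse VDP comparison on a gating scheme.

    Simulates the naive and prepulsed tail G-V families and the
    variable-duration family, fits Boltzmanns, and summarises the prepulse
    shift, energetics, tail fold-change and deactivation slowing.
    """
    scheme = scheme or vdp_six_state()
    naive = run_protocol_family(scheme, gv_family(prepulse=False))
    prepulsed = run_protocol_family(scheme, gv_family(prepulse=True))
    gv_before = build_gv(naive, normalize=normalize)
    gv_after = build_gv(prepulsed, normalize=normalize)
    fit_before = fit_boltzmann(gv_before)
    fit_after = fit_boltzmann(gv_after)

    dur = run_protocol_family(scheme, duration_family())
    tails = [abs(measure_tail(tr, tr.meta["tail_start"])) for tr in dur]
    taus = []
    for tr in dur:
        t0 = tr.meta["tail_start"]
        fit = fit_exponential(tr, (t0 + 2e-4, t0 + 0.08), n=1)
        taus.append(fit.taus[0])
    summary = prepulse_ddg(
        fit_before,
        fit_after,
        temperature=temperature,
        fold_change=tails[-1] / tails[0],
        tau_before=taus[0],
        tau_after=taus[-1],
    )
    return summary, fit_before, fit_after


def recovery_course_from_scheme(
    scheme: GatingScheme | None = None,
    durations=(0.0, 0.025, 0.05, 0.1, 0.15, 0.2, 0.3, 0.5),
) -> tuple[RecoveryCourse, float]:
    """V1/2 vs recovery-pulse duration for a scheme, plus the fitted tau (s).

    For each hyperpolarising recovery duration after a potentiating prepulse
    the full tail G-V family is simulated and fitted; the relaxation of V1/2
    back to its naive value is then fitted with a single exponential.
    """
    scheme = scheme or vdp_six_state()
    v_halves = []
    for dur in durations:
        traces = run_protocol_family(scheme, recovery_protocol(dur))
        fit = fit_boltzmann(build_gv(traces))
        v_halves.append(fit.v_half)
    course = RecoveryCourse(np.asarray(durations), np.asarray(v_halves), kind="v_half")
    return course, fit_recovery_course(course).tau


# ---------------------------------------------------------------------------
# Run configuration and result bundle
# ---------------------------------------------------------------------------

class RunConfig(BaseModel):
    """Validated configuration for a full pipeline run (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    scheme_path: str | None = None
    seed: int = 1
    temperature_k: float = Field(295.0, gt=0)
    boltzmann_v_slope: float = Field(12.0, gt=0)
    r0_angstrom: float = Field(12.0, gt=0)
    efficiency_method: str = "corrected"
    fret_eff_max: float = Field(0.71, gt=0, lt=1)
    fret_k_half_uM: float = Field(66.1, gt=0)
    titration_noise_sigma: float = Field(0.03, ge=0)
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        try:
            return cls(**data)
        except ValidationError as exc:
            raise ConfigError(str(exc)) from exc

    def hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ResultBundle:
    """Per-stage results with provenance; serialises losslessly to JSON."""

    results: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    errors: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, default=float, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ResultBundle":
        d = json.loads(text)
        return cls(**d)

    @property
    def ok(self) -> bool:
        return not self.errors


def run_pipeline(config: RunConfig) -> ResultBundle:
    """Run every analysis stage deterministically under one config + seed."""
    bundle = ResultBundle(
        provenance={
            "config": config.model_dump(),
            "config_hash": config.hash(),
            "package_version": __version__,
            "seed": config.seed,
        }
    )

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            bundle.results[name] = fn()
        except Exception as exc:  # record and continue with later stages
            log.error("stage %s failed: %s", name, exc)
            bundle.errors[name] = f"{type(exc).__name__}: {exc}"
        finally:
            bundle.timings[name] = round(time.perf_counter() - t0, 3)
            log.info("stage %s finished in %.2fs", name, bundle.timings[name])

    scheme = load_scheme(config.scheme_path) if config.scheme_path else vdp_six_state()

    def _vdp():
        summary, before, after = vdp_summary_from_scheme(
            scheme, temperature=config.temperature_k
        )
        return {
            "potentiation_summary": asdict(summary),
            "boltzmann_naive": asdict(before),
            "boltzmann_prepulsed": asdict(after),
        }

    def _recovery():
        course, tau = recovery_course_from_scheme(scheme)
        return {
            "durations_s": course.durations.tolist(),
            "v_half_mV": course.values.tolist(),
            "tau_s": tau,
        }

    def _tmfret():
        noise = NoiseSpec("multiplicative-gaussian", config.titration_noise_sigma,
                          config.seed)
        test, control = gen_titration(
            eff_max=config.fret_eff_max, k_half_uM=config.fret_k_half_uM, noise=noise
        )
        fit = fit_langmuir(test, control, method=config.efficiency_method)
        dist = forster_distance(min(fit.eff_max, 1.0 - 1e-9), r0=config.r0_angstrom)
        return {"langmuir_fit": asdict(fit), "distance": asdict(dist)}

    stage("vdp_summary", _vdp)
    stage("recovery", _recovery)
    stage("tmfret", _tmfret)
    return bundle
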