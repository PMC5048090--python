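"""Lyapunov-spectrum estimation and attractor classification.

The spectrum is computed by the tangent-space (Benettin) method: a frame
of four perturbation vectors is co-evolved with the trajectory under the
analytic Jacobian and re-orthonormalized by Gram-Schmidt at a fixed
interval; each exponent is the time-averaged log stretch factor of one
frame vector.  The method is deterministic (origin start, identity
initial frame) — there is no perturbation size to tune.

An attractor is then classified from the signs of the exponents with an
explicit zero tolerance: all negative -> equilibrium; one zero ->
limit cycle; two zeros -> 2-torus; a positive leading exponent (plus the
obligatory zero along the flow) -> chaos.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _kernels
from .model import ActivationKind, ModelConfig
from .simulate import IntegrationSettings, IntegrationError, _KIND_CODE

__all__ = [
    "LyapunovSpectrum",
    "AttractorClass",
    "DEFAULT_SPECTRUM_SETTINGS",
    "lyapunov_spectrum",
    "isolated_population_spectrum",
    "classify",
    "classify_planar",
]

#: Default budget: 500 time units of transient, 4000 of averaging window.
#: The exponents of all reference parameter sets converge to two decimal
#: places at this budget within minutes on one CPU.
DEFAULT_SPECTRUM_SETTINGS = IntegrationSettings(
    step=0.01, t_end=4500.0, transient=500.0
)

#: |L| below this counts as a zero exponent when classifying.
DEFAULT_ZERO_TOL = 0.01


class AttractorClass(enum.Enum):
    EQUILIBRIUM = "equilibrium"
    LIMIT_CYCLE = "limit_cycle"
    TORUS_2D = "torus_2d"
    CHAOTIC = "chaotic"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class LyapunovSpectrum:
    """Exponents in descending order plus the settings that produced them.

    ``trace_average`` is the time-averaged Jacobian trace along the
    measurement window; for a consistent run it equals the exponent sum
    (phase-space volume contraction rate).
    """

    exponents: tuple  # (L1, L2, L3, L4) or (L1, L2) for a planar subsystem
    renorm_interval: float
    transient: float
    total_time: float
    step: float
    trace_average: Optional[float] = None

    def __post_init__(self) -> None:
        exps = tuple(float(v) for v in self.exponents)
        if any(exps[i] < exps[i + 1] for i in range(len(exps) - 1)):
            raise ValueError(f"exponents must be descending, got {exps}")
        object.__setattr__(self, "exponents", exps)

    @property
    def L1(self) -> float:
        return self.exponents[0]


def _window_steps(settings: IntegrationSettings, renorm_interval: float):
    if renorm_interval <= 0:
        raise ValueError("renorm_interval must be positive")
    renorm_every = int(round(renorm_interval / settings.step))
    if renorm_every < 1 or abs(renorm_every * settings.step - renorm_interval) > 1e-9:
        raise ValueError(
            f"renorm_interval {renorm_interval} is not a positive multiple "
            f"of the step {settings.step}"
        )
    n_transient = int(round(settings.transient / settings.step))
    n_window = settings.n_steps - n_transient
    if n_window < renorm_every:
        raise ValueError("averaging window shorter than one renorm interval")
    return n_transient, n_window, renorm_every


def lyapunov_spectrum(config: ModelConfig,
                      kind: ActivationKind = ActivationKind.NONLINEAR,
                      settings: Optional[IntegrationSettings] = None,
                      renorm_interval: float = 0.5) -> LyapunovSpectrum:
    """Estimate the full four-exponent spectrum along the attractor reached
    from ``settings.initial_state`` (default: the origin)."""
    if kind is ActivationKind.SATURATING:
        raise ValueError("spectrum needs a differentiable activation")
    settings = settings or DEFAULT_SPECTRUM_SETTINGS
    n_transient, n_window, renorm_every = _window_steps(settings, renorm_interval)
    exps, mean_trace, final_state, blowup = _kernels.lyapunov_benettin(
        config.to_array(), _KIND_CODE[kind],
        np.array(settings.initial_state), settings.step,
        n_transient, n_window, renorm_every,
    )
    if blowup:
        raise IntegrationError(float("nan"), final_state)
    return LyapunovSpectrum(
        exponents=tuple(exps),
        renorm_interval=renorm_interval,
        transient=settings.transient,
        total_time=settings.t_end,
        step=settings.step,
        trace_average=float(mean_trace),
    )


def isolated_population_spectrum(config: ModelConfig, population: int = 1,
                                 kind: ActivationKind = ActivationKind.NONLINEAR,
                                 settings: Optional[IntegrationSettings] = None,
                                 renorm_interval: float = 0.5) -> LyapunovSpectrum:
    """Two-exponent spectrum of one population's planar subsystem.

    Only valid when all couplings are zero, in which case the 4-D flow is a
    product of two independent planar flows and the product spectrum mixes
    the factors' exponents (e.g. two independent cycles contribute two
    zeros, mimicking a torus signature).  Classifying each factor
    separately recovers the per-population attractor.
    """
    if not config.coupling.is_isolated:
        raise ValueError("planar subsystem spectrum requires zero couplings")
    if population not in (1, 2):
        raise ValueError("population must be 1 or 2")
    if kind is ActivationKind.SATURATING:
        raise ValueError("spectrum needs a differentiable activation")
    settings = settings or DEFAULT_SPECTRUM_SETTINGS
    n_transient, n_window, renorm_every = _window_steps(settings, renorm_interval)
    p, s = config.population, config.stimulus
    I, J = (s.I1, s.J1) if population == 1 else (s.I2, s.J2)
    pp = np.array([p.a, p.b, p.c, p.d, p.e, p.w, I, J])
    init = settings.initial_state
    y0 = np.array(init[0:2] if population == 1 else init[2:4])
    exps, final_state, blowup = _kernels.lyapunov_benettin_2d(
        pp, _KIND_CODE[kind], y0, settings.step,
        n_transient, n_window, renorm_every,
    )
    if blowup:
        raise IntegrationError(float("nan"), final_state)
    return LyapunovSpectrum(
        exponents=tuple(exps),
        renorm_interval=renorm_interval,
        transient=settings.transient,
        total_time=settings.t_end,
        step=settings.step,
    )


def classify(spectrum: LyapunovSpectrum,
             zero_tol: float = DEFAULT_ZERO_TOL) -> AttractorClass:
    """Attractor category from the signs of the four exponents.

    With |L| < zero_tol treated as zero:
    (-,-,-,-) equilibrium; (0,-,-,-) limit cycle; (0,0,-,-) 2-torus;
    (+,0,-,-) chaotic; anything else unclassified.
    """
    if zero_tol <= 0:
        raise ValueError("zero_tol must be positive")
    L = spectrum.exponents
    if len(L) != 4:
        raise ValueError("full classification needs a 4-exponent spectrum")
    zero = [abs(v) < zero_tol for v in L]
    neg = [v <= -zero_tol for v in L]
    pos = [v >= zero_tol for v in L]
    if all(neg):
        return AttractorClass.EQUILIBRIUM
    if zero[0] and neg[1] and neg[2] and neg[3]:
        return AttractorClass.LIMIT_CYCLE
    if zero[0] and zero[1] and neg[2] and neg[3]:
        return AttractorClass.TORUS_2D
    if pos[0] and zero[1] and neg[2] and neg[3]:
        return AttractorClass.CHAOTIC
    return AttractorClass.UNCLASSIFIED


def classify_planar(spectrum: LyapunovSpectrum,
                    zero_tol: float = DEFAULT_ZERO_TOL) -> AttractorClass:
    """Attractor category for a planar (single-population) spectrum.

    A planar autonomous flow admits only equilibria and limit cycles
    (Poincare-Bendixson): (-,-) equilibrium; (0,-) limit cycle.
    """
    if zero_tol <= 0:
        raise ValueError("zero_tol must be positive")
    L = spectrum.exponents
    if len(L) != 2:
        raise ValueError("planar classification needs a 2-exponent spectrum")
    if L[0] <= -zero_tol and L[1] <= -zero_tol:
        return AttractorClass.EQUILIBRIUM
    if abs(L[0]) < zero_tol and L[1] <= -zero_tol:
        return AttractorClass.LIMIT_CYCLE
    return AttractorClass.UNCLASSIFIED
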