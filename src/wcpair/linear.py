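"""Closed-form analysis of the model under the small-signal approximation.

With ``S(z) ~ z`` the coupled system becomes affine, ``ds/dt = A s + u``
with ``u = (I1, J1, I2, J2)``, and admits exactly one equilibrium when
``A`` is nonsingular.  This module provides that equilibrium, the
coefficients of the quartic characteristic polynomial of ``A``, the
Routh-Hurwitz stability table, the critical parameter values at which the
equilibrium loses stability, and the Hopf-bifurcation frequency/period for
symmetric coupling.

Shorthand used throughout (and in the report JSON):

    W = w - a      effective excitatory gain
    E = d + e      effective inhibitory decay
    M = b*c - E*W
    P_i = E*alpha_i - b*beta_i
    Q_i = E*I_i - b*J_i

The unique equilibrium has ``x1* = (M Q1 + P1 Q2) / (M^2 - P1 P2)`` (and
symmetrically for ``x2*``); the denominator equals ``det A = gamma4``.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import bisect

from .model import ActivationKind, ModelConfig, jacobian, STATE_DIM

__all__ = [
    "LinearSummary",
    "Equilibrium",
    "CharPolyCoeffs",
    "RouthHurwitz",
    "HopfInfo",
    "CriticalValues",
    "SingularEquilibriumError",
    "MarginalStabilityError",
    "linear_summary",
    "equilibrium",
    "char_poly_coeffs",
    "routh_hurwitz",
    "eigenvalues",
    "critical_values",
    "hopf_info",
    "find_critical_beta",
    "analysis_report",
]

#: |value| below this is treated as "on a stability boundary" rather than
#: given a sign; Hopf boundaries are measure-zero and must not be silently
#: classified.
MARGINAL_TOL = 1e-9


class SingularEquilibriumError(ValueError):
    """The linearized system has no unique equilibrium (singular matrix)."""


class MarginalStabilityError(ValueError):
    """A Routh-Hurwitz quantity sits on a boundary; verdict undecided."""


@dataclass(frozen=True)
class LinearSummary:
    """Composite quantities of the linearized model (pure function of config)."""

    W: float
    E: float
    M: float
    P1: float
    P2: float
    Q1: float
    Q2: float


def linear_summary(config: ModelConfig) -> LinearSummary:
    p, k, s = config.population, config.coupling, config.stimulus
    W = p.w - p.a
    E = p.d + p.e
    return LinearSummary(
        W=W,
        E=E,
        M=p.b * p.c - E * W,
        P1=E * k.alpha1 - p.b * k.beta1,
        P2=E * k.alpha2 - p.b * k.beta2,
        Q1=E * s.I1 - p.b * s.J1,
        Q2=E * s.I2 - p.b * s.J2,
    )


@dataclass(frozen=True)
class Equilibrium:
    """The unique fixed point of the linearized system."""

    state: np.ndarray  # (x1*, y1*, x2*, y2*)
    denominator: float  # M^2 - P1 P2 = det(A) = gamma4

    @property
    def x1(self) -> float:
        return float(self.state[0])

    @property
    def y1(self) -> float:
        return float(self.state[1])

    @property
    def x2(self) -> float:
        return float(self.state[2])

    @property
    def y2(self) -> float:
        return float(self.state[3])


def _linear_matrix(config: ModelConfig) -> np.ndarray:
    return jacobian(np.zeros(STATE_DIM), config, ActivationKind.LINEAR)


def equilibrium(config: ModelConfig) -> Equilibrium:
    """Solve ``A s + u = 0`` for the unique linear-model fixed point.

    Raises :class:`SingularEquilibriumError` when the denominator
    ``M^2 - P1 P2`` vanishes (degenerate parameter combination).
    """
    ls = linear_summary(config)
    den = ls.M * ls.M - ls.P1 * ls.P2
    scale = max(1.0, ls.M * ls.M, abs(ls.P1 * ls.P2))
    if abs(den) <= 1e-12 * scale:
        raise SingularEquilibriumError(
            f"M^2 - P1*P2 = {den:g} is numerically singular; "
            "the linear model has no unique equilibrium"
        )
    s = config.stimulus
    u = np.array([s.I1, s.J1, s.I2, s.J2])
    state = np.linalg.solve(_linear_matrix(config), -u)
    return Equilibrium(state=state, denominator=den)


def _closed_form_state(config: ModelConfig) -> np.ndarray:
    """Documentation-form equilibrium, used as an internal cross-check.

    ``x1* = (M Q1 + P1 Q2)/(M^2 - P1 P2)``, symmetric for ``x2*``; the
    inhibitory coordinates follow from their own stationarity,
    ``E y_i* = c x_i* + beta_i x_j* + J_i``.
    """
    ls = linear_summary(config)
    k, s = config.coupling, config.stimulus
    c = config.population.c
    den = ls.M * ls.M - ls.P1 * ls.P2
    x1 = (ls.M * ls.Q1 + ls.P1 * ls.Q2) / den
    x2 = (ls.M * ls.Q2 + ls.P2 * ls.Q1) / den
    y1 = (c * x1 + k.beta1 * x2 + s.J1) / ls.E
    y2 = (c * x2 + k.beta2 * x1 + s.J2) / ls.E
    return np.array([x1, y1, x2, y2])


@dataclass(frozen=True)
class CharPolyCoeffs:
    """Coefficients of ``lambda^4 + g1 l^3 + g2 l^2 + g3 l + g4``."""

    gamma1: float
    gamma2: float
    gamma3: float
    gamma4: float

    def as_poly(self) -> np.ndarray:
        return np.array([1.0, self.gamma1, self.gamma2, self.gamma3, self.gamma4])


def char_poly_coeffs(config: ModelConfig) -> CharPolyCoeffs:
    """Closed-form characteristic-polynomial coefficients of the linear system.

    gamma1 = 2(E - W)
    gamma2 = (E - W)^2 + 2M - a1 a2
    gamma3 = 2(E - W) M + b (a1 b2 + a2 b1) - 2 E a1 a2
    gamma4 = M^2 + b E (a1 b2 + a2 b1) - b^2 b1 b2 - E^2 a1 a2

    with ``M = bc - EW`` and (a_i, b_i) the alpha/beta couplings.
    """
    ls = linear_summary(config)
    k = config.coupling
    b = config.population.b
    D = ls.E - ls.W
    cross = k.alpha1 * k.beta2 + k.alpha2 * k.beta1
    aa = k.alpha1 * k.alpha2
    return CharPolyCoeffs(
        gamma1=2.0 * D,
        gamma2=D * D + 2.0 * ls.M - aa,
        gamma3=2.0 * D * ls.M + b * cross - 2.0 * ls.E * aa,
        gamma4=ls.M * ls.M + b * ls.E * cross
        - b * b * k.beta1 * k.beta2 - ls.E * ls.E * aa,
    )


@dataclass(frozen=True)
class RouthHurwitz:
    """Routh-Hurwitz table for the quartic: verdict and the six conditions.

    ``stable`` is True iff gamma1..4, delta1 and delta2 are all strictly
    positive, which is equivalent to every eigenvalue having negative real
    part.
    """

    delta1: float
    delta2: float
    conditions: tuple  # (g1>0, g2>0, g3>0, g4>0, d1>0, d2>0)
    stable: bool
    marginal: bool  # some quantity within MARGINAL_TOL of zero


def routh_hurwitz(coeffs: CharPolyCoeffs) -> RouthHurwitz:
    """Evaluate the stability table ``delta1 = (g1 g2 - g3)/g1``,
    ``delta2 = (d1 g3 - g1 g4)/d1`` and the six positivity conditions."""
    g1, g2, g3, g4 = coeffs.gamma1, coeffs.gamma2, coeffs.gamma3, coeffs.gamma4
    if g1 == 0.0:
        raise MarginalStabilityError("gamma1 = 0: Routh table degenerate")
    d1 = (g1 * g2 - g3) / g1
    if d1 == 0.0:
        raise MarginalStabilityError("delta1 = 0: Routh table degenerate")
    d2 = (d1 * g3 - g1 * g4) / d1
    values = (g1, g2, g3, g4, d1, d2)
    conditions = tuple(v > 0.0 for v in values)
    marginal = any(abs(v) < MARGINAL_TOL for v in values)
    return RouthHurwitz(
        delta1=d1,
        delta2=d2,
        conditions=conditions,
        stable=all(conditions),
        marginal=marginal,
    )


def eigenvalues(config: ModelConfig) -> np.ndarray:
    """Eigenvalues of the linear-model matrix, sorted by descending real
    part, then descending imaginary part (dense eigensolver, not quartic
    root formulas)."""
    lam = np.linalg.eigvals(_linear_matrix(config))
    order = np.lexsort((-lam.imag, -lam.real))
    return lam[order]


@dataclass(frozen=True)
class CriticalValues:
    """Destabilization thresholds of the linearized model.

    w_c = a + d + e : the equilibrium can only be stable for w < w_c.
    e_c = w - (a + d) : equivalently, only for e > e_c.
    alpha_c = a + d + e - w : symmetric-coupling threshold (may be
        negative, meaning the instability already holds at alpha = 0).
    beta_c : optional numerically located delta2 = 0 root in a beta
        parameter (see :func:`find_critical_beta`).
    """

    w_c: float
    e_c: float
    alpha_c: float
    beta_c: Optional[float] = None


def critical_values(config: ModelConfig) -> CriticalValues:
    p = config.population
    return CriticalValues(
        w_c=p.a + p.d + p.e,
        e_c=p.w - (p.a + p.d),
        alpha_c=p.a + p.d + p.e - p.w,
    )


@dataclass(frozen=True)
class HopfInfo:
    """Hopf-bifurcation quantities for symmetric coupling (alpha1 = alpha2,
    beta1 = beta2).

    epsilon1 = (w + alpha) - (a + d + e): the delta2 = 0 condition.
    epsilon2 = b (c + beta) - (w + alpha - a)(d + e): squared angular
        frequency of the newborn cycle.
    period ~= 2 pi / sqrt(epsilon2) when epsilon2 > 0, else None.
    """

    epsilon1: float
    epsilon2: float
    period: Optional[float]


def hopf_info(config: ModelConfig) -> HopfInfo:
    k = config.coupling
    if not k.is_symmetric:
        raise ValueError(
            "Hopf closed form requires symmetric coupling "
            f"(alpha1={k.alpha1}, alpha2={k.alpha2}, "
            f"beta1={k.beta1}, beta2={k.beta2})"
        )
    p = config.population
    alpha, beta = k.alpha1, k.beta1
    eps1 = (p.w + alpha) - (p.a + p.d + p.e)
    eps2 = p.b * (p.c + beta) - (p.w + alpha - p.a) * (p.d + p.e)
    period = 2.0 * math.pi / math.sqrt(eps2) if eps2 > 0 else None
    return HopfInfo(epsilon1=eps1, epsilon2=eps2, period=period)


def find_critical_beta(config: ModelConfig, which: str = "beta2",
                       bracket: tuple = (0.0, 5.0)) -> float:
    """Locate the ``delta2 = 0`` crossing in one beta coupling by bisection.

    ``which`` selects ``beta1`` or ``beta2``; the other parameters are held
    at their config values.  The bracket endpoints must give delta2 values
    of opposite sign.  Root located to absolute tolerance 1e-6.
    """
    if which not in ("beta1", "beta2"):
        raise ValueError(f"which must be 'beta1' or 'beta2', got {which!r}")

    def delta2_of(beta: float) -> float:
        cfg = config.replace(**{which: float(beta)})
        return routh_hurwitz(char_poly_coeffs(cfg)).delta2

    lo, hi = float(bracket[0]), float(bracket[1])
    f_lo, f_hi = delta2_of(lo), delta2_of(hi)
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if f_lo * f_hi > 0:
        raise ValueError(
            f"delta2 does not change sign on [{lo}, {hi}]: "
            f"delta2({lo}) = {f_lo:g}, delta2({hi}) = {f_hi:g}"
        )
    return float(bisect(delta2_of, lo, hi, xtol=1e-6))


def analysis_report(config: ModelConfig) -> dict:
    """Full linear-analysis report as a JSON-serializable dict."""
    coeffs = char_poly_coeffs(config)
    rh = routh_hurwitz(coeffs)
    lam = eigenvalues(config)
    crit = critical_values(config)
    report = {
        "config": config.to_dict(),
        "gamma": [coeffs.gamma1, coeffs.gamma2, coeffs.gamma3, coeffs.gamma4],
        "delta1": rh.delta1,
        "delta2": rh.delta2,
        "conditions": list(rh.conditions),
        "stable": rh.stable,
        "marginal": rh.marginal,
        "eigenvalues": [{"re": z.real, "im": z.imag} for z in lam],
        "critical_values": {
            "w_c": crit.w_c, "e_c": crit.e_c, "alpha_c": crit.alpha_c,
        },
    }
    try:
        eq = equilibrium(config)
        report["equilibrium"] = list(eq.state)
        report["equilibrium_denominator"] = eq.denominator
    except SingularEquilibriumError as exc:
        report["equilibrium"] = None
        report["equilibrium_error"] = str(exc)
    if config.coupling.is_symmetric:
        h = hopf_info(config)
        report["hopf"] = {
            "epsilon1": h.epsilon1, "epsilon2": h.epsilon2, "period": h.period,
        }
    else:
        report["hopf"] = None
    return report
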