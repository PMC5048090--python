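"""Model definition for a pair of coupled Wilson-Cowan neuronal populations.

Each population consists of an excitatory group (activity ``x_i``) and an
inhibitory group (activity ``y_i``), obeying first-order rate equations of
the form ``dg/dt = -decay * g + S(input)``, where ``S`` is a sigmoidal
input-output function and the input is a linear combination of group
activities plus a constant external stimulus.  The two populations share
identical intrinsic parameters and are coupled through links originating
from their excitatory groups (strengths ``alpha_i`` into the other
population's excitatory group, ``beta_i`` into its inhibitory group).

The refractory term of the original Wilson-Cowan formulation is taken to be
zero throughout.

State ordering is fixed as ``(x1, y1, x2, y2)``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ActivationKind",
    "PopulationParams",
    "CouplingParams",
    "StimulusParams",
    "ModelConfig",
    "sigmoid",
    "sigmoid_derivative",
    "rhs",
    "jacobian",
]

#: Number of state variables (x1, y1, x2, y2).
STATE_DIM = 4

#: Flat serialization key order for the 14 model parameters.
PARAM_KEYS = (
    "a", "b", "c", "d", "e", "w",
    "alpha1", "alpha2", "beta1", "beta2",
    "I1", "I2", "J1", "J2",
)


class ActivationKind(enum.Enum):
    """Input-output nonlinearity selector.

    NONLINEAR is the model proper: ``S(z) = z / sqrt(1 + z^2)``, a bounded,
    odd sigmoid with unit slope at the origin.  LINEAR (``S(z) = z``) is the
    small-signal approximation used for closed-form analysis.  SATURATING
    (``S(z) = sign(z)``) is the large-input limit ``|S(z)| -> 1``; it is
    provided for the saturation-regime discussion only and has no derivative.
    """

    NONLINEAR = "nonlinear"
    LINEAR = "linear"
    SATURATING = "saturating"


def _check_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class PopulationParams:
    """Intrinsic parameters shared by both (identical) populations.

    a, d : exponential decay rates of excitatory / inhibitory activity.
    b : inhibitory -> excitatory connection strength (y_i to x_i).
    c : excitatory -> inhibitory connection strength (x_i to y_i).
    w : excitatory self-connection strength (x_i to x_i).
    e : inhibitory self-connection strength (y_i to y_i).

    All six are strictly positive.
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    w: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d", "e", "w"):
            value = _check_finite(name, getattr(self, name))
            if value <= 0:
                raise ValueError(f"population parameter {name} must be > 0, got {value}")
            object.__setattr__(self, name, value)


@dataclass(frozen=True)
class CouplingParams:
    """Inter-population connection strengths, all from excitatory groups.

    alpha1 : x2 -> x1,  alpha2 : x1 -> x2,
    beta1  : x2 -> y1,  beta2  : x1 -> y2.

    Non-negative; all zero means the populations are isolated.
    """

    alpha1: float = 0.0
    alpha2: float = 0.0
    beta1: float = 0.0
    beta2: float = 0.0

    def __post_init__(self) -> None:
        for name in ("alpha1", "alpha2", "beta1", "beta2"):
            value = _check_finite(name, getattr(self, name))
            if value < 0:
                raise ValueError(f"coupling parameter {name} must be >= 0, got {value}")
            object.__setattr__(self, name, value)

    @property
    def is_isolated(self) -> bool:
        return self.alpha1 == self.alpha2 == self.beta1 == self.beta2 == 0.0

    @property
    def is_symmetric(self) -> bool:
        return (
            abs(self.alpha1 - self.alpha2) <= 1e-12
            and abs(self.beta1 - self.beta2) <= 1e-12
        )


@dataclass(frozen=True)
class StimulusParams:
    """Constant external inputs: I_i to excitatory, J_i to inhibitory groups."""

    I1: float = 0.0
    I2: float = 0.0
    J1: float = 0.0
    J2: float = 0.0

    def __post_init__(self) -> None:
        for name in ("I1", "I2", "J1", "J2"):
            object.__setattr__(self, name, _check_finite(name, getattr(self, name)))


@dataclass(frozen=True)
class ModelConfig:
    """The full 14-parameter configuration of the two-population model."""

    population: PopulationParams
    coupling: CouplingParams
    stimulus: StimulusParams

    @classmethod
    def from_dict(cls, flat: dict) -> "ModelConfig":
        """Build from a flat mapping with keys ``a..w, alpha*, beta*, I*, J*``."""
        missing = [k for k in PARAM_KEYS if k not in flat]
        if missing:
            raise KeyError(f"missing model parameter(s): {', '.join(missing)}")
        vals = {}
        for key in PARAM_KEYS:
            v = flat[key]
            if isinstance(v, bool) or not isinstance(v, (int, float)):
                raise TypeError(f"model parameter {key} must be numeric, got {v!r}")
            vals[key] = float(v)
        return cls(
            population=PopulationParams(
                a=vals["a"], b=vals["b"], c=vals["c"],
                d=vals["d"], e=vals["e"], w=vals["w"],
            ),
            coupling=CouplingParams(
                alpha1=vals["alpha1"], alpha2=vals["alpha2"],
                beta1=vals["beta1"], beta2=vals["beta2"],
            ),
            stimulus=StimulusParams(
                I1=vals["I1"], I2=vals["I2"], J1=vals["J1"], J2=vals["J2"],
            ),
        )

    def to_dict(self) -> dict:
        """Flat mapping inverse of :meth:`from_dict`."""
        p, k, s = self.population, self.coupling, self.stimulus
        return {
            "a": p.a, "b": p.b, "c": p.c, "d": p.d, "e": p.e, "w": p.w,
            "alpha1": k.alpha1, "alpha2": k.alpha2,
            "beta1": k.beta1, "beta2": k.beta2,
            "I1": s.I1, "I2": s.I2, "J1": s.J1, "J2": s.J2,
        }

    def to_array(self) -> np.ndarray:
        """The 14 parameters as a float array in :data:`PARAM_KEYS` order."""
        d = self.to_dict()
        return np.array([d[k] for k in PARAM_KEYS], dtype=float)

    def replace(self, **flat_updates: float) -> "ModelConfig":
        """Return a copy with flat-key overrides applied."""
        d = self.to_dict()
        unknown = set(flat_updates) - set(PARAM_KEYS)
        if unknown:
            raise KeyError(f"unknown model parameter(s): {', '.join(sorted(unknown))}")
        d.update(flat_updates)
        return ModelConfig.from_dict(d)


def _as_state(state) -> np.ndarray:
    arr = np.asarray(state, dtype=float)
    if arr.shape != (STATE_DIM,):
        raise ValueError(f"state must have shape ({STATE_DIM},), got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("state contains non-finite values")
    return arr


def sigmoid(z, kind: ActivationKind = ActivationKind.NONLINEAR):
    """Evaluate the activation function ``S(z)`` (scalar or array).

    NONLINEAR: ``z / sqrt(1 + z^2)``, odd, strictly increasing, in (-1, 1).
    LINEAR: identity. SATURATING: ``sign(z)`` (0 at z = 0).
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("sigmoid input must be finite")
    if kind is ActivationKind.NONLINEAR:
        out = z / np.sqrt(1.0 + z * z)
    elif kind is ActivationKind.LINEAR:
        out = z.copy()
    elif kind is ActivationKind.SATURATING:
        out = np.sign(z)
    else:  # pragma: no cover
        raise ValueError(f"unknown activation kind {kind!r}")
    return out.item() if out.ndim == 0 else out


def sigmoid_derivative(z, kind: ActivationKind = ActivationKind.NONLINEAR):
    """Evaluate ``S'(z)``: ``(1 + z^2)^(-3/2)`` for NONLINEAR, 1 for LINEAR.

    SATURATING has no usable derivative (zero a.e., undefined at the kink)
    and is rejected.
    """
    if kind is ActivationKind.SATURATING:
        raise ValueError("SATURATING activation has no derivative")
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("sigmoid_derivative input must be finite")
    if kind is ActivationKind.NONLINEAR:
        out = (1.0 + z * z) ** -1.5
    else:
        out = np.ones_like(z)
    return out.item() if out.ndim == 0 else out


def _inputs(state: np.ndarray, config: ModelConfig) -> np.ndarray:
    """The four sigmoid arguments z1..z4, one per rate equation."""
    x1, y1, x2, y2 = state
    p, k, s = config.population, config.coupling, config.stimulus
    return np.array([
        p.w * x1 - p.b * y1 + k.alpha1 * x2 + s.I1,
        p.c * x1 - p.e * y1 + k.beta1 * x2 + s.J1,
        p.w * x2 - p.b * y2 + k.alpha2 * x1 + s.I2,
        p.c * x2 - p.e * y2 + k.beta2 * x1 + s.J2,
    ])


def rhs(state, config: ModelConfig,
        kind: ActivationKind = ActivationKind.NONLINEAR) -> np.ndarray:
    """Time derivatives ``(dx1, dy1, dx2, dy2)/dt`` of the coupled system.

    Each equation has the form ``-decay * activity + S(input)`` with decay
    ``a`` for excitatory and ``d`` for inhibitory groups.
    """
    state = _as_state(state)
    p = config.population
    decay = np.array([p.a, p.d, p.a, p.d])
    return -decay * state + sigmoid(_inputs(state, config), kind)


def jacobian(state, config: ModelConfig,
             kind: ActivationKind = ActivationKind.NONLINEAR) -> np.ndarray:
    """Analytic Jacobian ``d(rhs)/d(state)`` (4x4).

    Row i is ``S'(z_i) * (gradient of z_i) - decay_i * e_i``.  For LINEAR
    activation the matrix is state-independent.
    """
    if kind is ActivationKind.SATURATING:
        raise ValueError("Jacobian undefined for SATURATING activation")
    state = _as_state(state)
    p, k = config.population, config.coupling
    sp = sigmoid_derivative(_inputs(state, config), kind)
    J = np.array([
        [p.w, -p.b, k.alpha1, 0.0],
        [p.c, -p.e, k.beta1, 0.0],
        [k.alpha2, 0.0, p.w, -p.b],
        [k.beta2, 0.0, p.c, -p.e],
    ])
    J *= sp[:, None]
    J[np.diag_indices(4)] -= np.array([p.a, p.d, p.a, p.d])
    return J
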