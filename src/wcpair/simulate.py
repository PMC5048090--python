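"""Fixed-step RK4 integration, steady-state detection, period measurement.

The integration contract deliberately preserves the plain classical
Runge-Kutta scheme with a fixed step (default 0.01) from the origin: runs
are bit-reproducible and no adaptive machinery is involved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import _kernels
from .model import ActivationKind, ModelConfig, STATE_DIM

__all__ = [
    "IntegrationSettings",
    "Trajectory",
    "IntegrationError",
    "integrate",
    "steady_state",
    "measure_period",
    "measure_period_spectral",
]

_KIND_CODE = {
    ActivationKind.NONLINEAR: _kernels.KIND_NONLINEAR,
    ActivationKind.LINEAR: _kernels.KIND_LINEAR,
    ActivationKind.SATURATING: _kernels.KIND_SATURATING,
}

CSV_COLUMNS = ("t", "x1", "y1", "x2", "y2")


class IntegrationError(RuntimeError):
    """Trajectory blew up (|state| > 1e6 or non-finite)."""

    def __init__(self, time: float, state) -> None:
        self.time = time
        self.state = np.asarray(state)
        super().__init__(
            f"trajectory diverged at t = {time:g} (state = {self.state})"
        )


@dataclass(frozen=True)
class IntegrationSettings:
    """Integration contract: step size, horizon, measurement transient.

    ``transient`` is the initial time span discarded before steady-state /
    period / spectrum measurements; it defaults to half of ``t_end``.
    """

    step: float = 0.01
    t_end: float = 2000.0
    transient: Optional[float] = None
    initial_state: tuple = (0.0, 0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not (self.step > 0 and math.isfinite(self.step)):
            raise ValueError(f"step must be positive, got {self.step}")
        if not (self.t_end > 0 and math.isfinite(self.t_end)):
            raise ValueError(f"t_end must be positive, got {self.t_end}")
        tr = self.t_end / 2.0 if self.transient is None else float(self.transient)
        if not (0 <= tr < self.t_end):
            raise ValueError(f"transient must lie in [0, t_end), got {tr}")
        object.__setattr__(self, "transient", tr)
        init = tuple(float(v) for v in self.initial_state)
        if len(init) != STATE_DIM or not all(math.isfinite(v) for v in init):
            raise ValueError(f"initial_state must be 4 finite values, got {init}")
        object.__setattr__(self, "initial_state", init)

    @property
    def n_steps(self) -> int:
        return int(round(self.t_end / self.step))


@dataclass(frozen=True)
class Trajectory:
    """Uniform time grid and the state time series on it."""

    times: np.ndarray  # (n,)
    states: np.ndarray  # (n, 4), columns (x1, y1, x2, y2)

    def __post_init__(self) -> None:
        if len(self.times) != len(self.states):
            raise ValueError("times and states must have equal length")

    @property
    def step(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def x1(self) -> np.ndarray:
        return self.states[:, 0]

    def tail(self, t_from: float) -> "Trajectory":
        """Sub-trajectory with times >= t_from (measurement window)."""
        mask = self.times >= t_from
        return Trajectory(times=self.times[mask], states=self.states[mask])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.times, "x1": self.states[:, 0], "y1": self.states[:, 1],
             "x2": self.states[:, 2], "y2": self.states[:, 3]}
        )

    def to_csv(self, path) -> None:
        # 17 significant digits: float64 round-trip is lossless
        self.to_frame().to_csv(path, index=False, float_format="%.17g",
                               lineterminator="\n")

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path, float_precision="round_trip")
        missing = set(CSV_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"trajectory CSV missing column(s): {sorted(missing)}")
        return cls(times=df["t"].to_numpy(),
                   states=df[["x1", "y1", "x2", "y2"]].to_numpy())


def integrate(config: ModelConfig,
              kind: ActivationKind = ActivationKind.NONLINEAR,
              settings: Optional[IntegrationSettings] = None) -> Trajectory:
    """Integrate the coupled system with classical fixed-step RK4.

    Deterministic: identical inputs give bit-identical trajectories.
    Raises :class:`IntegrationError` with the divergence time if the state
    leaves |state| <= 1e6 (the linear activation is genuinely unstable in
    several parameter regimes).
    """
    settings = settings or IntegrationSettings()
    y0 = np.array(settings.initial_state, dtype=float)
    states, blowup = _kernels.integrate_rk4(
        config.to_array(), _KIND_CODE[kind], y0, settings.step, settings.n_steps
    )
    times = settings.step * np.arange(settings.n_steps + 1)
    if blowup >= 0:
        raise IntegrationError(times[blowup], states[blowup - 1])
    return Trajectory(times=times, states=states)


def steady_state(traj: Trajectory, tol: float = 1e-6) -> Optional[np.ndarray]:
    """Tail mean if the trajectory has settled, else None.

    The caller passes the measurement window (transient already removed).
    "Settled" means every coordinate's peak-to-peak range over the window
    is below ``tol``.
    """
    if len(traj.times) == 0:
        raise ValueError("empty trajectory tail")
    ptp = traj.states.max(axis=0) - traj.states.min(axis=0)
    if np.all(ptp == 0.0):  # exactly constant
        return traj.states[0].copy()
    if np.all(ptp < tol):
        return traj.states.mean(axis=0)
    return None


def _upward_crossings(times: np.ndarray, signal: np.ndarray) -> np.ndarray:
    """Times of upward zero crossings, linearly interpolated between samples."""
    s0, s1 = signal[:-1], signal[1:]
    idx = np.nonzero((s0 < 0) & (s1 >= 0))[0]
    frac = -s0[idx] / (s1[idx] - s0[idx])
    return times[idx] + frac * (times[idx + 1] - times[idx])


def measure_period(traj: Trajectory, coordinate: int = 0,
                   noise_floor: float = 1e-6) -> Optional[float]:
    """Oscillation period of one coordinate over the given window.

    Mean spacing of upward zero crossings of the mean-removed signal with
    linear interpolation between samples.  Returns None when the signal is
    flat (peak-to-peak below ``noise_floor``) or has fewer than 3
    crossings.
    """
    if len(traj.times) == 0:
        raise ValueError("empty trajectory tail")
    signal = traj.states[:, coordinate]
    if signal.max() - signal.min() < noise_floor:
        return None
    centered = signal - signal.mean()
    crossings = _upward_crossings(traj.times, centered)
    if len(crossings) < 3:
        return None
    return float(np.diff(crossings).mean())


def measure_period_spectral(traj: Trajectory, coordinate: int = 0) -> Optional[float]:
    """Cross-check period estimate from the dominant FFT frequency.

    Convenience utility; the zero-crossing estimate is the contract.
    """
    signal = traj.states[:, coordinate]
    centered = signal - signal.mean()
    if centered.max() - centered.min() < 1e-12:
        return None
    spectrum = np.abs(np.fft.rfft(centered))
    freqs = np.fft.rfftfreq(len(centered), d=traj.step)
    peak = spectrum[1:].argmax() + 1
    if freqs[peak] == 0:
        return None
    return float(1.0 / freqs[peak])
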