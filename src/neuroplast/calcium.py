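"""Per-neuron calcium traces used as a firing-rate proxy.

Each neuron carries a dimensionless intracellular calcium concentration
``Ca(t)`` that decays exponentially with time constant ``tau`` and jumps by
``beta`` every time the neuron spikes:

    dCa/dt = -Ca/tau            between spikes
    Ca    -> Ca + beta          at each spike

Under stationary Poisson firing at rate ``r`` (spikes/ms) the trace is a
shot-noise process with mean ``beta * r * tau``, which is what makes it a
linear read-out of the mean firing rate: with ``beta = 0.001`` and
``tau = 10^4`` ms, a calcium setpoint of 0.05 corresponds to 5 Hz.

Decay is evaluated lazily through the closed form ``Ca * exp(-dt/tau)`` at
event times (spikes and structural-update boundaries), which is exact for the
linear ODE, so no fine-grained integration of the trace is ever needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CalciumParams",
    "CalciumState",
    "advance",
    "on_spike",
    "CalciumField",
]


@dataclass(frozen=True)
class CalciumParams:
    """Constants of the calcium trace.

    Parameters
    ----------
    tau : float
        Decay time constant in ms. Must be positive.
    beta : float
        Intake per spike (dimensionless calcium units). Must be positive.
    """

    tau: float = 10000.0
    beta: float = 0.001

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if not self.beta > 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")


@dataclass(frozen=True)
class CalciumState:
    """A calcium concentration together with the time it was last updated."""

    ca: float = 0.0
    t_last: float = 0.0

    def __post_init__(self) -> None:
        if self.ca < 0:
            raise ValueError(f"calcium concentration must be >= 0, got {self.ca}")


def advance(state: CalciumState, dt: float, params: CalciumParams) -> CalciumState:
    """Decay the trace over ``dt`` milliseconds with no intervening spike.

    Uses the exact solution ``ca' = ca * exp(-dt/tau)`` of the decay ODE.
    """
    if dt < 0:
        raise ValueError(f"dt must be >= 0, got {dt}")
    return CalciumState(ca=state.ca * math.exp(-dt / params.tau), t_last=state.t_last + dt)


def on_spike(state: CalciumState, t_spike: float, params: CalciumParams) -> CalciumState:
    """Register a spike at ``t_spike``: decay since the last update, then add ``beta``."""
    elapsed = t_spike - state.t_last
    if elapsed < 0:
        raise ValueError(
            f"out-of-order spike: t_spike={t_spike} precedes t_last={state.t_last}"
        )
    decayed = state.ca * math.exp(-elapsed / params.tau)
    return CalciumState(ca=decayed + params.beta, t_last=t_spike)


class CalciumField:
    """Vectorized calcium traces for a whole network.

    Semantically identical to applying :func:`advance` / :func:`on_spike` per
    neuron; the engine uses one multiplicative decay per electrical step
    (exact, since the decay factor for a fixed step is constant) followed by
    ``beta`` intake for the neurons that spiked in that step.
    """

    def __init__(self, tau: np.ndarray, beta: np.ndarray) -> None:
        tau = np.asarray(tau, dtype=float)
        beta = np.asarray(beta, dtype=float)
        if np.any(tau <= 0) or np.any(beta <= 0):
            raise ValueError("tau and beta must be positive for every neuron")
        self.tau = tau
        self.beta = beta
        self.ca = np.zeros_like(tau)

    def decay_factor(self, dt: float) -> np.ndarray:
        """Per-neuron multiplicative factor for a step of ``dt`` ms."""
        return np.exp(-dt / self.tau)

    def step(self, factor: np.ndarray, spiking: np.ndarray) -> None:
        """Apply one step of decay, then intake for ``spiking`` (index array)."""
        self.ca *= factor
        if spiking.size:
            self.ca[spiking] += self.beta[spiking]
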