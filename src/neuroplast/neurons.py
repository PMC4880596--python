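"""Leaky integrate-and-fire populations with delta synapses and Poisson drive.

The electrical layer is deliberately minimal: current-free LIF neurons whose
membrane potential leaks exponentially toward rest and jumps instantaneously
by the synaptic amplitude (in mV) whenever a presynaptic spike arrives, plus
an independent external Poisson generator per neuron. Delta synapses are the
natural reading of a model parameterized purely by post-synaptic amplitudes
in mV.

All state lives in flat per-neuron numpy arrays; one call to
:func:`step_population` advances every neuron by one electrical step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LIFParams", "ExternalDrive", "step_population", "deliver"]


@dataclass(frozen=True)
class LIFParams:
    """Membrane parameters of a leaky integrate-and-fire population.

    Defaults follow the basic integrate-and-fire family of the major spiking
    simulators: tau_m 10 ms, threshold -55 mV, reset and rest at -70 mV,
    2 ms absolute refractory period.
    """

    tau_m: float = 10.0
    v_th: float = -55.0
    v_reset: float = -70.0
    e_l: float = -70.0
    t_ref: float = 2.0

    def __post_init__(self) -> None:
        if not (self.v_reset <= self.e_l < self.v_th):
            raise ValueError(
                f"require v_reset <= e_l < v_th, got {self.v_reset}, {self.e_l}, {self.v_th}"
            )
        if not self.tau_m > 0 or not self.t_ref > 0:
            raise ValueError("tau_m and t_ref must be positive")


@dataclass(frozen=True)
class ExternalDrive:
    """Independent Poisson input per neuron.

    rate is in Hz; amplitude is the voltage jump per external event in mV.
    """

    rate: float = 10000.0
    amplitude: float = 0.01

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError(f"rate must be >= 0, got {self.rate}")


def step_population(
    v: np.ndarray,
    refrac_steps: np.ndarray,
    alpha: np.ndarray,
    leak_mv: np.ndarray,
    v_th: np.ndarray,
    v_reset: np.ndarray,
    ref_steps_total: np.ndarray,
    input_mv: np.ndarray,
) -> np.ndarray:
    """Advance all neurons one electrical step in place; return spiker indices.

    Parameters
    ----------
    v, refrac_steps : state arrays, modified in place. ``refrac_steps`` counts
        remaining refractory steps (0 = integrating).
    alpha : per-neuron leak factor ``exp(-dt/tau_m)``.
    leak_mv : per-neuron constant ``(1 - alpha) * e_l`` (exponential-Euler
        leak toward rest, precomputed once for the run).
    input_mv : summed voltage jumps arriving this step (external drive plus
        recurrent events whose delay elapses now).
    ref_steps_total : refractory period in steps, per neuron.

    During refractoriness the membrane is clamped to ``v_reset`` and incoming
    events are discarded.
    """
    v *= alpha
    v += leak_mv
    v += input_mv
    refractory = refrac_steps > 0
    np.copyto(v, v_reset, where=refractory)
    refrac_steps -= refractory
    spiking = np.flatnonzero(v >= v_th)
    if spiking.size:
        v[spiking] = v_reset[spiking]
        refrac_steps[spiking] = ref_steps_total[spiking]
    return spiking


def deliver(spike_ids: np.ndarray, store, t: float) -> list[tuple[int, float, float]]:
    """Fan spikes out along the synapse store into delayed events.

    Returns a list of ``(target, amplitude_mv, delivery_time)`` tuples — one
    per outgoing synapse of each spiker, at ``t + delay`` of that synapse's
    rule. Inhibitory synapses carry negative amplitudes. The simulation engine
    uses an equivalent weight-matrix ring buffer; this explicit form is the
    reference semantics and serves small-scale cross-checks.
    """
    events: list[tuple[int, float, float]] = []
    spike_set = set(int(s) for s in np.atleast_1d(spike_ids))
    for rule in store.rules.values():
        pre, post = store.alive_edges(rule.label)
        for p, q in zip(pre, post):
            if int(p) in spike_set:
                events.append((int(q), rule.amplitude, t + rule.delay))
    return events
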