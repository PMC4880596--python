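"""The simulation loop: fast electrical steps, slow structural updates.

Biological time advances in electrical steps of ``dt`` (default 0.1 ms).
Every ``structural_interval`` (default 10 ms, i.e. 100 steps) the engine
performs one connectivity update:

    (a) simulate electrical activity for the interval, updating calcium at
        spikes;
    (b) calcium decay is carried to the interval end (implicit in the
        per-step closed-form decay);
    (c) integrate every element pool against the interval-start calcium;
    (d) prune a fraction of the vacant elements;
    (e) build the global structural report (vacant / to-delete per neuron);
    (f) commit deletions (partners become vacant, excluded from (g));
    (g) form new synapses by the global shuffle.

Structural plasticity can be disabled and re-enabled at runtime; calcium
tracking continues regardless so a later re-enable sees correct activity
history. Time intervals are half-open ``[t, t + dt)``: an event exactly on a
boundary belongs to the closing interval.

Randomness comes from one master seed split into independent named streams
(initial membrane potentials, Poisson drive, deletion sampling, matching
shuffles), so structural randomness is replayable independently of activity
randomness. Fixed seed implies bitwise-identical rasters and edge lists.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import Network
from .neurons import step_population
from .plasticity import build_reports, check_conservation, commit_deletions, form_synapses

__all__ = [
    "ScheduleConfig",
    "SimulationResult",
    "run",
    "enable_plasticity",
    "disable_plasticity",
]


@dataclass(frozen=True)
class ScheduleConfig:
    """Timing of a run.

    ``structural_interval`` must be an integer multiple of ``dt``; a ratio
    below 100 is allowed but triggers a warning, since the model assumes
    connectivity changes around two orders of magnitude slower than
    electrical activity.
    """

    t_total: float
    dt: float = 0.1
    structural_interval: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.structural_interval <= 0 or self.t_total < 0:
            raise ValueError("dt and structural_interval must be > 0, t_total >= 0")
        ratio = self.structural_interval / self.dt
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("structural_interval must be an integer multiple of dt")
        if round(ratio) < 100:
            warnings.warn(
                "structural_interval is less than 100 electrical steps; the "
                "slow-structural-timescale assumption may not hold",
                UserWarning,
                stacklevel=2,
            )

    @property
    def interval_steps(self) -> int:
        return round(self.structural_interval / self.dt)

    @property
    def total_steps(self) -> int:
        return round(self.t_total / self.dt)


def enable_plasticity(network: Network) -> None:
    network.plasticity_enabled = True


def disable_plasticity(network: Network) -> None:
    """Freeze the edge set; calcium tracking continues."""
    network.plasticity_enabled = False


@dataclass
class SimulationResult:
    network: Network
    spike_times: np.ndarray
    spike_ids: np.ndarray
    history: pd.DataFrame
    recorders: list = field(default_factory=list)

    def spikes(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ms": self.spike_times, "neuron_id": self.spike_ids})


class _Engine:
    def __init__(self, net: Network, schedule: ScheduleConfig):
        self.net = net
        self.schedule = schedule
        dt = schedule.dt
        ss = np.random.SeedSequence(schedule.seed)
        s_init, s_drive, s_del, s_shuf = ss.spawn(4)
        self.rng_drive = np.random.default_rng(s_drive)
        self.rng_del = np.random.default_rng(s_del)
        self.rng_shuf = np.random.default_rng(s_shuf)

        n = net.n
        self.alpha = np.exp(-dt / net.tau_m)
        self.lam = net.drive_rate * dt * 1e-3
        self.ref_steps_total = np.maximum(1, np.round(net.t_ref / dt).astype(np.int64))
        self.refrac = np.zeros(n, dtype=np.int64)
        self.ca_factor = net.calcium.decay_factor(dt)
        # randomized initial membrane potentials: desynchronizes onset and lets
        # near-threshold cells seed activity (zero-length runs leave state alone)
        if schedule.total_steps > 0:
            rng_init = np.random.default_rng(s_init)
            net.v[:] = net.v_reset + rng_init.random(n) * (net.v_th - net.v_reset)

        self.leak_mv = (1.0 - self.alpha) * net.e_l

        # exact Poisson drive via inverse-CDF tables, one per distinct rate;
        # bulk uniforms + searchsorted are ~an order of magnitude faster than
        # generic array-lambda Poisson sampling and exact to ~1e-15 tail mass
        self._drive_groups: list[tuple[np.ndarray, np.ndarray]] = []
        for lam in np.unique(self.lam):
            cols = np.flatnonzero(self.lam == lam)
            if lam <= 0:
                cdf = np.array([1.0])
            else:
                k_max = int(lam + 10.0 * math.sqrt(lam) + 20.0)
                pmf = np.exp(
                    -lam + np.arange(k_max + 1) * math.log(lam)
                    - np.cumsum(np.concatenate([[0.0], np.log(np.arange(1, k_max + 1))]))
                )
                cdf = np.cumsum(pmf)
                cdf[-1] = 1.0
            self._drive_groups.append((cols, cdf))

        # one adjacency per distinct delay, in CSR-by-presynaptic-neuron form;
        # rebuilt after every structural update (edge churn is ~100x slower
        # than the electrical step, so the rebuild cost is negligible)
        self.delay_steps: dict[str, int] = {}
        for rule in net.store.rules.values():
            d = round(rule.delay / dt)
            if d < 1 or abs(rule.delay / dt - d) > 1e-9:
                raise ValueError(
                    f"rule {rule.label!r}: delay must be a multiple of dt and >= dt"
                )
            self.delay_steps[rule.label] = d
        self.adj: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._rebuild_adjacency()
        self.D = max(self.delay_steps.values()) + 1
        self.buf = np.zeros((self.D, n))
        self.cur = 0

        self.spike_step_chunks: list[np.ndarray] = []
        self.spike_id_chunks: list[np.ndarray] = []
        self.history_rows: list[dict] = []

    def _rebuild_adjacency(self) -> None:
        """(indptr, targets, weights) per delay, rows ordered by presynaptic id."""
        net = self.net
        by_delay: dict[int, list] = {}
        for label, rule in net.store.rules.items():
            pre, post = net.store.alive_edges(label)
            if len(pre):
                by_delay.setdefault(self.delay_steps[label], []).append(
                    (pre, post, np.full(len(pre), rule.amplitude))
                )
        self.adj = {}
        for d, chunks in by_delay.items():
            pre = np.concatenate([c[0] for c in chunks])
            post = np.concatenate([c[1] for c in chunks])
            amp = np.concatenate([c[2] for c in chunks])
            order = np.argsort(pre, kind="stable")
            pre_sorted = pre[order]
            indptr = np.searchsorted(pre_sorted, np.arange(net.n + 1))
            self.adj[d] = (indptr, post[order], amp[order])

    def _deliver(self, spiking: np.ndarray) -> None:
        """Fan spikes out along each delay's adjacency into the ring buffer."""
        for d, (indptr, targets, weights) in self.adj.items():
            starts = indptr[spiking]
            counts = indptr[spiking + 1] - starts
            total = int(counts.sum())
            if total == 0:
                continue
            # flat indices of every outgoing edge of every spiker
            offsets = np.repeat(np.cumsum(counts) - counts, counts)
            flat = np.repeat(starts, counts) + np.arange(total) - offsets
            row = self.buf[(self.cur + d) % self.D]
            np.add.at(row, targets[flat], weights[flat])

    def electrical_interval(self, step0: int, n_steps: int) -> None:
        net, buf = self.net, self.buf
        v = net.v
        # one drive draw for the whole interval: (n_steps, n) event counts
        drive = np.empty((n_steps, net.n))
        for cols, cdf in self._drive_groups:
            u = self.rng_drive.random((n_steps, len(cols)))
            drive[:, cols] = np.searchsorted(cdf, u)
        drive *= net.drive_amp
        for k, s in enumerate(range(step0, step0 + n_steps)):
            input_mv = drive[k]
            input_mv += buf[self.cur]
            buf[self.cur] = 0.0
            spiking = step_population(
                v, self.refrac, self.alpha, self.leak_mv, net.v_th, net.v_reset,
                self.ref_steps_total, input_mv,
            )
            net.calcium.step(self.ca_factor, spiking)
            if spiking.size:
                self.spike_step_chunks.append(np.full(spiking.size, s, np.int64))
                self.spike_id_chunks.append(spiking.copy())
                self._deliver(spiking)
            self.cur = (self.cur + 1) % self.D

    def structural_update(self, ca_start: np.ndarray) -> tuple[int, int]:
        net = self.net
        n_deleted: dict[str, np.ndarray] = {}
        for etype, arr in net.elements.items():
            ids = arr.owner_ids
            _, nd = arr.integrate(ca_start[ids], self.schedule.structural_interval, net.calcium.tau[ids])
            n_deleted[etype] = nd
            arr.prune(net.prune_fraction)
        report = build_reports(net.elements, n_deleted)
        removed = commit_deletions(net.store, report, net.elements, self.rng_del)
        added = form_synapses(
            net.store, report.vacant, net.elements, self.rng_shuf, net.allow_autapses
        )
        n_rem = sum(len(pre) for pre, _post in removed.values())
        n_add = sum(len(pre) for pre, _post in added.values())
        net.store.compact()
        if n_rem or n_add:
            self._rebuild_adjacency()
        return n_add, n_rem


def run(
    network: Network,
    schedule: ScheduleConfig,
    recorders: list | None = None,
    enable_at: float | None = None,
    disable_at: float | None = None,
    check_invariants: bool = False,
    progress_every: float | None = None,
) -> SimulationResult:
    """Advance the network by ``schedule.t_total`` ms of biological time.

    Parameters
    ----------
    recorders : objects with ``prepare(network, dt)`` and
        ``sample(t_ms, network)``; sampled at their own cadence.
    enable_at, disable_at : optional times (ms, snapped to structural
        boundaries) at which plasticity is toggled during the run.
    check_invariants : verify element-synapse conservation after every
        structural interval (debug mode; raises on violation).
    progress_every : if set, log per-interval synapse counts and mean calcium
        roughly every this many ms.
    """
    recorders = list(recorders or [])
    eng = _Engine(network, schedule)
    dt = schedule.dt
    for rec in recorders:
        rec.prepare(network, dt)
        rec.sample(0.0, network)

    toggles = []  # one-shot scheduled plasticity switches, in time order
    if disable_at is not None:
        toggles.append((disable_at, False))
    if enable_at is not None:
        toggles.append((enable_at, True))
    toggles.sort()

    n_intervals, rem_steps = divmod(schedule.total_steps, schedule.interval_steps)
    step = 0
    next_progress = 0.0
    for k in range(n_intervals):
        t = step * dt
        while toggles and t >= toggles[0][0]:
            network.plasticity_enabled = toggles.pop(0)[1]
        ca_start = network.calcium.ca.copy()
        eng.electrical_interval(step, schedule.interval_steps)
        step += schedule.interval_steps
        t_end = step * dt
        n_add = n_rem = 0
        if network.plasticity_enabled:
            n_add, n_rem = eng.structural_update(ca_start)
            if check_invariants:
                check_conservation(network.store, network.elements)
        row = {"time_ms": t_end, "formed": n_add, "removed": n_rem,
               "plasticity": network.plasticity_enabled}
        for label in network.store.rules:
            row[f"syn_{label}"] = network.store.count(label)
        for p in network.populations:
            row[f"ca_{p.name}"] = network.mean_calcium(p.name)
        eng.history_rows.append(row)
        for rec in recorders:
            if rec.due(step):
                rec.sample(t_end, network)
        if progress_every is not None and t_end >= next_progress:
            syn = {l: network.store.count(l) for l in network.store.rules}
            ca = {p.name: round(network.mean_calcium(p.name), 4) for p in network.populations}
            print(f"[t={t_end:.0f} ms] synapses={syn} mean_ca={ca}", flush=True)
            next_progress = t_end + progress_every
    if rem_steps:  # trailing partial interval: electrical only
        eng.electrical_interval(step, rem_steps)
        step += rem_steps

    if eng.spike_step_chunks:
        spike_times = np.concatenate(eng.spike_step_chunks) * dt
        spike_ids = np.concatenate(eng.spike_id_chunks)
    else:
        spike_times = np.empty(0)
        spike_ids = np.empty(0, np.int64)
    history = pd.DataFrame(eng.history_rows)
    return SimulationResult(network, spike_times, spike_ids, history, recorders)
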