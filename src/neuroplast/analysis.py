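"""Recorders, file writers, and connectivity-comparison metrics.

All tabular output is plain CSV with header rows naming populations, so
snapshots round-trip losslessly through pandas.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .network import Network

__all__ = [
    "ConnectivityMatrix",
    "percent_connectivity",
    "average_error",
    "calcium_summary",
    "convergence_time",
    "CalciumRecorder",
    "ConnectivityRecorder",
    "write_spikes_csv",
    "read_spikes_csv",
    "write_matrix_csv",
    "read_matrix_csv",
]


class ConnectivityMatrix:
    """Source x target population synapse counts at one timestamp."""

    def __init__(self, counts: pd.DataFrame, sizes: dict[str, int], time_ms: float = 0.0):
        if list(counts.index) != list(counts.columns):
            raise ValueError("counts must be square with matching row/column labels")
        if (counts.to_numpy() < 0).any():
            raise ValueError("synapse counts cannot be negative")
        self.counts = counts
        self.sizes = dict(sizes)
        self.time_ms = time_ms

    @classmethod
    def from_network(cls, net: Network, time_ms: float = 0.0) -> "ConnectivityMatrix":
        return cls(
            net.connection_count_matrix(),
            {p.name: p.size for p in net.populations},
            time_ms,
        )

    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


def percent_connectivity(m: ConnectivityMatrix, normalization: str = "share") -> pd.DataFrame:
    """Normalize pairwise synapse counts to percentages.

    normalization="share" (default): each entry is the share of all synapses
    carried by that population pair, ``100 * c_ij / sum(c)`` — entries sum
    to 100. normalization="pair-probability": each entry is
    ``100 * c_ij / (N_i * N_j)``, the mean number of synapses per ordered
    neuron pair expressed as a percentage.
    """
    c = m.counts.to_numpy(dtype=float)
    if normalization == "share":
        total = c.sum()
        if total <= 0:
            raise ValueError("cannot normalize an empty network")
        out = 100.0 * c / total
    elif normalization == "pair-probability":
        sizes = np.array([m.sizes[name] for name in m.counts.index], dtype=float)
        out = 100.0 * c / np.outer(sizes, sizes)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return pd.DataFrame(out, index=m.counts.index, columns=m.counts.columns)


def average_error(a: pd.DataFrame, b: pd.DataFrame) -> tuple[float, float]:
    """Mean and standard deviation of elementwise |a - b| over all pairs.

    The matrices must share shape and labels. Symmetric in (a, b).
    """
    if list(a.index) != list(b.index) or list(a.columns) != list(b.columns):
        raise ValueError("matrix labels do not match")
    diff = np.abs(a.to_numpy(dtype=float) - b.to_numpy(dtype=float)).ravel()
    return float(diff.mean()), float(diff.std())


def convergence_time(
    times: np.ndarray,
    values: np.ndarray,
    eps: float,
    band: float = 0.05,
    window_ms: float = 10000.0,
) -> float | None:
    """First time from which the running mean stays within ``band*eps`` of eps.

    The running mean is taken over a trailing window of ``window_ms`` to
    suppress shot noise. Returns None if the trace never settles within the
    run ("not converged").
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(times) == 0:
        return None
    # trailing-window running mean on a (possibly irregular) sample grid
    rm = np.empty_like(values)
    j = 0
    csum = np.concatenate([[0.0], np.cumsum(values)])
    for i, t in enumerate(times):
        while times[j] < t - window_ms:
            j += 1
        rm[i] = (csum[i + 1] - csum[j]) / (i + 1 - j)
    inside = np.abs(rm - eps) <= band * eps
    if not inside[-1]:
        return None
    # last index before the final uninterrupted inside-stretch
    outside = np.flatnonzero(~inside)
    first = 0 if len(outside) == 0 else int(outside[-1]) + 1
    return float(times[first])


def calcium_summary(
    stream: pd.DataFrame,
    eps: dict[str, float],
    band: float = 0.05,
    window_ms: float = 10000.0,
) -> pd.DataFrame:
    """Per-population convergence report from a recorded calcium stream.

    ``stream`` has columns ``time_ms`` and one column per population holding
    the population-mean calcium. Returns a table with the target, the final
    running-mean value, and the convergence time (NaN if not converged).
    """
    rows = []
    t = stream["time_ms"].to_numpy()
    for name, e in eps.items():
        v = stream[name].to_numpy()
        ct = convergence_time(t, v, e, band=band, window_ms=window_ms)
        tail = v[t >= t[-1] - window_ms] if len(t) else v
        rows.append(
            {
                "population": name,
                "eps": e,
                "final_mean_ca": float(tail.mean()) if len(tail) else np.nan,
                "converged": ct is not None,
                "convergence_time_ms": np.nan if ct is None else ct,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# recorders


class _Recorder:
    def __init__(self, interval_ms: float):
        if interval_ms <= 0:
            raise ValueError("interval_ms must be > 0")
        self.interval_ms = interval_ms
        self.interval_steps = 1

    def prepare(self, net: Network, dt: float) -> None:
        self.interval_steps = max(1, round(self.interval_ms / dt))

    def due(self, step: int) -> bool:
        return step % self.interval_steps == 0

    def sample(self, t_ms: float, net: Network) -> None:  # pragma: no cover
        raise NotImplementedError


class CalciumRecorder(_Recorder):
    """Samples population-mean calcium (and optionally every neuron's trace)."""

    def __init__(self, interval_ms: float = 1000.0, per_neuron: bool = False):
        super().__init__(interval_ms)
        self.per_neuron = per_neuron
        self._rows: list[dict] = []
        self._neuron_rows: list[np.ndarray] = []
        self._times: list[float] = []

    def sample(self, t_ms: float, net: Network) -> None:
        row = {"time_ms": t_ms}
        for p in net.populations:
            row[p.name] = net.mean_calcium(p.name)
        self._rows.append(row)
        if self.per_neuron:
            self._times.append(t_ms)
            self._neuron_rows.append(net.calcium.ca.copy())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self._rows)

    def per_neuron_dataframe(self) -> pd.DataFrame:
        """Long-format (time_ms, neuron_id, ca) table."""
        if not self._neuron_rows:
            return pd.DataFrame(columns=["time_ms", "neuron_id", "ca"])
        n = len(self._neuron_rows[0])
        return pd.DataFrame(
            {
                "time_ms": np.repeat(self._times, n),
                "neuron_id": np.tile(np.arange(n), len(self._times)),
                "ca": np.concatenate(self._neuron_rows),
            }
        )


class ConnectivityRecorder(_Recorder):
    """Snapshots the population-pair count matrix (and optionally edge lists)."""

    def __init__(self, interval_ms: float = 10000.0, edges: bool = False):
        super().__init__(interval_ms)
        self.edges = edges
        self.snapshots: list[ConnectivityMatrix] = []
        self.edge_frames: list[pd.DataFrame] = []

    def sample(self, t_ms: float, net: Network) -> None:
        self.snapshots.append(ConnectivityMatrix.from_network(net, t_ms))
        if self.edges:
            self.edge_frames.append(net.store.to_dataframe(time_ms=t_ms))


# ---------------------------------------------------------------------------
# file formats


def write_spikes_csv(path, spikes: pd.DataFrame) -> None:
    """Two-column raster (time_ms, neuron_id); appends if the file exists."""
    path = Path(path)
    header = not path.exists()
    spikes.to_csv(path, mode="a", header=header, index=False)


def read_spikes_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_matrix_csv(path, matrix: pd.DataFrame) -> None:
    matrix.to_csv(path, index_label="source")


def read_matrix_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="source")
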