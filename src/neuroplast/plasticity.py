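"""Connectivity updates: synapse deletion, formation, and rewiring.

A synapse is a bound pair of compatible synaptic elements — an axonal element
on the presynaptic neuron and a dendritic element on the postsynaptic neuron,
as named by a :class:`SynapseRule`. At every structural interval the manager:

1. collects, per neuron and element type, how many vacant elements are
   available and how many connected elements must be released (the
   :class:`StructuralReport`);
2. breaks synapses for the released elements, choosing uniformly at random
   among the neuron's connected synapses of that type. The partner element of
   a broken synapse survives and becomes vacant again — this is what lets the
   network *rewire* rather than merely shrink;
3. forms new synapses by a global shuffle: every vacant element enters a
   pool, both sides are independently permuted, and positional pairs become
   synapses. Connection probability between two neurons therefore depends
   solely on how many compatible vacant elements they hold. Multapses
   (parallel synapses) arise naturally; autapses are skipped by default, the
   two elements staying vacant for the next interval.

Elements freed by step 2 are excluded from step 3's pool in the same
interval: a freed counterpart can re-match only at the *next* connectivity
update.

No topological or distance constraints enter anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .growth import ElementArray

__all__ = [
    "SynapseRule",
    "SynapseStore",
    "StructuralReport",
    "build_reports",
    "commit_deletions",
    "form_synapses",
    "disconnect",
    "check_conservation",
]


@dataclass(frozen=True)
class SynapseRule:
    """Declares one synapse model: which element types bind, and the edge traits."""

    label: str
    pre_element: str
    post_element: str
    amplitude: float
    delay: float = 1.0
    plastic: bool = True


class SynapseStore:
    """Global edge lists, one per synapse rule, with lazy compaction.

    Edges are append-only arrays plus an ``alive`` mask; dead slots are
    compacted away when they exceed half the array. Indices returned by
    queries are only valid until the next compaction, i.e. within one
    structural interval.
    """

    def __init__(self, rules: list[SynapseRule]) -> None:
        labels = [r.label for r in rules]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate synapse rule labels")
        self.rules: dict[str, SynapseRule] = {r.label: r for r in rules}
        self._pre: dict[str, np.ndarray] = {l: np.empty(0, np.int64) for l in labels}
        self._post: dict[str, np.ndarray] = {l: np.empty(0, np.int64) for l in labels}
        self._alive: dict[str, np.ndarray] = {l: np.empty(0, bool) for l in labels}

    def add(self, label: str, pre_ids: np.ndarray, post_ids: np.ndarray) -> None:
        if label not in self.rules:
            raise KeyError(f"unknown synapse rule {label!r}")
        pre_ids = np.asarray(pre_ids, np.int64)
        post_ids = np.asarray(post_ids, np.int64)
        if pre_ids.shape != post_ids.shape:
            raise ValueError("pre and post id arrays must have equal length")
        self._pre[label] = np.concatenate([self._pre[label], pre_ids])
        self._post[label] = np.concatenate([self._post[label], post_ids])
        self._alive[label] = np.concatenate([self._alive[label], np.ones(len(pre_ids), bool)])

    def kill(self, label: str, idx) -> None:
        """Mark edges dead by (current) index."""
        self._alive[label][idx] = False

    def compact(self) -> None:
        for label, alive in self._alive.items():
            if alive.size and (~alive).sum() > alive.size // 2:
                self._pre[label] = self._pre[label][alive]
                self._post[label] = self._post[label][alive]
                self._alive[label] = np.ones(len(self._pre[label]), bool)

    def count(self, label: str) -> int:
        return int(self._alive[label].sum())

    def total(self) -> int:
        return sum(self.count(l) for l in self.rules)

    def alive_edges(self, label: str) -> tuple[np.ndarray, np.ndarray]:
        alive = self._alive[label]
        return self._pre[label][alive], self._post[label][alive]

    def incident(self, label: str, side: str, neuron: int) -> np.ndarray:
        """Alive edge indices where ``neuron`` occupies ``side`` ('pre'|'post')."""
        arr = self._pre[label] if side == "pre" else self._post[label]
        return np.flatnonzero((arr == neuron) & self._alive[label])

    def endpoints(self, label: str, idx: int) -> tuple[int, int]:
        return int(self._pre[label][idx]), int(self._post[label][idx])

    def to_dataframe(self, time_ms: float | None = None) -> pd.DataFrame:
        frames = []
        for label in self.rules:
            pre, post = self.alive_edges(label)
            frames.append(pd.DataFrame({"pre_id": pre, "post_id": post, "label": label}))
        df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["pre_id", "post_id", "label"]
        )
        if time_ms is not None:
            df.insert(0, "time_ms", time_ms)
        return df


@dataclass
class StructuralReport:
    """Per element type, aligned to the owner arrays: vacant counts available
    for formation and connected counts that must be released."""

    vacant: dict[str, np.ndarray] = field(default_factory=dict)
    to_delete: dict[str, np.ndarray] = field(default_factory=dict)

    def total_vacant(self) -> int:
        return int(sum(v.sum() for v in self.vacant.values()))

    def total_to_delete(self) -> int:
        return int(sum(v.sum() for v in self.to_delete.values()))


def build_reports(
    elements: dict[str, ElementArray], n_deleted: dict[str, np.ndarray] | None = None
) -> StructuralReport:
    """Aggregate element state into the global report driving the update.

    ``vacant`` is the *total* current vacancy (old unmatched elements persist,
    less pruning, plus this interval's newly formed ones); ``to_delete`` comes
    from the integration step's floor crossings. Gains and losses on one
    neuron are never netted across element types.
    """
    report = StructuralReport()
    for etype, arr in elements.items():
        report.vacant[etype] = arr.vacant.copy()
        td = (
            np.asarray(n_deleted[etype], np.int64)
            if n_deleted is not None and etype in n_deleted
            else np.zeros(len(arr), np.int64)
        )
        if np.any(td < 0) or np.any(td > arr.connected):
            raise ValueError(f"to_delete exceeds connected count for {etype!r}")
        report.to_delete[etype] = td
    return report


class _Incidence:
    """Per-(rule, side) neuron -> edge-index lookup, built once per update.

    A stable argsort of the endpoint array gives each neuron's incident edges
    as a contiguous slice; the live ``alive`` mask is applied at query time so
    removals during the same update are respected.
    """

    def __init__(self, store: SynapseStore, label: str, side: str) -> None:
        arr = store._pre[label] if side == "pre" else store._post[label]
        self._order = np.argsort(arr, kind="stable")
        self._sorted = arr[self._order]
        self._alive = store._alive[label]

    def edges_of(self, neuron: int) -> np.ndarray:
        lo = np.searchsorted(self._sorted, neuron, side="left")
        hi = np.searchsorted(self._sorted, neuron, side="right")
        idx = self._order[lo:hi]
        return idx[self._alive[idx]]


def _sides_using(store: SynapseStore, etype: str) -> list[tuple[str, str]]:
    sides = []
    for rule in store.rules.values():
        if rule.pre_element == etype:
            sides.append((rule.label, "pre"))
        if rule.post_element == etype:
            sides.append((rule.label, "post"))
    return sides


def _remove_edge(
    store: SynapseStore, elements: dict[str, ElementArray], label: str, idx: int
) -> tuple[int, int]:
    """Kill one edge and decrement connected counts on both endpoints."""
    rule = store.rules[label]
    pre, post = store.endpoints(label, idx)
    store.kill(label, idx)
    ea = elements[rule.pre_element]
    ea.connected[ea.index_of(np.array([pre]))[0]] -= 1
    ed = elements[rule.post_element]
    ed.connected[ed.index_of(np.array([post]))[0]] -= 1
    return pre, post


def commit_deletions(
    store: SynapseStore,
    report: StructuralReport,
    elements: dict[str, ElementArray],
    rng: np.random.Generator,
) -> dict[str, tuple[list[int], list[int]]]:
    """Break synapses for every element scheduled for release.

    For each neuron owing deletions of element type T, the synapses to break
    are drawn uniformly without replacement from its connected synapses using
    T. The partner's counterpart element flips connected -> vacant (its z is
    untouched), restoring the conservation invariant.

    If both endpoints of an edge are scheduled in the same interval, the edge
    is removed once and the second neuron's remaining need is recomputed
    against its current connected count — both deletions are honored with no
    double-free.

    Returns the removed edges per rule label, for downstream bookkeeping
    (e.g. weight-matrix patching).
    """
    removed: dict[str, tuple[list[int], list[int]]] = {l: ([], []) for l in store.rules}
    for etype in sorted(elements):
        arr = elements[etype]
        td = report.to_delete.get(etype)
        if td is None or not td.any():
            continue
        sides = _sides_using(store, etype)
        incidences = [(label, _Incidence(store, label, side)) for label, side in sides]
        for pos in np.flatnonzero(td):
            neuron = int(arr.owner_ids[pos])
            avail = int(np.floor(max(arr.z[pos], 0.0)))
            need = int(arr.connected[pos]) - avail
            if need <= 0:
                continue  # already satisfied by partner-side removals
            cands = [
                (label, int(i))
                for label, inc in incidences
                for i in inc.edges_of(neuron)
            ]
            if need > len(cands):
                raise ValueError(
                    f"bookkeeping error: neuron {neuron} must release {need} "
                    f"{etype!r} elements but holds only {len(cands)} such synapses"
                )
            chosen = rng.choice(len(cands), size=need, replace=False)
            for c in chosen:
                label, idx = cands[int(c)]
                pre, post = _remove_edge(store, elements, label, idx)
                removed[label][0].append(pre)
                removed[label][1].append(post)
    return removed


def form_synapses(
    store: SynapseStore,
    vacancies: dict[str, np.ndarray],
    elements: dict[str, ElementArray],
    rng: np.random.Generator,
    allow_autapses: bool = False,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Match vacant elements into new synapses by a global shuffle.

    Per rule, the vacancy counts expand into one slot per vacant element on
    each side; both sequences are independently permuted and paired
    positionally for ``min(n_pre, n_post)`` pairs. Pairs violating the autapse
    policy are skipped (both elements stay vacant for the next interval).
    Matched elements flip vacant -> connected and an edge with the rule's
    amplitude and delay is appended; repeated pairs yield parallel edges.

    ``vacancies`` is consumed in place so element types shared between rules
    cannot be double-matched.
    """
    added: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for rule in store.rules.values():
        for etype in (rule.pre_element, rule.post_element):
            if etype not in elements:
                raise KeyError(f"rule {rule.label!r} references unknown element type {etype!r}")
        if not rule.plastic:
            continue
        pre_arr, post_arr = elements[rule.pre_element], elements[rule.post_element]
        vp = np.minimum(vacancies[rule.pre_element], pre_arr.vacant)
        vq = np.minimum(vacancies[rule.post_element], post_arr.vacant)
        pre_seq = np.repeat(pre_arr.owner_ids, vp)
        post_seq = np.repeat(post_arr.owner_ids, vq)
        rng.shuffle(pre_seq)
        rng.shuffle(post_seq)
        m = min(len(pre_seq), len(post_seq))
        pre_m, post_m = pre_seq[:m], post_seq[:m]
        if not allow_autapses:
            keep = pre_m != post_m
            pre_m, post_m = pre_m[keep], post_m[keep]
        if len(pre_m):
            store.add(rule.label, pre_m, post_m)
            np.add.at(pre_arr.connected, pre_arr.index_of(np.sort(pre_m)), 1)
            np.add.at(post_arr.connected, post_arr.index_of(np.sort(post_m)), 1)
            np.subtract.at(
                vacancies[rule.pre_element], pre_arr.index_of(np.sort(pre_m)), 1
            )
            np.subtract.at(
                vacancies[rule.post_element], post_arr.index_of(np.sort(post_m)), 1
            )
        added[rule.label] = (pre_m, post_m)
    return added


def disconnect(
    store: SynapseStore, elements: dict[str, ElementArray], label: str, idx: int
) -> tuple[int, int]:
    """Manually delete one synapse; *both* endpoint elements become vacant."""
    return _remove_edge(store, elements, label, idx)


def check_conservation(store: SynapseStore, elements: dict[str, ElementArray]) -> None:
    """Raise AssertionError unless element and synapse counts agree globally.

    For every element type T, the summed connected count over all neurons
    must equal the number of alive edges using T, summed over the rules and
    sides where T participates; and no neuron's connected count may exceed
    its usable element count or fall below zero.
    """
    for etype, arr in elements.items():
        if np.any(arr.connected < 0):
            raise AssertionError(f"negative connected count for {etype!r}")
        if np.any(arr.connected > arr.avail):
            raise AssertionError(f"connected exceeds usable elements for {etype!r}")
        expected = sum(store.count(label) for label, _side in _sides_using(store, etype))
        got = int(arr.connected.sum())
        if got != expected:
            raise AssertionError(
                f"conservation violated for {etype!r}: {got} connected elements "
                f"vs {expected} synapse endpoints"
            )
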