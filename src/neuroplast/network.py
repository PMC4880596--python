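"""Network container: populations, element pools, synapse store, flat state.

A :class:`Network` owns everything the engine advances: per-neuron membrane
and calcium arrays, one :class:`~neuroplast.growth.ElementArray` per declared
element type, and the global :class:`~neuroplast.plasticity.SynapseStore`.
Neurons are numbered globally and contiguously per population, in declaration
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calcium import CalciumField, CalciumParams
from .growth import ElementArray, GrowthCurveSpec
from .neurons import ExternalDrive, LIFParams
from .plasticity import SynapseRule, SynapseStore

__all__ = ["Population", "Network"]


@dataclass(frozen=True)
class Population:
    """One homogeneous population and the element types its neurons express."""

    name: str
    size: int
    lif: LIFParams = field(default_factory=LIFParams)
    drive: ExternalDrive = field(default_factory=ExternalDrive)
    elements: dict[str, GrowthCurveSpec] = field(default_factory=dict)
    calcium: CalciumParams = field(default_factory=CalciumParams)

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError(f"population {self.name!r} must have size > 0")


class Network:
    def __init__(
        self,
        populations: list[Population],
        rules: list[SynapseRule],
        prune_fraction: float = 0.0,
        allow_autapses: bool = False,
    ) -> None:
        if not 0.0 <= prune_fraction <= 1.0:
            raise ValueError("prune_fraction must be in [0, 1]")
        names = [p.name for p in populations]
        if len(set(names)) != len(names):
            raise ValueError("duplicate population names")
        self.populations = list(populations)
        self.prune_fraction = prune_fraction
        self.allow_autapses = allow_autapses
        self.plasticity_enabled = True

        sizes = np.array([p.size for p in populations], dtype=np.int64)
        self.pop_starts = np.concatenate([[0], np.cumsum(sizes)])
        self.n = int(self.pop_starts[-1])

        # flat per-neuron parameter arrays
        def flat(get):
            return np.concatenate([np.full(p.size, get(p), dtype=float) for p in populations])

        self.tau_m = flat(lambda p: p.lif.tau_m)
        self.v_th = flat(lambda p: p.lif.v_th)
        self.v_reset = flat(lambda p: p.lif.v_reset)
        self.e_l = flat(lambda p: p.lif.e_l)
        self.t_ref = flat(lambda p: p.lif.t_ref)
        self.drive_rate = flat(lambda p: p.drive.rate)
        self.drive_amp = flat(lambda p: p.drive.amplitude)
        self.calcium = CalciumField(
            tau=flat(lambda p: p.calcium.tau), beta=flat(lambda p: p.calcium.beta)
        )
        self.v = self.e_l.copy()

        # element arrays, owners in ascending global id order
        etypes: list[str] = []
        for p in populations:
            for e in p.elements:
                if e not in etypes:
                    etypes.append(e)
        self.elements: dict[str, ElementArray] = {}
        for e in etypes:
            owners, curves = [], []
            for k, p in enumerate(populations):
                if e in p.elements:
                    ids = np.arange(self.pop_starts[k], self.pop_starts[k + 1])
                    owners.append(ids)
                    curves.extend([p.elements[e]] * p.size)
            self.elements[e] = ElementArray(e, np.concatenate(owners), curves)

        for r in rules:
            for e in (r.pre_element, r.post_element):
                if e not in self.elements:
                    raise ValueError(
                        f"synapse rule {r.label!r} references element type {e!r} "
                        "not declared on any population"
                    )
        self.store = SynapseStore(rules)

    # -- lookup ------------------------------------------------------------
    def population_index_of(self, neuron_ids: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.pop_starts, np.asarray(neuron_ids), side="right") - 1

    def population_slice(self, name: str) -> slice:
        for k, p in enumerate(self.populations):
            if p.name == name:
                return slice(int(self.pop_starts[k]), int(self.pop_starts[k + 1]))
        raise KeyError(f"unknown population {name!r}")

    # -- construction helpers ---------------------------------------------
    def pre_connect(self, label: str, pre_ids: np.ndarray, post_ids: np.ndarray) -> None:
        """Install edges before a run, backing them with connected elements.

        Each installed synapse grants both endpoints one element (z += 1,
        connected += 1), so pre-connected networks start on the conservation
        invariant with zero vacancy.
        """
        rule = self.store.rules[label]
        pre_ids = np.asarray(pre_ids, np.int64)
        post_ids = np.asarray(post_ids, np.int64)
        self.store.add(label, pre_ids, post_ids)
        for etype, ids in ((rule.pre_element, pre_ids), (rule.post_element, post_ids)):
            arr = self.elements[etype]
            idx = arr.index_of(np.sort(ids))
            np.add.at(arr.connected, idx, 1)
            np.add.at(arr.z, idx, 1.0)

    # -- summaries ----------------------------------------------------------
    def connection_count_matrix(self) -> pd.DataFrame:
        """Population-pair synapse counts (rows: source, columns: target)."""
        names = [p.name for p in self.populations]
        m = np.zeros((len(names), len(names)), dtype=np.int64)
        for label in self.store.rules:
            pre, post = self.store.alive_edges(label)
            if len(pre):
                np.add.at(
                    m, (self.population_index_of(pre), self.population_index_of(post)), 1
                )
        return pd.DataFrame(m, index=names, columns=names)

    def mean_calcium(self, name: str) -> float:
        return float(self.calcium.ca[self.population_slice(name)].mean())

    def manifest(self) -> dict:
        """All construction parameters, for provenance echoing."""
        return {
            "populations": [
                {
                    "name": p.name,
                    "size": p.size,
                    "lif": vars(p.lif).copy(),
                    "drive": vars(p.drive).copy(),
                    "calcium": vars(p.calcium).copy(),
                    "elements": {
                        e: {
                            "growth_curve": c.kind,
                            "growth_rate": c.nu,
                            "eps": c.eps,
                            "eta": c.eta,
                            "continuous": c.continuous,
                        }
                        for e, c in p.elements.items()
                    },
                }
                for p in self.populations
            ],
            "synapse_rules": [vars(r).copy() for r in self.store.rules.values()],
            "prune_fraction": self.prune_fraction,
            "allow_autapses": self.allow_autapses,
        }
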