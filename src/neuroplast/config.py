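"""YAML run-configuration surface.

A run configuration names one of the bundled models, its build arguments,
and the schedule. Growth-curve dictionaries use the same key layout as the
simulator configuration convention this model family comes from::

    {growth_curve: "gaussian", growth_rate: 1.0e-4, eta: 0.0, eps: 0.05,
     continuous: false}

Example run file::

    model: two_population
    scale: 0.1
    nu_scale: 10.0
    schedule: {t_total: 150000.0, dt: 0.1, structural_interval: 10.0, seed: 1}
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .engine import ScheduleConfig
from .growth import GrowthCurveSpec
from .models import build_microcircuit, build_two_population
from .network import Network

__all__ = ["growth_curve_from_dict", "growth_curve_to_dict", "load_config"]


def growth_curve_from_dict(d: dict) -> GrowthCurveSpec:
    """Parse the {growth_curve, growth_rate, eta, eps, continuous} layout."""
    return GrowthCurveSpec(
        kind=d["growth_curve"],
        nu=float(d["growth_rate"]),
        eps=float(d["eps"]),
        eta=float(d.get("eta", 0.0)),
        continuous=bool(d.get("continuous", True)),
    )


def growth_curve_to_dict(c: GrowthCurveSpec) -> dict:
    return {
        "growth_curve": c.kind,
        "growth_rate": c.nu,
        "eta": c.eta,
        "eps": c.eps,
        "continuous": c.continuous,
    }


_BUILDERS = {
    "two_population": build_two_population,
    "microcircuit": build_microcircuit,
}


def load_config(path: str | Path) -> tuple[Network, ScheduleConfig]:
    """Build (network, schedule) from a YAML run file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    model = cfg.get("model")
    if model not in _BUILDERS:
        raise ValueError(f"unknown model {model!r}; expected one of {sorted(_BUILDERS)}")
    sched_cfg = cfg.get("schedule", {})
    schedule = ScheduleConfig(
        t_total=float(sched_cfg.get("t_total", 100000.0)),
        dt=float(sched_cfg.get("dt", 0.1)),
        structural_interval=float(sched_cfg.get("structural_interval", 10.0)),
        seed=int(sched_cfg.get("seed", 0)),
    )
    kwargs = {k: v for k, v in cfg.items() if k not in ("model", "schedule")}
    network = _BUILDERS[model](**kwargs)
    return network, schedule
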