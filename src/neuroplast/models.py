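"""Builders for the bundled network models.

Two self-organizing setups ship with the package:

* a simple two-population network (80% excitatory / 20% inhibitory) whose
  Gaussian growth rules drive the excitatory population toward a calcium
  setpoint of 0.05 (≈5 Hz) and the inhibitory population toward 0.2 (≈20 Hz);
* an eight-population, four-layer cortical microcircuit in the tradition of
  the layered column models (L2/3, L4, L5, L6, each with an excitatory and an
  inhibitory population), starting either disconnected, from a reference
  connectivity table, or from a perturbed copy of it.

Both builders accept a ``scale`` knob multiplying all population sizes and a
``nu_scale`` knob multiplying all growth rates, so desk-scale runs converge
in minutes instead of hours of biological time. Builders are pure: the same
arguments always produce an identical initial network.

Three electrical choices matter for self-organization and are worth
spelling out (all overridable):

* **drive amplitude 0.125 mV** at 10^4 Hz. The external generator alone then
  fires an isolated neuron at ~0.5 Hz (mean depolarization 12.5 mV toward a
  15 mV threshold gap, fluctuation σ ≈ 0.9 mV). A disconnected network needs
  that spontaneous trickle: with η = 0 a perfectly silent neuron sits exactly
  on the lower zero of its Gaussian growth curve and could never form an
  element. The benchmark-style 0.01 mV amplitude leaves the threshold
  hundreds of σ away — a dead network — while amplitudes driving more than
  ~5 Hz put excitatory neurons above their setpoint from the start, which
  (as the activity-first ordering requires) starves the inhibitory
  population of excitatory axons.
* **hyperpolarizing reset** (v_reset −85 mV, 15 mV below rest). With 1 mV
  delta synapses a network whose in-degrees exceed ~100 supports an
  epileptic, refractory-limited attractor; making each spike costly damps
  synchronous avalanches enough that the homeostat can steer through the
  overshoot phase without igniting it.
* **vacant-element decay 0.005 per update**. Unmatched element backlogs act
  as stored energy: when a matching partner finally appears, a whole backlog
  converts to synapses in a few intervals, kicking the network. A decay well
  below the per-interval growth increment leaves element formation intact
  but bleeds stale backlogs away and creates a small deadband around the
  setpoint, turning a structural limit cycle into damped convergence.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calcium import CalciumParams
from .growth import GrowthCurveSpec
from .network import Network, Population
from .neurons import ExternalDrive, LIFParams
from .plasticity import SynapseRule

__all__ = [
    "BUNDLED_LIF",
    "BUNDLED_DRIVE",
    "build_two_population",
    "two_population_schedule",
    "build_microcircuit",
    "microcircuit_default_params",
    "MICROCIRCUIT_POPULATIONS",
]

#: Membrane parameters of the bundled models (see module docstring).
BUNDLED_LIF = LIFParams(tau_m=10.0, v_th=-55.0, v_reset=-85.0, e_l=-70.0, t_ref=2.0)

#: External drive of the bundled models (see module docstring).
BUNDLED_DRIVE = ExternalDrive(rate=10000.0, amplitude=0.125)

#: Fixed population order of the microcircuit model.
MICROCIRCUIT_POPULATIONS = ["L23e", "L23i", "L4e", "L4i", "L5e", "L5i", "L6e", "L6i"]


def build_two_population(
    scale: float = 1.0,
    nu_scale: float = 1.0,
    lif: LIFParams | None = None,
    drive: ExternalDrive | None = None,
    calcium: CalciumParams | None = None,
    exc_amplitude: float = 1.0,
    g: float = 1.0,
    exc_delay: float = 1.0,
    inh_delay: float = 1.0,
    prune_fraction: float = 0.005,
    allow_autapses: bool = False,
) -> Network:
    """The simple excitatory/inhibitory self-organizing network.

    At scale 1 the network holds 1000 LIF neurons, 80% excitatory and 20%
    inhibitory, with zero initial synapses. Excitatory neurons carry
    Axon_ex, Den_ex and Den_in elements under a Gaussian rule with eta=0,
    eps=0.05, nu=1e-4 elements/ms; inhibitory neurons carry Axon_in, Den_ex
    and Den_in with eps=0.2 and the same nu, except their excitatory
    (Den_ex) elements which grow four times faster. Excitatory synapses
    (Axon_ex->Den_ex) jump the target by +1 mV, inhibitory ones
    (Axon_in->Den_in) by -1 mV.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    n = round(1000 * scale)
    n_ex = round(0.8 * n)
    n_in = n - n_ex
    if n_ex < 2 or n_in < 2:
        raise ValueError(f"scale {scale} leaves fewer than 2 neurons in a population")
    lif = lif or BUNDLED_LIF
    drive = drive or BUNDLED_DRIVE
    calcium = calcium or CalciumParams()

    def gauss(nu, eps):
        return GrowthCurveSpec("gaussian", nu=nu * nu_scale, eps=eps, eta=0.0)

    ex = Population(
        "ex", n_ex, lif=lif, drive=drive, calcium=calcium,
        elements={
            "Axon_ex": gauss(1.0e-4, 0.05),
            "Den_ex": gauss(1.0e-4, 0.05),
            "Den_in": gauss(1.0e-4, 0.05),
        },
    )
    inh = Population(
        "in", n_in, lif=lif, drive=drive, calcium=calcium,
        elements={
            "Axon_in": gauss(1.0e-4, 0.2),
            "Den_ex": gauss(4.0e-4, 0.2),
            "Den_in": gauss(1.0e-4, 0.2),
        },
    )
    rules = [
        SynapseRule("ex_syn", "Axon_ex", "Den_ex", amplitude=exc_amplitude, delay=exc_delay),
        SynapseRule("in_syn", "Axon_in", "Den_in", amplitude=-g * exc_amplitude, delay=inh_delay),
    ]
    return Network([ex, inh], rules, prune_fraction=prune_fraction, allow_autapses=allow_autapses)


def two_population_schedule(t_total: float = 3_000_000.0, seed: int = 0):
    """The full-scale run configuration: 3000 s, dt 0.1 ms, structural update
    every 100 integration steps."""
    from .engine import ScheduleConfig

    return ScheduleConfig(t_total=t_total, dt=0.1, structural_interval=10.0, seed=seed)


# ---------------------------------------------------------------------------
# cortical microcircuit


def microcircuit_default_params() -> dict:
    """The bundled illustrative microcircuit parameter set (parsed YAML)."""
    with resources.files("neuroplast.data").joinpath("microcircuit_default.yaml").open() as fh:
        return yaml.safe_load(fh)


def _load_params(params) -> dict:
    if params is None:
        return microcircuit_default_params()
    if isinstance(params, (str, Path)):
        with open(params) as fh:
            return yaml.safe_load(fh)
    return dict(params)


def build_microcircuit(
    scale: float = 1.0,
    connectivity_init: str = "empty",
    params=None,
    reference_table: pd.DataFrame | str | Path | None = None,
    error_percent: float = 10.0,
    nu_scale: float = 1.0,
    seed: int = 0,
    prune_fraction: float = 0.005,
    allow_autapses: bool = False,
) -> Network:
    """The four-layer, eight-population cortical microcircuit.

    Parameters
    ----------
    scale : multiplies the per-population neuron counts of the reference
        column model (config values, not hard-coded truths).
    connectivity_init : "empty" (no synapses), "reference" (edges sampled
        from ``reference_table`` pairwise connection probabilities), or
        "perturbed" (table entries jittered uniformly by ±``error_percent``%
        before sampling).
    params : path or mapping with per-population sizes and growth targets;
        defaults to the bundled illustrative parameter file.
    reference_table : 8x8 CSV or DataFrame of connection probabilities
        (rows: source population, columns: target). Required for the
        "reference" and "perturbed" modes; the package bundles none.
    seed : drives the sampling of the initial connectivity only.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    cfg = _load_params(params)
    pops_cfg = cfg.get("populations", {})
    missing = [name for name in MICROCIRCUIT_POPULATIONS if name not in pops_cfg]
    if missing:
        raise ValueError(f"parameter file is missing populations: {', '.join(missing)}")
    lif = LIFParams(**cfg.get("lif", {})) if cfg.get("lif") else BUNDLED_LIF
    drive_cfg = cfg.get("drive", {})
    calcium = CalciumParams(**cfg.get("calcium", {})) if cfg.get("calcium") else CalciumParams()
    syn = cfg.get("synapses", {})
    amp_e = float(syn.get("excitatory_amplitude", 1.0))
    amp_i = float(syn.get("inhibitory_amplitude", -1.0))
    delay = float(syn.get("delay", 1.0))

    populations = []
    for name in MICROCIRCUIT_POPULATIONS:
        p = pops_cfg[name]
        size = max(2, round(p["size"] * scale))
        nu = float(p.get("nu", 1.0e-4)) * nu_scale
        # populations chasing a high setpoint must offer excitatory dendritic
        # elements faster than the excitatory sources themselves, or the
        # sources reach equilibrium first and the supply of axons dries up
        nu_den_ex = float(p.get("nu_den_ex", p.get("nu", 1.0e-4))) * nu_scale
        eps = float(p["eps"])
        eta = float(p.get("eta", 0.0))

        def gauss(rate):
            return GrowthCurveSpec("gaussian", nu=rate, eps=eps, eta=eta)

        axon = "Axon_ex" if name.endswith("e") else "Axon_in"
        elements = {axon: gauss(nu), "Den_ex": gauss(nu_den_ex), "Den_in": gauss(nu)}
        drive = ExternalDrive(
            rate=float(p.get("drive_rate", drive_cfg.get("rate", 10000.0))),
            amplitude=float(drive_cfg.get("amplitude", 0.125)),
        )
        populations.append(
            Population(name, size, lif=lif, drive=drive, calcium=calcium, elements=elements)
        )
    rules = [
        SynapseRule("ex_syn", "Axon_ex", "Den_ex", amplitude=amp_e, delay=delay),
        SynapseRule("in_syn", "Axon_in", "Den_in", amplitude=amp_i, delay=delay),
    ]
    net = Network(populations, rules, prune_fraction=prune_fraction, allow_autapses=allow_autapses)

    if connectivity_init != "empty":
        if reference_table is None:
            raise ValueError(
                f"connectivity_init={connectivity_init!r} requires a reference_table"
            )
        if isinstance(reference_table, (str, Path)):
            table = pd.read_csv(reference_table, index_col=0)
        else:
            table = reference_table
        table = table.loc[MICROCIRCUIT_POPULATIONS, MICROCIRCUIT_POPULATIONS]
        rng = np.random.default_rng(seed)
        probs = table.to_numpy(dtype=float)
        if connectivity_init == "perturbed":
            jitter = rng.uniform(-error_percent / 100.0, error_percent / 100.0, probs.shape)
            probs = np.clip(probs * (1.0 + jitter), 0.0, 1.0)
        elif connectivity_init != "reference":
            raise ValueError(f"unknown connectivity_init {connectivity_init!r}")
        _sample_initial_edges(net, probs, rng)
    return net


def _sample_initial_edges(net: Network, probs: np.ndarray, rng: np.random.Generator) -> None:
    """Install edges pair-probability-wise; every edge is backed by elements."""
    for i, src in enumerate(net.populations):
        s = net.population_slice(src.name)
        label = "ex_syn" if src.name.endswith("e") else "in_syn"
        for j, tgt in enumerate(net.populations):
            p = probs[i, j]
            if p <= 0:
                continue
            t = net.population_slice(tgt.name)
            n_edges = rng.binomial(src.size * tgt.size, min(p, 1.0))
            if n_edges == 0:
                continue
            pre = rng.integers(s.start, s.stop, n_edges)
            post = rng.integers(t.start, t.stop, n_edges)
            if not net.allow_autapses:
                keep = pre != post
                pre, post = pre[keep], post[keep]
            net.pre_connect(label, pre, post)
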