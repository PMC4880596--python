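# neuroplast

Self-organizing spiking neuronal networks with **homeostatic structural
plasticity**: instead of prescribing who connects to whom, every neuron grows
and retracts abstract synaptic contact points — axonal boutons and dendritic
spines, collectively *synaptic elements* — under a calcium-dependent
homeostatic rule, and a global connectivity manager pairs vacant elements
into synapses and breaks synapses whose elements are retracted. Networks
wire themselves from a fully disconnected state toward per-population
activity setpoints.

The package is aimed at computational neuroscientists who want to *generate*
connectivity from activity constraints (e.g. find a connectome consistent
with target firing rates of cortical populations), study critical-period-like
rewiring, or prototype structural-plasticity rules without a full simulator
stack.

## Model

Each neuron tracks a calcium trace, a linear read-out of its firing rate:

    dCa/dt = -Ca/τ,   Ca → Ca + β at each spike

so that under Poisson firing at rate r, ⟨Ca⟩ = β·r·τ (with β = 0.001 and
τ = 10⁴ ms, a setpoint ε = 0.05 corresponds to 5 Hz). Each element type on a
neuron carries a continuous count z obeying a growth rule dz/dt = g(Ca),
either

    linear:    g(Ca) = ν (1 − Ca/ε)
    gaussian:  g(Ca) = ν (2 exp(−((Ca − ξ)/ζ)²) − 1),
               ξ = (η+ε)/2,  ζ = (ε−η)/(2√ln2)

The Gaussian rule crosses zero at η (minimum calcium to form elements) and at
the setpoint ε, and retracts elements (g → −ν) when activity is far above
target. The usable element count is ⌊max(z, 0)⌋: upward integer crossings
create *vacant* elements; if the count drops below the number of elements
bound in synapses, synapses are broken — the partner element survives and
becomes vacant again, which is what lets the network *rewire* rather than
only grow or shrink. At every connectivity update (default every 10 ms = 100
electrical steps) all vacant compatible elements enter a global pool, both
sides are shuffled, and positional pairs become synapses: connection
probability depends only on the number of compatible vacant elements offered.

The electrical layer is a leaky integrate-and-fire network with delta
(voltage-jump) synapses and independent Poisson drive per neuron.

Two self-organizing models ship with the package: a **two-population
network** (80% excitatory neurons with ε = 0.05, 20% inhibitory with
ε = 0.2, ±1 mV synapses) and an eight-population, four-layer **cortical
microcircuit** with illustrative per-population setpoints.

## Worked example

Grow the two-population network from zero synapses at desk scale (100
neurons, growth rates ×10, 500 biological seconds, ~2 minutes of wall time):

```python
from neuroplast import build_two_population, ScheduleConfig, run

net = build_two_population(scale=0.1, nu_scale=10.0)
res = run(net, ScheduleConfig(t_total=500_000.0, seed=1),
          progress_every=50_000.0)
tail = res.history[res.history.time_ms >= 400_000.0]
print(tail.ca_ex.mean(), tail.ca_in.mean())
```

Progress output (excerpt):

```
[t=200010 ms] synapses={'ex_syn': 940, 'in_syn': 38} mean_ca={'ex': 0.0373, 'in': 0.1171}
[t=250010 ms] synapses={'ex_syn': 1997, 'in_syn': 271} mean_ca={'ex': 0.0449, 'in': 0.1916}
[t=350010 ms] synapses={'ex_syn': 1343, 'in_syn': 102} mean_ca={'ex': 0.0481, 'in': 0.1954}
[t=450010 ms] synapses={'ex_syn': 1317, 'in_syn': 76} mean_ca={'ex': 0.0474, 'in': 0.1996}
0.0482 0.1982
```

Reading this: the disconnected network is silent at first (calcium ≈ 0),
excitatory connections proliferate and overshoot (the `ex_syn` peak around
t = 250 s), inhibition builds up later and triggers a pruning/rewiring
episode, and both populations settle at their calcium setpoints — the
excitatory mean 0.0482 ≈ ε = 0.05 (≈5 Hz) and the inhibitory mean
0.1982 ≈ ε = 0.2 (≈20 Hz). The final graph is *generated*, not prescribed.

The same run is available from the shell:

```bash
neuroplast run --config examples/two_population.yaml --seed 1 --out results/run1
neuroplast analyze calcium --stream results/run1/calcium.csv --eps-file examples/two_population_eps.yaml
```

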