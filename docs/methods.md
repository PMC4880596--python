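# Methods

## The model

Structural plasticity is modeled at the level of *synaptic elements*:
abstract contact points that neurons grow and retract, with a synapse being a
bound pair of one axonal element (on the presynaptic neuron) and one
dendritic element (on the postsynaptic neuron). Three coupled processes run
on separated timescales:

1. **Electrical activity** (0.1 ms step). Leaky integrate-and-fire neurons
   with instantaneous voltage-jump (delta) synapses and an independent
   Poisson generator per neuron. Delta synapses are the natural reading of a
   model parameterized purely by post-synaptic amplitudes in mV; no
   conductances or synaptic time constants are introduced.
2. **Calcium traces** (event-driven, exact). Per neuron,
   dCa/dt = −Ca/τ with an intake β at each spike. The trace is a linear
   firing-rate read-out: ⟨Ca⟩ = β·r·τ under Poisson firing at rate r. Decay
   is applied via the closed form Ca·e^(−Δ/τ), so the integration is exact
   regardless of where it is evaluated; per-step multiplicative decay in the
   engine and lazy event-time evaluation in the scalar API are identical.
3. **Element counts and connectivity** (10 ms interval, i.e. 100 electrical
   steps). Each element type carries a continuous count z with
   dz/dt = g(Ca). The linear rule is integrated exactly over the interval
   under the no-spike decay of calcium (spikes inside the interval roll into
   the next interval's start value); the Gaussian rule takes one forward
   Euler step at the interval-start calcium. Usable elements are
   ⌊max(z,0)⌋; z may go negative, modeling a deficit that must be regrown
   before elements reappear, which prevents churn at the zero boundary.

At each connectivity update, per-neuron reports of vacant and to-be-released
elements are aggregated globally; synapses for released elements are drawn
uniformly without replacement from the neuron's connected synapses of that
type (the partner element survives and becomes vacant — rewiring); then all
vacant compatible elements are expanded into per-element slots, both sides
independently shuffled, and paired positionally. Consequences embraced by the
model: multapses (parallel synapses) occur with the natural multiplicity;
connection probability depends only on offered element counts, never on
distance or topology. Autapses are skipped by default (the pair's elements
stay vacant for the next interval); elements freed by a deletion are excluded
from the same interval's matching pool and can re-match only at the next
update. Both endpoints of an edge being scheduled for release in the same
interval is honored with no double-free: needs are recomputed against the
current connected count as deletions land.

A note on the Gaussian rule: with ζ = (ε−η)/(2√ln2), only the *squared*
exponent exp(−((Ca−ξ)/ζ)²) yields the defining property of two zero
crossings at η and ε with peak ν at the midpoint; the package implements
that form.

## Key parameters

| parameter | default | units | role |
|---|---|---|---|
| β | 0.001 | Ca | calcium intake per spike |
| τ | 10⁴ | ms | calcium decay; sets ⟨Ca⟩ = β·r·τ and the feedback delay |
| ν | 10⁻⁴ | elements/ms | peak element growth rate |
| ε | per population | Ca | setpoint (0.05 ↔ 5 Hz, 0.2 ↔ 20 Hz) |
| η | 0.0 | Ca | lower zero of the Gaussian rule |
| dt | 0.1 | ms | electrical step |
| structural interval | 10 | ms | connectivity update cadence (warn if < 100·dt) |
| synaptic amplitude | ±1.0 | mV | recurrent delta-PSP |
| drive | 10⁴ Hz × 0.125 mV | | external Poisson input per neuron |
| prune fraction | 0.005 (bundled models) | per update | decay of vacant elements |

## Choices where the design was open

**External drive and membrane parameters.** The model family's standard amplitudes
(±1 mV recurrent, weak external events) leave the electrical substrate
underdetermined, and not every completion supports self-organization. Two
hard constraints shaped the defaults: (i) a fully disconnected network must
fire *sparsely but not never* — with η = 0 a silent neuron sits exactly on
the lower zero of its growth curve, so without spontaneous drive-induced
spikes nothing can ever grow; (ii) the recurrent PSP must be small against
the threshold gap, or single presynaptic spikes relay with probability ≈ 1
and every target state is shadowed by a synchronous epileptic attractor. The
bundled models therefore use the standard 15 mV threshold gap (v_th −55,
rest −70 mV) with an external-event amplitude of 0.125 mV — the scale used
for external inputs in layered cortical column models — which gives a mean
drive depolarization of 12.5 mV, fluctuations σ ≈ 0.9 mV, and ~0.5 Hz
spontaneous firing in isolation. The reset is hyperpolarizing (−85 mV):
making each spike cost 30 mV of recovery damps synchronous avalanches, which
otherwise ignite during the development overshoot. All of these are ordinary
config values; nothing in the algorithm depends on them.

**Vacant-element decay.** Deleting a fraction f of unused elements per update
is part of the model family, but f must satisfy f ≪ ν·Δ (the per-interval
growth increment): any larger f pins z just below its first integer crossing
and the network can never form an element at realistic growth rates — with
ν·Δ = 10⁻³, an f of 0.1 freezes the model entirely. The core `Network`
default is therefore 0 (pruning off). The bundled models set f = 0.005,
well below their boosted increment: besides its biological reading (unused
contacts decay), the term acts as the loop's damper. Unmatched element
backlogs are stored energy — when a matching partner finally appears, a
whole backlog converts to synapses within a few intervals and kicks the
network — and a small decay bleeds stale backlogs away while creating a
narrow deadband around the setpoint. Without it, desk-scale runs orbit the
setpoints in a structural limit cycle instead of converging.

**Faster excitatory dendrites on high-setpoint populations.** If all element
types grow at one rate, populations with low setpoints equilibrate first and
stop producing axonal elements, starving high-setpoint (inhibitory)
populations of excitatory input forever. Both bundled models therefore give
inhibitory populations' excitatory dendritic elements a 4× growth rate —
the two-population model by its standard parameters, the microcircuit as
part of the bundled illustrative parameter file.

**RNG discipline.** One master seed is split into independent named streams
(initial membrane potentials, Poisson drive, deletion sampling, matching
shuffles), so structural randomness replays independently of activity
randomness; a fixed seed yields bitwise-identical rasters and edge lists.
Initial membrane potentials are uniform on [v_reset, v_th), which
desynchronizes onset. Poisson drive is sampled exactly by inverse-CDF table
lookup (tail truncated at cumulative mass 1 − 10⁻¹⁵).

**Timing conventions.** Intervals are half-open [t, t+Δ): an event exactly on
a boundary belongs to the closing interval. Synaptic delays must be positive
multiples of dt (default 1 ms). During the absolute refractory period the
membrane is clamped to v_reset and inputs are discarded.

## Desk-scale study conditions and what they show

The bundled self-organization runs are scaled-down surrogates of runs that
originally occupied thousands of biological seconds:

* **Two-population network**: scale 0.1 (80 exc + 20 inh neurons), growth
  rates ×10, 500 biological seconds (~2 min wall). The full-scale protocol is
  1000 neurons for 3000 s; the surrogate keeps dt, the structural interval,
  β, τ, ε, η and the amplitude structure, and completes one
  overshoot–rewiring–settling cycle. The convergence measure is the
  population-mean calcium averaged over the final 20% of the run; across
  seeds 1–4 both populations land within a few percent of their setpoints.
  300 s is not quite enough for the rewiring episode to finish at this
  scale, hence 500 s.
* **Microcircuit**: scale 0.02 (~1540 neurons over 8 populations), growth
  rates ×10, 500 biological seconds, with the bundled *illustrative*
  setpoints (this model family fixes no numeric per-population setpoints;
  the bundled file preserves the qualitative structure — excitatory below
  inhibitory within each layer, L2/3e lowest). The numeric table came out of
  a stability exploration, which is itself part of the method: with no
  topology, all populations compete in one global matching pool, and widely
  spread excitatory setpoints (e.g. 0.05–0.08) frustrate one another into a
  slow structural limit cycle that undershoots on average, while the bundled
  tighter spread (0.05–0.065 excitatory, 0.12–0.14 inhibitory) settles with
  every population within a few percent of its target. Stronger inhibitory
  weights (2–4× the excitatory amplitude) collapse this substrate into a
  low-rate trap, so the bundled table keeps symmetric ±1 mV synapses.

What passing these runs does *not* show: behavior of the full-size networks
(finite-size effects at 100× fewer neurons are substantial — per-neuron
in-degrees, and hence the granularity of the homeostatic control, are much
coarser), stability at the unboosted growth rate over hours of biological
time, or realism of the electrical substrate (delta synapses, homogeneous
populations, no topology). The structural bookkeeping itself — conservation
between elements and synapses, uniform matching, rewiring semantics — is
exercised identically at any scale and is checked exactly.

## Numerical notes and degenerate inputs

* Calcium advance/growth integration are exact for the linear pieces; the
  Gaussian element update is first-order in the structural interval
  (verified by interval-refinement consistency tests).
* ⌊max(z,0)⌋ bookkeeping: upward crossings report new vacancies; downward
  crossings below the connected count trigger deletions, at most `connected`.
* Deletion needs are recomputed against live connected counts, so
  simultaneous deletions on both endpoints of one edge cannot double-free.
* Empty networks: percent-connectivity normalization refuses a zero total;
  a zero-duration run leaves the network untouched.
* Edge storage is append-plus-mask with lazy compaction (when more than half
  the slots are dead); indices are only valid within one structural update.

## Known limitations

* Single-process; networks beyond ~10⁴ neurons are impractical.
* Convergence of the *self-organization* (as opposed to correctness of the
  bookkeeping) depends on electrical parameters; the defaults document one
  working regime, not the boundary of the stable region.
* The microcircuit's reference-connectivity mode requires a user-supplied
  8×8 probability table; none ships with the package.
* User-defined growth rules beyond linear/Gaussian are not implemented (the
  `GrowthCurveSpec` kind field is the extension point).
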