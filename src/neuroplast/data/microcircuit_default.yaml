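# Illustrative default parameters for the eight-population cortical
# microcircuit builder. Population sizes follow the widely used layered
# column model; the growth targets (eps), minimum calcium levels (eta) and
# growth rates (nu) are ILLUSTRATIVE DEFAULTS chosen by this package so that
# the disconnected network self-organizes into a stable state: within each
# layer the excitatory setpoint lies below the inhibitory one, and L2/3e has
# the lowest target of all. The numeric values were fixed by a stability
# exploration (widely spread excitatory targets frustrate each other through
# the shared topology-free matching pool and produce structural limit cycles
# instead of settling). They are configuration values, not measurements;
# supply your own file to override any of them.
#
# eps/eta are dimensionless calcium concentrations (with beta = 0.001 and
# tau = 10^4 ms, eps = 0.05 corresponds to a 5 Hz target rate); nu is in
# elements/ms.

# nu_den_ex: growth rate of the excitatory dendritic elements. Inhibitory
# populations chase a higher activity target than their excitatory sources,
# so they must offer excitatory postsynaptic elements faster (4x here) than
# the sources themselves — otherwise the excitatory populations reach their
# setpoints first, stop producing axonal elements, and the inhibitory
# populations can never be driven to their targets.
populations:
  L23e: {size: 20683, eps: 0.05,  eta: 0.0, nu: 1.0e-4}
  L23i: {size: 5834,  eps: 0.12,  eta: 0.0, nu: 1.0e-4, nu_den_ex: 4.0e-4}
  L4e:  {size: 21915, eps: 0.06,  eta: 0.0, nu: 1.0e-4}
  L4i:  {size: 5479,  eps: 0.13,  eta: 0.0, nu: 1.0e-4, nu_den_ex: 4.0e-4}
  L5e:  {size: 4850,  eps: 0.065, eta: 0.0, nu: 1.0e-4}
  L5i:  {size: 1065,  eps: 0.14,  eta: 0.0, nu: 1.0e-4, nu_den_ex: 4.0e-4}
  L6e:  {size: 14395, eps: 0.055, eta: 0.0, nu: 1.0e-4}
  L6i:  {size: 2948,  eps: 0.12,  eta: 0.0, nu: 1.0e-4, nu_den_ex: 4.0e-4}

synapses:
  excitatory_amplitude: 1.0   # mV
  inhibitory_amplitude: -1.0  # mV
  delay: 1.0                  # ms

drive:
  rate: 10000.0      # Hz, independent Poisson generator per neuron
  amplitude: 0.125   # mV per external event; alone yields ~0.5 Hz sparse
                     # firing, which seeds the disconnected network

lif:
  tau_m: 10.0
  v_th: -55.0
  v_reset: -85.0     # hyperpolarizing reset damps synchronous avalanches
  e_l: -70.0
  t_ref: 2.0

calcium:
  tau: 10000.0
  beta: 0.001
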