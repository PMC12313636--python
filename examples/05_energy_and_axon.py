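"""Energy accounting of the hybrid neuron and a 30-compartment axon.

One biological second of OU-driven activity is integrated; the report gives
the |V|*|i| dissipation of the emulated potassium channel and of the whole
circuit in two unit conventions, plus a whole-brain extrapolation.  A chain
of 30 resistively coupled hybrid compartments then shows that the reduced
spike amplitude still supports a propagating spike wave.
"""

import numpy as np

import memhh as M

hh = M.HHParams()
nbox = M.MemristorParams.preset("nbox")
scales = M.ScalingFactors.preset("nbox")

stim = M.ou_process(M.OUSpec(duration=1000.0, seed=1))
trace = M.simulate_hybrid(hh, nbox, scales, stim)
rep = M.energy_report(trace, hh, nbox, scales)
print(f"spikes in 1 biological s: {rep.spike_count}")
print(f"K-channel mean power  (membrane units): {rep.mean_power_K * 1e6:.3f} uW")
print(f"full-circuit mean power (membrane units): {rep.mean_power_HH * 1e6:.3f} uW")
print(f"energy per spike (K channel): {rep.energy_per_spike_K * 1e9:.1f} nJ")
print(f"device-unit channel energy over the physical {rep.duration_phys_s:.2f} s: "
      f"{rep.E_K_device * 1e6:.1f} uJ")
print(f"whole-brain extrapolation (86e9 neurons): "
      f"{M.brain_extrapolation(rep.mean_power_HH):.1f} kW")

print("\n30-compartment axon, OU drive into compartment 0:")
axon_stim = M.ou_process(M.OUSpec(duration=300.0, seed=1))
tr = M.simulate_axon(M.AxonConfig(), hh, nbox, scales, axon_stim)
propagated, delays = M.propagation_metrics(tr)
print(f"wave propagated to the last compartment: {propagated}")
print(f"conduction delay to compartment 30: {delays[-1]:.1f} ms "
      f"({delays[-1] / 29:.2f} ms per compartment, monotone along the chain)")
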