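"""Simulate the reference point neuron and characterize it.

Builds the active single-compartment cell, drives it with a random 8:3
excitatory:inhibitory event train, and runs the quantal conductance sweep
that yields the subthreshold I/V relation and the AP threshold.
"""

import numpy as np

from surroneuron import (
    active_point_model,
    excitatory_synapse,
    inhibitory_synapse,
    simulate_point_neuron,
)
from surroneuron import stimgen
from surroneuron.biophys.point import steady_state_init
from surroneuron.experiments import quantal_sweep_experiment
from surroneuron.spikes import spike_times_ms

model = active_point_model()
init = steady_state_init(model)
print(f"resting potential after 2-s settling: {init.v:.2f} mV")

events = stimgen.random_train(2000.0, 160, seed=1)
trace = simulate_point_neuron(
    model, [excitatory_synapse(), inhibitory_synapse()], events, 2000.0, init=init
)
spikes = spike_times_ms(trace.v)
print(f"2-s random train (160 events, 8:3): {len(spikes)} APs, "
      f"V in [{trace.v.min():.1f}, {trace.v.max():.1f}] mV")

sweep = quantal_sweep_experiment()
print(f"quantal sweep: slope {sweep.summary.slope_mV_per_nS:.3f} mV/nS, "
      f"r = {sweep.summary.pearson_r:.4f}, "
      f"AP threshold {sweep.summary.ap_threshold_mV:.2f} mV "
      f"(first spike at {sweep.first_spiking_nS:.1f} nS)")
# The slope says how many mV of EPSP each nS of quantal conductance buys in
# the linear regime; the threshold is the maximal subthreshold depolarization.
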