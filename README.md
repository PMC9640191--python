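# surroneuron

Surrogate-neuron modeling: train sequence-forecasting networks to stand in
for conductance-based neuron models, then simulate recurrent circuits of
those surrogates orders of magnitude faster than compartmental integration
allows.

The package is aimed at computational neuroscientists who want to
(1) generate biophysical ground truth — Hodgkin–Huxley point neurons with
alpha/NMDA synapses and a small passive cable — (2) fit forecasting
architectures to it, and (3) run accelerated network experiments (for
example, parameter-space maps of a Rett-syndrome-like layer-5 recurrent
microcircuit) with the fitted surrogates as drop-in cells.

## The model in brief

A surrogate predicts the next membrane-potential sample from a 64-ms
history window of voltage and synaptic-input channels,

&nbsp;&nbsp;&nbsp;&nbsp;V̂(t) = f_θ( V(t−64…t−1), g_exc(t−64…t−1), g_inh(t−64…t−1) ),

trained by backpropagation on simulated traces and evaluated in closed
loop: after one ground-truth window, each prediction is fed back while
future synaptic inputs come from the stimulus protocol. Five architectures
are provided (linear, nonlinear, deep, dilated-convolutional, CNN-LSTM),
plus a 201-channel CNN-LSTM for multicompartment input, a fixed NMDA
voltage-gate layer, and a hard-coded Izhikevich spiking head
(v' = 0.04v² + 5v + 140 − u + I, u' = a(bv − u)) whose five parameters are
fitted by Nelder–Mead. Networks of surrogates are coupled by a
row-presynaptic connectivity matrix with Tsodyks–Markram short-term
plasticity (U = 0.38, D = 365.6 ms, F = 25.71 ms), five contact sites per
connection and 1-ms delivery delays, advanced by one batched forward pass
per millisecond. All neural-network layers and optimizers are implemented
in numpy with explicit backward passes (gradient-checked in the tests).

## Worked example

```python
import numpy as np
from surroneuron import (active_point_model, excitatory_synapse,
                         inhibitory_synapse, simulate_point_neuron)
from surroneuron import stimgen
from surroneuron.biophys.point import steady_state_init
from surroneuron.experiments import quantal_sweep_experiment

# characterize the reference active point neuron with a quantal sweep
sweep = quantal_sweep_experiment()
print(f"subthreshold slope  {sweep.summary.slope_mV_per_nS:.3f} mV/nS")
print(f"sweep linearity r   {sweep.summary.pearson_r:.4f} over "
      f"{sweep.summary.n_subthreshold} subthreshold trials")
print(f"AP threshold        {sweep.summary.ap_threshold_mV:.2f} mV "
      f"(first spike at {sweep.first_spiking_nS:.1f} nS)")
```

prints

```
subthreshold slope  2.319 mV/nS
sweep linearity r   0.9887 over 35 subthreshold trials
AP threshold        -56.79 mV (first spike at 3.6 nS)
```

i.e. single excitatory quanta of 0.1–3.5 nS produce linearly growing
EPSPs of ~2.3 mV per nS, the cell reaches at most −56.8 mV without firing,
and the first action potential appears at 3.6 nS. The `examples/`
directory contains one short narrative script per capability (simulation,
stimulus protocols, dataset building, training + closed-loop forecasting,
Izhikevich fitting, network sweeps), and the `surroneuron` command exposes
the same steps as thin subcommands (`surroneuron simulate --help`).

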