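# Methods

This note documents the models, numerical choices and study conditions
behind `surroneuron`, in the spirit of a simulator's model description: what
is computed, under which assumptions, and what the shipped defaults mean.

## Ground-truth biophysics

### Reference point neuron

The reference cell is a single cylindrical compartment, 25 um long and
25 um in diameter (lateral area ~1963 um^2), with Cm = 1 uF/cm^2,
Rm = 1 kOhm*cm^2 and axial resistivity 35.4 Ohm*cm (irrelevant for one
compartment, used by the cable stand-in). The passive variant carries only
the Rm leak, anchored at the -70 mV resting potential. The active variant
adds the classic squid-kinetics channel trio at gNa = 0.12, gK = 0.036 and
gLeak = 0.0003 S/cm^2 (ENa = +50, EK = -77, ELeak = -54.3 mV) *on top of*
the Rm leak; the two ohmic leaks fold exactly into one equivalent leak
(1.3 mS/cm^2 at -66.38 mV). We adopted the both-leaks reading after testing the
alternatives against the cell's reference characterization: with both
leaks the quantal-sweep intercept (-0.003 mV), subthreshold slope, sweep
linearity (r = 0.99) and maximal subthreshold depolarization (-56.8 mV)
all land on the reference values, while a channels-only cell rests at
-65 mV and fires at 0.9 nS, inconsistent with every one of them.

Synapses are alpha-conductance point processes,
g(t) = w (t/tau) exp(1 - t/tau), peaking at the quantal weight w at
tau after onset; excitatory tau = 2 ms, 2.5 nS, 0 mV and inhibitory
tau = 1 ms, 8 nS, -90 mV by default. NMDA-bearing synapses multiply the
alpha transient by a Boltzmann function of the instantaneous voltage,
A2 + (A1-A2)/(1 + exp((x0-v)/dx)) with A1 = 1, A2 = -1, x0 = -63.32 mV,
dx = 0.013 mV. The argument sign is chosen so the gate opens with
depolarization (relief of block); with dx = 0.013 mV the gate is effectively
a step at x0. Negative gate values are clamped to zero conductance during
integration.

### Integration

Gates and synaptic states advance by exponential (exact for the alpha
system) updates; the voltage by an implicit (backward) Euler step. The
internal step is 25 us; output is decimated to 1 kHz by keeping the sample
at each integer millisecond. Halving/doubling the internal step moves
subthreshold peak amplitudes by well under 1% (tested). Initialization
integrates the event-free model for 2 s from the analytic fixed point
(root-finding on the steady-state membrane current) and verifies the drift
is below 0.01 mV; non-convergence raises instead of returning a bad state.

### AP threshold convention

The model is a quasi-threshold (graded-response) system: with a marginal
stimulus the peak response varies continuously, so a dV/dt-criterion
measured on a barely-suprathreshold trial lands on the upstroke
(~-48 mV) rather than on the physiological threshold. Sweep-based
threshold is therefore reported as the **maximal subthreshold
depolarization**: the peak voltage of the largest non-spiking trial below
the smallest spiking one (the classical bracketing estimate). On the
0.1-3.5 nS sweep this gives -56.8 mV, with the first spike at 3.6 nS. A
dV/dt-based estimator (`spikes.ap_threshold_dvdt`, default 20 mV/ms) is
provided for trace-level use. Spikes on sampled traces are upward 0-mV
crossings, timed at the local maximum.

The subthreshold I/V summary fits peak amplitude against quantal
conductance by OLS over the *linear regime*: the initial run of trials
whose amplitude stays within 5% of the low-conductance linear prediction
(anchored on the first five trials). Near threshold the persistent-sodium
boost bends the curve upward; including those trials inflates the slope.
The reference axis convention reports the slope per 10 nS; `iv_summary` reports
mV/nS and the reproduction script scales by 10.

### KDR shift

The delayed rectifier's "shift" variant evaluates the n-gate rates at
(v - shift); a positive (rightward) shift needs stronger depolarization to
activate, so responses above the ~-67 mV activation region depolarize
relative to control, and symmetrically for leftward shifts; below that
region the variants are indistinguishable. Asserted as sign-of-difference,
not magnitude.

### Cable stand-in

The multicompartment model is an unbranched chain: the reference soma
(optionally active) plus a passive dendrite (default 500 um, 2 um
diameter) split into equal compartments, coupled by axial conductances from
Ri and the half-segment geometry, advanced by implicit Euler with a
tridiagonal (Thomas) solve. Synaptic sites map onto compartments evenly and
feed the 201-row dataset format. It reproduces cable attenuation and delay
and is deliberately **not** a reconstructed morphology: no branching, no
dendritic channels, no spines. Quantitative fidelity claims about detailed
reconstructions are out of scope here; tests assert discretization
convergence (refined-grid somatic peak within 1%) and qualitative cable
behavior only.

## Stimulus generators

All generators are pure functions of (parameters, seed) with onsets on the
1-ms grid (matching the 1 kHz channel encoding): uniform-random trains with
counts split 8:3 between excitation and inhibition (remainder to
excitation), quantal sweeps (0.1-3.5 nS in 0.1-nS steps), paired-pulse
trains (2-10 ms inter-stimulus intervals), normally distributed weights
(mean 2.5 nS, variance 0.001 nS^2 -- the nominal "nS" unit is read as a
variance), and E/I-ratio grids (2:1 and 1:2) with event counts proportional
to rate.

## Datasets and normalization

Each supervised example is a 64-sample history window (the window length
that the forecasting study found optimal) of voltage plus synaptic-input
channels -- pooled exc/inh columns for point neurons, 200 per-site rows for
the cable format, optionally I_Na/I_K -- and the target is the next sample
of the predicted channels. Voltage maps affinely from fixed physiological
bounds (-90, +40 mV) to [0, 1], so the inverse is model-independent;
out-of-bounds samples are clipped and counted. Detected spike peaks are
standardized to +40 mV before scaling because 1 kHz sampling truncates AP
peaks at arbitrary heights. Currents scale to [-1, 1] by their
training-split maximum; conductance channels by a fixed 0.1/nS.

Splits are contiguous 80/10/10 blocks per trace rather than shuffled
windows: overlapping windows shuffled across splits would leak almost the
entire test answer into training. Curriculum staging orders corpora
resting -> subthreshold -> suprathreshold, with a 0.3 replay fraction of
earlier stages mixed into later-stage batches (the replay share is a
package default; staged training with replay is the documented remedy for
catastrophic forgetting here).

## Architectures

Five point-neuron stacks (window 64, C input channels; parameter counts at
C = 5):

- linear: flatten -> 64-unit affine -> affine head (20,609)
- nonlinear: the same with a sigmoid hidden map (20,609)
- deep: 64-unit map + nine tanh layers 128/256/512/1024/1024/512/256/128/64
  with 0.15 dropout (2,465,729)
- convnet: 12 causal dilated convolutions, 128 filters, kernel 2, tanh,
  dilations 2^n, last-timestep head (363,393)
- cnn_lstm: convolutions 128/100/50 (kernels 1/5/1, relu/relu/tanh,
  He/He/Glorot-uniform init), flatten + length-1 repeat, two stacked
  128-unit LSTM layers, four 100-unit SELU layers with 0.15 dropout, affine
  head (1,949,251)

The recurrent stack's reference free-parameter count (1.95e6) corresponds
to two stacked LSTM layers (1,949,251 parameters; a single layer would
give 1.82e6), so the builder uses two. The repeat length after flattening is 1 (one-step
prediction); output heads carry 1, 3 or 6 units (voltage, +ionic currents,
or the three-site multi-output variant).

The multicompartment variant takes 201 channels: convolutions 512/256/128
with an L1 penalty (1e-5) on the first convolution, three 128-unit LSTM
layers, dense stack 128/100/100/100/100/head, plus a single trainable
additive output bias correcting the skew that the non-normally distributed
voltage targets induce (deliberately the simplest such correction). `extract_first_layer_filters` returns the first convolution's
weights and a filters x synapses selectivity matrix (max |w| over kernel
taps per synapse channel).

An NMDA gate layer can be inserted at the input: a frozen, non-trainable
layer that rescales the NMDA conductance channel by the Boltzmann gate of
the instantaneous normalized voltage (layer-space x0 = 1.44, dx = 0.12).

All layers, initializers (He/Glorot/LeCun uniform), losses and optimizers
are implemented in numpy with explicit backward passes inside the package
(`surroneuron.nn`); every layer's gradient is verified against central
finite differences in the test suite.

## Training

Default optimizer: Adam with Nesterov momentum (Nadam), gradient clipping
at global norm 1; Adamax for the multicompartment stack. Learning rates
(1e-3; 2e-3 for Adamax) and batch size (256) are package defaults, exposed
in `TrainingConfig`. Mean absolute error suffices for passive corpora;
active corpora use mean squared error to weight the rare AP samples. Early
stopping monitors validation loss with patience 10 (20 for the longer
corpus-level trainings) and restores the best checkpoint. Training is
deterministic under a fixed seed in single-threaded execution.
`partial_retrain` freezes everything below the fully connected head
(bit-identical before/after, tested) and retrains the head only -- the
mechanism used to adapt a trained surrogate to an altered biophysical
condition such as a shifted delayed rectifier.

## Closed-loop prediction

Teacher forcing predicts each next sample from ground-truth history.
Autoregressive (continuous self-reliant) prediction initializes with one
64-ms ground-truth window and then feeds each prediction back in
normalized space, unmodified; synaptic-input channels always come from the
scheduled protocol (bit-identity asserted), and predicted currents feed
back on their own channels. Runs sharing a horizon are batched into one
rollout.

## Evaluation

Explained variance is 1 - MSE/var(truth) (possibly negative). Spike
matching uses the 10-ms window as +/-5 ms around each true spike with
greedy one-to-one matching in ascending |shift| order, preventing
double-counting; precision with no predicted spikes is reported as 0 and
recall with no true spikes as 1, both flagged. Firing-rate transfer curves
are compared between a linear model and a 4-parameter logistic (divisive
normalization) by AIC in the Gaussian least-squares form n ln(RSS/n) + 2k;
a non-convergent logistic falls back to linear with a flag.

## Izhikevich spiking head

The hard-coded head integrates v' = 0.04 v^2 + 5v + 140 - u + I,
u' = a(bv - u), reset v <- c, u <- u + d at +30, one explicit update per
1 kHz sample scaled by a free time-step parameter dt (absorbing membrane
time-constant differences), plus a drive gain mapping physical current
(nA) into the dimensionless I -- the classic model is dimensionless, and a
pure (a, b, c, d, dt) set cannot both rest at the teacher's potential and
see correctly scaled input. The
recovery variable persists across steps outside any enclosing forecaster.
Four presets (tonic, adapting, bursting, fast-spiking) cover the
qualitative firing patterns.

Fitting is derivative-free (Nelder-Mead) with 20 seeded restarts on a
composite objective: normalized firing-rate error on current steps plus
subthreshold normalized MSE (1:1), with spurious subthreshold spikes
penalized gradually so the search can descend out of the spiking regime.
Two refinements make the search robust: a system-identification initial
guess (b from the teacher's resting potential; gain and dt from its input
resistance and membrane time constant via the local linearization), and a
staged schedule that first fits (a, b, dt, gain) on the subthreshold
objective alone before releasing all parameters; the incumbent is polished
by two simplex restarts.

The shipped fast-spiking teacher is a conductance-based cell with the
classic kinetics at reduced densities (gNa 0.07, gK 0.018, gLeak 0.00015
S/cm^2, no Rm leak): it rests near -65 mV, has a ~3 ms membrane time
constant, and fires sustained, non-adapting ~45-75 Hz trains across the
rising branch of its f-I curve. Two properties make it a fair teacher for
a quadratic integrate-and-fire head: its threshold sits a few millivolts
above rest (matching the head's fixed voltage geometry, so the rheobase of
the fitted head aligns with the teacher's and the sub-rheobase zeros of
the f-I table are reproduced), and its subthreshold response is close to
linear for small inputs. The characterization protocol: f-I from 2-s
current steps (0-0.2 nA, 20-pA increments, 200-ms settling discarded), and
subthreshold corpora of summed alpha-shaped current transients (tau 10 ms,
amplitudes 1-3 pA, halved automatically if the teacher fires) shared
sample-for-sample by teacher and head, with the head's output after
integrating drive sample t compared against teacher sample t+1 (the head
updates state first, the simulator records first). Explained variance is
reported on held-out waveforms. These conditions are the package's own
study definition for the teacher; larger-amplitude corpora
engage the teacher's near-threshold sodium nonlinearity, which no
two-variable quadratic model represents, and the achievable explained
variance drops accordingly (documented limitation, not a tunable).

## Recurrent network engine

All cells share one backend instance; a step advances the whole population
at once, so runtime per step is independent of connection count (delivery
is one matrix product). Connectivity samples each unordered pair:
reciprocal with probability 0.5 p_uni (weight multiplier 1.5), otherwise
one-way with probability p_uni in a random direction; rows are
presynaptic. Transmission follows the Tsodyks-Markram model with U = 0.38,
D = 365.6 ms, F = 25.71 ms, state kept per presynaptic cell (all five
contact sites of a connection see the same spike train, so their states
coincide; the delivered conductance is g_conn x multiplier x 5 x release).
Spikes are anchored at the AP peak sample and delivered +1 ms later onto
postsynaptic excitatory channels via a ring buffer. A delivery audit
(total delivered == scheduled) runs in every simulation.

The reference backend is the Izhikevich fast-spiking preset
with exponential synaptic filters (tau_e = 2 ms, tau_i = 1 ms) and
conductance-to-drive gains k_e = 0.4, k_i = 0.1; a trained forecasting
model drops in through `SurrogateBackend` for full reproduction. The
protocol: 100 ms pre-stimulus, one 50-nS perisomatic stimulus (calibrated
so that every cell of the reference network fires within 10 ms), 150 ms
observation. Instability = population APs before the stimulus (first 10 ms
of settling discarded); immediate response = cells firing within 10 ms
after it; a run is "stable" below 5 pre-stimulus APs (a named config
constant; any stability percentage is only meaningful relative to this
threshold). Background drive is an independent random 8:3 train per cell;
its statistics are a package choice: the default rate
(1500 events/s per cell) was calibrated once so that the reference network
sits near its reverberation threshold, where recurrent excitation scale
(applied to the recurrent quantal size) and connection probability visibly
control instability. Excitation scaling deliberately does not touch the
background; inhibition scaling applies to the background inhibitory
quantal size (the circuit carries no explicit inhibitory population).

## Problem sizes of the shipped reproductions

- Quantal sweep: 35 + up to 20 extension trials, 150 ms each (seconds).
- Spiking-head fit: 11 current steps x 2.2 s, three 2-s fit waveforms,
  five validation waveforms, 16-20 restarts (tens of seconds).
- Linear passive forecasting: 8 x 10-s traces (500 events each), training
  to early stopping (patience 20, <=150 epochs), fifty 500-ms rollouts on
  held-out trains (about a minute).
- Rett sweep: 150 cells x 250 ms, 3x2 grid x 3 repeats for the sign-level
  map; the grid and repeat count are configurable upward.

## Known limitations

- The cable stand-in is not a morphological reconstruction; numbers tied
  to reconstructed dendritic trees are out of scope.
- The quadratic spiking head cannot represent near-threshold sodium
  amplification; its subthreshold fidelity is only meaningful in the
  small-signal regime defined above.
- The engine's 1-ms delivery grid excludes sub-millisecond phenomena (gap
  junctions, jittered delays); the delay buffer supports integer
  milliseconds only.
- Reported reproductions use the seeded study conditions above; they are
  statements about these synthetic conditions, not about recordings from
  real neurons.
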