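# Methods

## Neuron model and simulation conventions

The simulator integrates current-based LIF neurons on a fixed grid of
Δt = 1 ms. The canonical update is the factored form

    u[k] = u[k-1] · d · (1 − θ[k]) + gain · I[k],     d = e^(−Δt/τ_m),
    θ[k] = 1{u[k-1] ≥ u_th}   (inclusive threshold),

with defaults u_rest = u_reset = 0, u_th = 0.3, τ_m = 9.4912 ms (d = 0.9).
The `(1 − θ)` factor is the embedded reset. For nonzero resting/reset
potentials the implementation generalizes to
`u = u_rest + [θ ? (u_reset − u_rest) : (u_prev − u_rest)·d] + gain·I`,
which reduces bitwise to the factored form at the defaults. The equivalent
piecewise reading is *reset-then-integrate*: on a spike step the membrane
restarts from u_reset and still receives the current arriving that step; a
reading that discards the input on reset steps would make the factored and
piecewise forms disagree whenever a spike coincides with input, so it is
not used.

**Timing.** The synaptic delay equals the simulation resolution: spikes
emitted at step k−1 produce the current applied at step k, and the spike at
step k is decided by the membrane after step k−1. Input at the first step
therefore can never elicit a first-step spike, and truncating an input
raster after step k leaves all spikes up to k unchanged (causality
property, tested). Within-step (zero-delay) propagation is deliberately
rejected.

Simulations start from rest (u = 0). There is no refractory period and no
conductance-based synapse model; synapses are pure current sources.

**`gain` = Δt/c_m.** The membrane-capacitance division of the continuous
model is folded into a single potential-per-unit-current factor. In
normalized units the default is 1 and any physical scale lives in the
weights.

## Network

Elman topology: N inputs → M liquid neurons (all-to-all recurrent,
self-connections included) → C readout neurons (no lateral connectivity, no
feedback into the liquid, no biases). W_ih and W_hh are i.i.d. uniform on
[−1/N, 1/N], frozen forever. The readout initialization is not part of the
frozen-weight law; it uses the analogous uniform(−1/M, 1/M) rule and is
configurable.

## Operating point of the packaged synthetic study

With binary rasters, uniform(±1/N) weights and u_th = 0.3, a gain of 1
leaves the liquid provably silent: even with all N inputs active every
step, the stationary membrane s.d. is ≈ 2.3·√N·(2/N)/√12 ≈ 0.06 for
N = 512, a 5σ shortfall from threshold. A functioning reservoir therefore
needs an operating gain. It was chosen once, by a firing-rate criterion
(not by task accuracy): sweeping gain over {4, 8, 12, 16, 20, 24, 28, 32,
40} and measuring the mean hidden firing rate on training rasters, gain 32
lands mid-band in the targeted 5–15 % fluctuation-driven regime (≈ 9 %).
`NeuronParams` keeps gain = 1 as the neutral default; the packaged config
sets 32.

## STBP readout training

Only W_ho is trained. Hidden rasters are constants of the optimization
(the liquid is frozen and the readout never feeds back), so they are
computed once per dataset; no optimizer state ever exists for W_ih/W_hh.
The loss is the squared distance between one-hot labels and mean readout
spike rates over the T-step window, averaged over samples; it is zero
exactly when the correct readout neuron fires every step and the rest stay
silent.

Backpropagation through time uses two standard STBP conventions: the reset
factor (1 − θ) is constant under differentiation, and the spike derivative
is replaced by a rectangular surrogate `(1/a)·1{|u − u_th| < a/2}` with
a = 1.0 (threshold units). Membranes reset at every sample boundary during
training, matching the independent-sample loss. Gradient correctness is
checked against an independent *forward-mode* sensitivity-propagation
oracle on small instances (T ≤ 3, M ≤ 3, C ≤ 2) to 1e−10.

**Optimizer.** The packaged study uses Adam at lr = 1e−3, batch 64,
20 epochs. Plain SGD works at small liquid sizes but its raw gradient
scale grows with the liquid's firing activity (the drive into the readout
is a sum over ~0.1·M active hidden channels multiplied by the gain); for
M = 256 this makes fixed-step SGD seed-fragile — weights overshoot until
readout membranes leave the surrogate window, gradients vanish, and the
fit stalls at chance. Adam's per-parameter normalization removes the size
dependence; across five independent seed sets and M ∈ {64, 128, 256}
test accuracy was ≥ 94 % everywhere and ≥ 99.5 % at M = 256. Both
optimizers remain available in `TrainConfig`.

## Weight quantization

`w_q = Δ·round(w/Δ)` with Δ = s·2^(1−b) and s = max|w| fitted per matrix
(W_ih and W_hh have different distributions). Rounding is ties-to-even for
bit-exact reproducibility. Zero is always a level, so [−s, s] carries at
most 2^b + 1 levels and the error bound |w − w_q| ≤ Δ/2 holds on [−s, s];
values outside (possible only with percentile scales) are lattice-rounded
without clipping. For b = 1 the lattice is {−s, 0, s}; a strict two-level
`s·sign(w)` mode is provided separately, since a genuinely binary scheme
cannot contain zero. W_ho and the neuron parameters are never quantized,
and because the quantized matrices never train, quantize-before-training
and quantize-after-training are literally identical.

## Event I/O and binning

The on-disk dialect is the 5-byte N-MNIST AER record (x, y, polarity bit,
23-bit µs timestamp); encoding and decoding are bit-exact inverses,
property-tested on random streams. Binning maps a stream onto a
T × (2·H·W) raster with half-open bins `[k·window/T, (k+1)·window/T)` and
polarity-major, row-major channel order `p·H·W + y·W + x` (0-based).
A raster cell is 1 iff at least one event fell into it — the natural input
for one-spike-per-step neurons; a count-preserving variant exists for
diagnostics, and the binarized raster is exactly the support of the count
raster. Events beyond the window are dropped and counted.

Two time mappings are supported for long recordings driven through a short
stimulus window: `compress` (default; the whole duration is divided into T
frames, so 300 ms → 25 frames ≈ 12 ms of real time per 1 ms step) and
`truncate` (first T·Δt ms at native resolution). Compression uses all the
events and is the packaged default.

## Synthetic study conditions

The generator emulates what a DVS sees when a rigid stimulus sweeps the
field of view: class c moves a 2-pixel bar east/west/south/north across a
16×16 grid over 300 ms (classes ≥ 4 use dots on diagonal trajectories);
pixels the stimulus enters emit Poisson(2.0) ON events, pixels it leaves
emit OFF events, timestamps get 1 ms Gaussian jitter, and both polarities
receive uniform background noise at 0.001 events/ms/pixel. 100 training
and 50 test streams per class, with disjoint seed streams for the two
splits. These conditions were fixed before any accuracy was measured.

What the generator does **not** emulate: per-pixel refractory behavior and
hot pixels, luminance-dependent event rates, saccade micro-trajectories,
multi-object scenes, and the heavy-tailed per-frame event counts of real
N-MNIST. Passing the packaged study therefore demonstrates that the
pipeline extracts class-dependent spatio-temporal structure from sparse
two-polarity event data — not that any particular accuracy carries over to
real recordings.

## Streaming inference

Streaming mode presents samples back-to-back: 25 ms stimulus + 25 ms
relaxation per sample, membrane state persisting throughout. The rhythmic
inhibitory neuron of the hardware implementation is modeled as a scheduled
current injection into every hidden neuron at the first relaxation step —
the neuron fires deterministically at fixed intervals, so the schedule is
behaviorally equivalent and simpler to reason about. The pulse targets the
liquid only; readout membranes decay naturally. Spike counts for
classification come exclusively from the stimulus window.

The pulse magnitude trades off two failure modes. Too weak, reverberating
liquid activity leaks into the next sample; too strong, the
hyperpolarization residual (inh·gain·d^relax_steps) outlasts the
relaxation and suppresses the next sample's onset — at d = 0.9 and 25
steps, 8 % of the pulse survives, so a pulse of −100·u_th in membrane
units still biases the next window by −8·u_th and measurably breaks
batch/streaming agreement. The packaged value (−0.05 in weight units,
≈ −5.3·u_th in membrane units after the gain) sits past the quench knee
with a residual under u_th/2. With relaxation long enough for the decay to
underflow, streaming reproduces batch predictions exactly (tested).

Ties in the spike-count argmax break toward the lowest class index; silent
samples are flagged, not rejected.

## Problem sizes

The packaged study (400 training + 200 test streams, N = 512, T = 25,
M up to 256, 20 epochs) was sized so the full test suite and the
reproduction script each finish in well under a minute on a single CPU
while still exercising every pipeline stage at realistic dimensionality.

## Known limitations

- The simulator is dense; very large liquids (M ≫ 10⁴) would need sparse
  or chunked rollouts.
- The rate loss only constrains mean rates; temporal spike placement within
  the window is unconstrained.
- The rectangular surrogate has zero gradient outside its window; badly
  scaled readout drives can still produce dead units (mitigated by Adam and
  the documented operating point).
- Conductance synapses, refractory periods, axonal delay distributions and
  sparse reservoir topologies are out of scope.
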