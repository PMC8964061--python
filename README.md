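# lsmkit — a Liquid State Machine toolkit for event-based classification

`lsmkit` implements a complete Liquid State Machine (LSM) pipeline for
classifying event-camera (DVS) data with spiking neural networks: a
discrete-time leaky integrate-and-fire (LIF) reservoir with frozen random
weights, a readout layer trained by spatio-temporal backpropagation (STBP)
on a spike-rate loss, uniform weight quantization of the reservoir, AER
event-stream I/O with frame binning, and two inference engines — batch
(state reset between samples) and streaming (persistent state with a
rhythmic inhibitory reset pulse, as used on neuromorphic hardware).

It is aimed at researchers studying reservoir computing with spiking
networks and at anyone prototyping spiking classifiers destined for
neuromorphic processors, where only the readout is trained and the frozen
reservoir must survive aggressive weight quantization.

## The model

Every neuron is a current-based LIF unit on a fixed grid of step Δt:

```
u_j[k] = u_j[k-1] · d · (1 − θ_j[k]) + (Δt/c_m) · I_j[k]        d = e^(−Δt/τ_m)
θ_j[k] = 1  iff  u_j[k-1] ≥ u_th
```

The `(1 − θ)` factor embeds the post-spike reset. The defaults are the
canonical 0.9-decay membrane: τ_m = 9.4912 ms at Δt = 1 ms, u_th = 0.3,
u_rest = u_reset = 0, no biases anywhere.

The network is an Elman-topology spiking net: N input channels fully
connected to a liquid of M recurrent neurons (all-to-all, one-step synaptic
delay), liquid fully connected to C readout neurons (no lateral readout
connections). Input and recurrent matrices are drawn i.i.d. uniform on
[−1/N, 1/N] and are **never trained**; only W_ho (C×M) is fitted, by BPTT
with a rectangular surrogate spike derivative, minimizing

```
ℓ = (1/S) Σ_s ‖ y_s − (1/T) Σ_t θ_{s,t} ‖²
```

so the readout neuron of the correct class is driven toward firing every
step. Classification is spike-count argmax over the stimulus window.
Reservoir weights can be quantized to b bits on the lattice
`w_q = Δ·round(w/Δ)`, `Δ = s·2^(1−b)` with scale `s = max|w|`, without
retraining — the quantization is training-agnostic because the quantized
matrices never train.

## Worked example

The packaged synthetic study (`configs/synthetic.yaml`) emulates DVS
recordings: four classes of bars sweeping a 16×16 pixel grid in different
directions over 300 ms, emitting Poisson ON bursts on pixel entry and OFF
bursts on exit plus background noise, binned to 25 frames with two polarity
channels (N = 512).

```python
from lsmkit import LSMClassifier, synthetic_experiment_config
from lsmkit.experiment import make_synthetic_rasters

cfg = synthetic_experiment_config()
Xtr, ytr, Xte, yte = make_synthetic_rasters(cfg)

clf = LSMClassifier(Xtr, ytr, hidden_size=128, neuron=cfg.neuron, seed=cfg.weight_seed)
res = clf.fit(cfg.train)
print(res.summary())
print(f"batch test accuracy:     {100 * res.score(Xte, yte):.1f}%")
print(f"streaming test accuracy: {100 * res.score(Xte, yte, mode='streaming', schedule=cfg.schedule):.1f}%")
print(f"2-bit reservoir accuracy: {100 * res.quantized(bits=2).score(Xte, yte):.1f}%")
```

prints

```
LSM classifier fit (STBP readout training)
==============================================
input channels                             512
liquid size M                              128
classes C                                    4
trainable parameters                       512
frozen parameters                        81920
membrane decay d                      0.900000
threshold u_th                             0.3
gain (dt/c_m)                               32
optimizer                                 adam
learning rate                            0.001
epochs                                      20
final rate loss                       0.186508
==============================================
batch test accuracy:     99.5%
streaming test accuracy: 98.0%
2-bit reservoir accuracy: 97.0%
```

i.e. a 128-neuron liquid with 512 trained parameters separates the four
spatio-temporal classes almost perfectly; streaming inference (25 ms
stimulus + 25 ms relaxation with the inhibitory quench pulse) agrees with
batch inference, and 2-bit reservoir weights cost ~2 accuracy points.

The same pipeline is available from the shell:

```bash
lsm gen-data --out data/              # synthetic AER dataset (5-byte N-MNIST dialect)
lsm train    --out model.npz --loss-out loss.txt
lsm eval     --model model.npz --mode streaming
lsm quantize --model model.npz --bits 2 --out model_q2.npz
lsm trace    --model model.npz --out trace.npz   # membrane/raster dumps for plots
```

`lsm` also reads N-MNIST-format directories (`<split>/<label>/<sample>.bin`)
via `--data`, so real 34×34 recordings can be dropped in unchanged.

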