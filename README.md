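# mfsnn — multiscale-fusion spiking decoding of invasive BCI signals

Chronic intracortical brain-computer interfaces must decode motor intent
from multi-channel spike recordings *stably across days*, even though
electrode drift, tissue response and neural plasticity shift the signal
distribution between sessions — and they must do it within the power
budget of an implantable device. `mfsnn` implements a spiking neural
network decoder built for exactly this setting, together with a
synthetic multi-session benchmark that reproduces the statistical
structure of the problem (tuned motor-cortex populations, trial
structure, session-to-session drift) and an energy-accounting module
that quantifies why spike-driven computation is cheap.

## The model

The input is a trial of binned spike counts with `Nc` channels and `T`
time bins. It is split into `Ns` contiguous blocks of `C = Nc / Ns`
channels, each processed by a parallel **sub-encoder** with three
branches:

* **LT** — a learnable linear time compression `LT_out = Input · M_l`
  (`M_l ∈ ℝ^{T×T'}`), a raw-data-level skip path;
* **CA** — spiking channel attention: global average pooling gives a
  per-channel summary `f_s`, and a bottleneck of two 1×1 spiking
  convolutions with leaky integrate-and-fire (LIF) activations,
  `w̃_c = SConv2d(SConv2d(f_s))`, yields a per-channel weight in [0, 1]
  (the final LIF layer's time-averaged spike rate);
* **TCN** — a depthwise causal dilated convolution
  `x'_t = b + Σ_{i=1..k} w_i · x_{t-(k-i)d}` (k = 3, d = 2, left
  zero-padding `(k−1)d = 4`) followed by window-`p` average pooling,
  `p = T / T'`.

The branches fuse as `E_i = LT_out + w̃_c · TCN_out`; the `Ns` fused
features concatenate to `E_out ∈ ℝ^{Nc×T'}`, which drives a spiking
classifier: the flattened feature is injected as a constant current into
a LIF layer for a 20-step time window and the spike rates feed a fully
connected readout. LIF units follow `V[t] = λ·V[t−1] + I[t]`, spiking
when `V ≥ θ` with a hard reset; training uses surrogate gradients (a
sigmoid-derivative stand-in for the spike step) with
backprop-through-time, Adam (batch 32) and a cosine-annealed learning
rate from 0.01 to 0.0001. A structurally identical non-spiking twin
("MFANN": rectifiers in place of LIF, logistic squashing for the
attention weights) serves as the energy comparator.

**Energy accounting.** A spiking layer costs
`SOPs(l) = Rate × T × FLOPs(l)` accumulate operations, against one
multiply-accumulate per FLOP for the twin; with 45 nm constants
`E_MAC = 4.6 pJ`, `E_AC = 0.9 pJ` the encoder totals are
`E = E_AC · Σ_i (SOP_LT_i + SOP_CA_i + SOP_TCN_i)` versus
`E_MAC · Σ FLOPs`. A layer is cheaper spiking exactly when
`Rate × T < E_MAC / E_AC ≈ 5.11`.

**Cross-day protocol.** Train on one session; for each later session,
adapt on a small stratified fraction of its trials (fine-tuning) and
evaluate on the untouched remainder. At ~300 trials/day of 2–4 s each,
an 8 % fraction is 24 trials, i.e. only **48–96 s** of new-session
recording.

## Worked example

```python
import numpy as np
from dataclasses import replace
from mfsnn import (DriftSpec, FinetuneConfig, MFSNN, ModelConfig,
                   PopulationSpec, TrainConfig, make_cross_day_benchmark)
from mfsnn.training import train, evaluate, finetune

spec = PopulationSpec(n_channels=64, paradigm="center_out_8")
day0, day1 = make_cross_day_benchmark(spec, 2, 300, DriftSpec(), seed=101)

model = MFSNN(ModelConfig.build(n_channels=64, n_subencoders=8, n_classes=8, seed=1))
train(model, (day0.spikes[:200].astype(float), day0.labels[:200].astype(int)),
      TrainConfig(epochs=30, seed=1))
print("within-session:", evaluate(model, (day0.spikes[200:].astype(float),
                                          day0.labels[200:].astype(int))))
print("next day, zero-shot:", evaluate(model, day1))

tuned, manifest = finetune(model.copy(), day1, FinetuneConfig(fraction=0.08, seed=1))
idx = np.asarray(manifest["test_indices"])
print("next day, fine-tuned:", evaluate(tuned, (day1.spikes[idx].astype(float),
                                                day1.labels[idx].astype(int))))
```

Output:

```
within-session: 97.0
next day, zero-shot: 80.0
next day, fine-tuned: 84.05797101449275
```

Within-session decoding of the 8-direction task is near-ceiling; one
simulated day of electrode drift costs ~17 percentage points zero-shot,
and fine-tuning on 24 labelled trials (8 %) recovers a good part of it
(averages over seeds are reported by the acceptance script below).

The same pipeline is available from the shell (`mfsnn simulate`,
`train`, `finetune`, `evaluate`, `crossday`, `energy`, `ablate`); every
run writes a config snapshot and seed record sufficient to reproduce it.

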