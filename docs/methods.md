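# Methods

This note documents the scientific and numerical choices behind the
package: the neuron model and its training, the architecture, the
energy-accounting conventions, what the synthetic benchmark does and
does not emulate, and the design decisions taken where more than one
reasonable reading existed.

## Neuron model

All spiking nonlinearities are layers of independent discrete-time LIF
units:

    V[t]      = leak · V_post[t−1] + I[t]
    s[t]      = 1{ V[t] ≥ threshold }
    V_post[t] = V[t] · (1 − s[t])        (hard reset, default)
              | V[t] − threshold · s[t]  (subtract reset)

Defaults: `threshold = 1.0`, `leak = 1.0` (a pure integrator — the
simplest dynamics consistent with rate-based readouts, and the one with
a closed form usable as a test oracle), hard reset, `n_steps = 20`
(a 20 ms window at 1 ms resolution), and zero initial potential at
every forward pass so no state leaks across trials or batches. With
`leak = 1` and hard reset, a constant current `I ∈ (0, θ]` produces a
perfectly periodic train with inter-spike interval `ceil(θ / I)`; the
tests exercise this closed form on a grid of dyadic currents `k/64` so
that the floating-point membrane sums are exact and the real-arithmetic
formula applies verbatim.

**Surrogate gradient.** The spike step has measure-zero support for its
derivative, so the backward pass substitutes
`σ'(slope · (V − θ)) · slope` with `slope = 5.0` — finite everywhere,
peaked at threshold. Backprop-through-time detaches the reset term (the
spike indicator inside the reset is treated as a constant), the common
convention that keeps the recurrent gradient stable. The whole model and
its adjoint are hand-written in numpy; correctness of the shared
backward machinery is established by central-difference checks in ANN
mode (where the model is genuinely differentiable) and by
loss-decrease / finite-nonzero-gradient contracts in spiking mode.

## Architecture conventions

* **Channel split** is contiguous in recorded order. Any fixed
  permutation is equivalent up to relabeling; a numerical symmetry test
  confirms that permuting whole sub-paths together with their parameters
  and classifier columns leaves the logits unchanged.
* **TCN padding.** The causal dilated convolution left-pads by
  `(k−1)·d = 4` zeros so output length equals input length and no
  future sample is read. Pooling windows are non-overlapping and must
  tile `T` exactly; an indivisible `T / T'` is a configuration error
  rather than a silent truncation.
* **Attention weights.** The channel-attention bottleneck
  (`C → C/r → C`, default `r = 2`) is spiking; its output spike train is
  converted to a scalar per-channel weight as the final LIF layer's
  time-averaged rate — bounded in [0, 1] and differentiable through the
  surrogate. The fusion `E_i = LT_out + w̃_c · TCN_out` scales only the
  TCN term, reading the fusion equation literally.
* **LT branch** is analog (a plain learnable matrix): the defining
  equation contains no spiking operator. Default `T' = 5` with `T = 20`
  (`p = 4`).
* **Classifier readout** uses spike rates, not membrane potentials:
  the spiking layer produces sparse binary features which the fully
  connected layer decodes. Argmax ties break to the lowest class index
  for determinism.
* **ANN twin.** Rectifiers replace the LIF layers, a logistic squashing
  keeps attention weights in [0, 1], and the time window collapses to a
  single step. Parameter shapes and per-layer FLOPs are identical to
  the spiking model by construction, which the tests verify.
* **Initialisation.** `M_l` starts near the block-averaging map (plus
  small noise) so early fused features are non-negative and the
  downstream LIF units start responsive; TCN kernels and attention
  weights use small scaled-normal draws, attention biases start at 0.5
  to guarantee initial spiking activity. All initial draws flow from
  the model config seed.

## Training and the cross-day protocol

Cross-entropy on the logits, Adam with batch size 32, cosine annealing
from 0.01 to 0.0001 over the epoch budget (default 50; the desk-scale
experiments use 30, which suffices at their problem size). Single-day
evaluation uses a stratified 8:2 split. Fine-tuning selects
`floor(f · n)` trials, stratified by class (a class receiving zero
trials is recorded as a warning, not an error), optimizes either all
parameters (default) or the classifier only, and reserves every
unselected trial for testing; the emitted manifest lists both index
sets so the no-leakage property is auditable.

Fine-tuning runs 20 epochs at a constant learning rate of 3e-4. An
earlier default of 1e-3 (one tenth of the training peak) proved too
aggressive: with a 2 % fraction — six trials for eight classes — twenty
Adam steps at 1e-3 drag the model several points *below* its zero-shot
accuracy, breaking the expected monotone improvement with fraction.
At 3e-4 the recovery curve is monotone across (0, 2, 4, 8, 16) % and
8 %-fraction recovery is slightly better as well.

## Energy accounting

FLOPs are MAC counts: `C·T·T'` for the time-compression matrix,
`C·T·k` for the depthwise convolution, `C_in·C_out` for the 1×1
bottleneck convolutions, `C·T'` for the attention scaling, and
`n_in·n_out` for the readout; pooling, biases and the fusion sum are
additions and count zero. `SOPs = Rate × T × FLOPs` with `T` the LIF
window. Rates are measured per layer from the batch: layers fed by
actual spike trains use the train's empirical mean; layers fed by
analog binned counts (LT, the TCN convolution, the attention
compressor) use the convention that a count of `n` in a `bin_ms` bin is
`n` spikes over `bin_ms` 1 ms steps, i.e. a per-step probability
`n / bin_ms`, clipped to [0, 1]. The headline encoder total sums only
the LT/CA/TCN branch SOPs across sub-encoders — the classifier is
profiled and reported on its own line but excluded from that total,
following the encoder-only summation convention; both numbers are in
the report.

## The synthetic benchmark

No public dataset exists for the targeted recordings, so the package
generates its own, emulating the two paradigms' statistical structure:

* **center_out_8** — cosine-tuned channels,
  `r_c(θ) = max(0, b_c + m_c·cos(θ − θ_c))`, the classic M1 rate model;
* **grasp_touch_4** — per-channel Gaussian class loadings,
  `r_c(class) = max(0, b_c + L[c, class])`.

Rates are shaped by a per-bin phase envelope (0.5 during the baseline
quarter, ramping to 1.0 by the trial midpoint, sustained through the
action phase) and counts are Poisson per 50 ms bin, 20 bins per trial.
Drift between sessions combines per-channel log-normal gain
(`σ = 0.15`), tuning loss ("dropout", p = 0.15), preferred-direction
jitter (0.4 rad; reinterpreted as a loading perturbation of 0.4 loading
SDs in the discrete-class paradigm) and additive baseline shifts
(2 spikes/s). Later sessions drift independently from the base
population so the expected distance from session 1 is constant and
seed-isolated; a `random_walk` flag chains drifts instead. Baselines
are uniform on 5–20 spikes/s and modulations on 3–12 spikes/s: these
levels were calibrated once so that within-session decoding sits above
90 % but below ceiling and one session of default drift costs roughly
15 accuracy points — enough head-room to resolve drift, fine-tuning and
ablation effects — and are fixed.

What the generator does *not* emulate: spike waveforms and sorting
artifacts, non-Poisson count statistics (refractoriness,
overdispersion), correlated noise across channels, within-session
non-stationarity, and behavioral variability in trial timing. Passing
tests therefore demonstrate that the decoder and protocol behave
correctly under the assumed generative structure, not that any
particular accuracy level transfers to real recordings.

Desk-scale experiment sizes (64 channels, 8 sub-encoders, 200 training
/ 100 test trials, 30 epochs, 5 seeds) were chosen as the smallest
configuration at which all the qualitative effects are resolved
cleanly.

## Known limitations

* The ablation analysis shows the attention branch contributes little
  to *mean* accuracy on this benchmark (its original motivation is
  robustness rather than average performance); the comparison test
  uses a low-data regime where branch contributions separate.
* Fine-tuning at very small fractions leaves some classes unrepresented
  and relies on the gentle learning rate for stability.
* Energy numbers are theoretical op counts under the stated
  conventions, not hardware measurements; the measured reduction
  depends on the input's firing statistics.
* The numpy implementation is single-threaded and sized for
  desk-scale experiments, not for the ~2,000-trial sessions of a full
  center-out day — those run, but training takes correspondingly
  longer.
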