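"""One parallel sub-path of the encoder.

Each sub-encoder sees a contiguous block of ``C`` of the recording's
channels over ``T`` time bins and produces a fused ``C x T'`` feature by
combining three branches:

* **Linear transformation (LT)** — a learnable ``T x T'`` matrix applied
  per channel, compressing the time axis and passing raw-data-level
  structure straight through (a skip connection in time).
* **Channel attention (CA)** — global average pooling over time gives a
  per-channel summary ``f_s``; a spiking bottleneck (1x1 conv ``C -> C/r``,
  LIF, 1x1 conv ``C/r -> C``, LIF) turns it into a per-channel weight in
  ``[0, 1]``, read out as the final LIF layer's time-averaged spike rate.
* **Temporal convolution (TCN)** — a depthwise causal dilated convolution
  (kernel ``k``, dilation ``d``, left zero-padding ``(k-1)*d`` so the
  length is preserved and no future sample is read) followed by
  non-overlapping average pooling with window ``p = T / T'``.

The branches fuse as ``E_i = LT_out + w_c * TCN_out`` with the attention
weight broadcast over time.

The functions here are single-trial, single-purpose reference
implementations; the batched network in :mod:`mfsnn.model` must agree
with their composition exactly, which the test-suite checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lif import LIFParams, lif_run, rate_encode, spike_rate

__all__ = [
    "SubEncoderConfig",
    "linear_transform",
    "global_avg_pool",
    "channel_attention",
    "causal_dilated_conv",
    "temporal_avg_pool",
    "tcn_forward",
    "fuse",
    "encode",
]


@dataclass(frozen=True)
class SubEncoderConfig:
    """Hyperparameters of one sub-encoder.

    ``pool_window`` is derived as ``T // T_prime`` and must divide ``T``
    exactly; ``C`` must be divisible by the attention bottleneck ratio
    ``bottleneck_ratio``.
    """

    C: int = 8
    T: int = 20
    T_prime: int = 5
    kernel_size: int = 3
    dilation: int = 2
    bottleneck_ratio: int = 2
    lif_params: LIFParams = field(default_factory=LIFParams)

    def __post_init__(self) -> None:
        if self.T_prime < 1 or self.T < 1:
            raise ValueError("T and T_prime must be >= 1")
        if self.T % self.T_prime != 0:
            raise ValueError(
                f"T={self.T} must be divisible by T_prime={self.T_prime}"
            )
        if self.C % self.bottleneck_ratio != 0:
            raise ValueError(
                f"C={self.C} must be divisible by bottleneck_ratio="
                f"{self.bottleneck_ratio}"
            )
        if self.kernel_size < 1 or self.dilation < 1:
            raise ValueError("kernel_size and dilation must be >= 1")

    @property
    def pool_window(self) -> int:
        return self.T // self.T_prime


def linear_transform(x: np.ndarray, M_l: np.ndarray) -> np.ndarray:
    """``LT_out = x @ M_l`` per channel: (C, T) x (T, T') -> (C, T')."""
    x = np.asarray(x, dtype=float)
    M_l = np.asarray(M_l, dtype=float)
    if x.ndim != 2 or M_l.ndim != 2 or x.shape[1] != M_l.shape[0]:
        raise ValueError(
            f"incompatible shapes for linear transform: {x.shape} @ {M_l.shape}"
        )
    return x @ M_l


def global_avg_pool(x: np.ndarray) -> np.ndarray:
    """Per-channel mean over time: (C, T) -> (C,)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] < 1:
        raise ValueError("global_avg_pool expects a non-empty (C, T) array")
    return x.mean(axis=1)


def channel_attention(
    x: np.ndarray,
    W1: np.ndarray,
    b1: np.ndarray,
    W2: np.ndarray,
    b2: np.ndarray,
    lif_params: LIFParams,
) -> np.ndarray:
    """Spiking squeeze-and-excite: per-channel weights in [0, 1].

    ``W1`` is ``(C/r, C)`` (the compressing 1x1 conv), ``W2`` is
    ``(C, C/r)`` (the expanding one).  The pooled summary drives the
    first LIF layer as a constant current; the second spiking conv is
    applied step-by-step to the first layer's spikes; the returned
    weight is the second LIF layer's mean spike rate.
    """
    f_s = global_avg_pool(x)
    C = f_s.shape[0]
    if W1.shape[1] != C or W2.shape[0] != C or W1.shape[0] != W2.shape[1]:
        raise ValueError(
            f"attention kernel shapes {W1.shape}/{W2.shape} do not match C={C}"
        )
    u1 = W1 @ f_s + b1
    s1 = lif_run(rate_encode(u1, lif_params), lif_params)
    currents2 = s1 @ W2.T + b2  # (n_steps, C)
    s2 = lif_run(currents2, lif_params)
    return spike_rate(s2)


def causal_dilated_conv(
    x: np.ndarray, weights: np.ndarray, bias: float, dilation: int
) -> np.ndarray:
    """Length-preserving causal dilated convolution of one channel.

    ``x'_t = b + sum_{i=1..k} w_i * x_{t - (k - i) d}`` with out-of-range
    samples read as zero (left zero-padding of ``(k-1)*d``).  The output
    never depends on samples later than ``t``.
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("causal_dilated_conv expects a non-empty 1-D sequence")
    if dilation < 1:
        raise ValueError(f"dilation must be >= 1, got {dilation}")
    k = w.size
    T = x.size
    padded = np.concatenate([np.zeros((k - 1) * dilation), x])
    out = np.full(T, float(bias))
    for i in range(k):  # tap i+1 sits (k-1-i)*d samples in the past
        out += w[i] * padded[i * dilation : i * dilation + T]
    return out


def temporal_avg_pool(x: np.ndarray, p: int) -> np.ndarray:
    """Non-overlapping mean pooling with window ``p``; requires p | T."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("temporal_avg_pool expects a non-empty 1-D sequence")
    if p < 1 or x.size % p != 0:
        raise ValueError(f"pool window {p} must divide sequence length {x.size}")
    return x.reshape(-1, p).mean(axis=1)


def tcn_forward(
    x: np.ndarray,
    kernels: np.ndarray,
    biases: np.ndarray,
    config: SubEncoderConfig,
) -> np.ndarray:
    """Depthwise TCN branch: per-channel conv then pooling, (C,T)->(C,T')."""
    x = np.asarray(x, dtype=float)
    if x.shape != (config.C, config.T):
        raise ValueError(f"expected input shape {(config.C, config.T)}, got {x.shape}")
    kernels = np.asarray(kernels, dtype=float)
    biases = np.asarray(biases, dtype=float)
    out = np.empty((config.C, config.T_prime))
    for c in range(config.C):
        conv = causal_dilated_conv(x[c], kernels[c], biases[c], config.dilation)
        out[c] = temporal_avg_pool(conv, config.pool_window)
    return out


def fuse(lt_out: np.ndarray, weights: np.ndarray, tcn_out: np.ndarray) -> np.ndarray:
    """``E_i[c, t] = lt_out[c, t] + w[c] * tcn_out[c, t]``."""
    lt_out = np.asarray(lt_out, dtype=float)
    tcn_out = np.asarray(tcn_out, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if lt_out.shape != tcn_out.shape or weights.shape != (lt_out.shape[0],):
        raise ValueError(
            f"fuse shape mismatch: lt {lt_out.shape}, tcn {tcn_out.shape}, "
            f"w {weights.shape}"
        )
    return lt_out + weights[:, None] * tcn_out


def encode(x: np.ndarray, params: dict, config: SubEncoderConfig) -> np.ndarray:
    """Full sub-encoder: fuse(LT(x), CA(x), TCN(x)).

    ``params`` holds ``Ml`` (T x T'), ``tcn_w`` (C x k), ``tcn_b`` (C,),
    ``ca_W1``/``ca_b1``/``ca_W2``/``ca_b2`` for the attention bottleneck.
    """
    lt = linear_transform(x, params["Ml"])
    w = channel_attention(
        x,
        params["ca_W1"],
        params["ca_b1"],
        params["ca_W2"],
        params["ca_b2"],
        config.lif_params,
    )
    tcn = tcn_forward(x, params["tcn_w"], params["tcn_b"], config)
    return fuse(lt, w, tcn)
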