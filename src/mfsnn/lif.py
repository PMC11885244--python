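"""Leaky integrate-and-fire neuron dynamics and surrogate gradients.

Every spiking nonlinearity in the network is a layer of independent LIF
units.  A unit integrates input current into a membrane potential with a
multiplicative leak, emits a binary spike when the potential crosses a
threshold, and then resets.  The discrete-time update used throughout is

    V[t] = leak * V_post[t-1] + I[t]
    s[t] = 1  if V[t] >= threshold else 0
    V_post[t] = V[t] * (1 - s[t])            (hard reset to zero)
               | V[t] - threshold * s[t]     (subtract-threshold reset)

with V_post[0-] = 0 at the start of every forward pass (no state carries
across calls).  With ``leak=1`` and hard reset the dynamics admit a closed
form: a constant current ``I`` in ``(0, threshold]`` produces a perfectly
regular train with inter-spike interval ``ceil(threshold / I)``, which the
test-suite uses as an independent oracle.

The spike step function has zero derivative almost everywhere, so training
uses a surrogate: the backward pass replaces d(spike)/d(V) with the
derivative of a sigmoid of slope ``surrogate_slope`` centred on the
threshold.  :func:`lif_backward` implements backprop-through-time with the
reset detached from the gradient path, the standard convention for
surrogate-gradient SNN training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LIFParams",
    "LIFState",
    "lif_step",
    "lif_run",
    "rate_encode",
    "spike_rate",
    "surrogate_grad",
    "lif_forward_cached",
    "lif_backward",
]

_RESET_MODES = ("hard", "subtract")


@dataclass(frozen=True)
class LIFParams:
    """Constants of a LIF layer.

    Parameters
    ----------
    threshold
        Firing threshold in membrane-potential units. Must be positive.
    leak
        Per-step multiplicative decay of the membrane potential, in
        ``(0, 1]``.  ``leak=1`` is a pure (non-leaky) integrator.
    reset_mode
        ``"hard"`` resets a spiking unit's potential to zero;
        ``"subtract"`` subtracts the threshold.
    n_steps
        Simulation steps per forward pass (the LIF time window T).  The
        default of 20 corresponds to a 20 ms window at 1 ms resolution.
    surrogate_slope
        Slope of the sigmoid whose derivative stands in for the spike
        step function during backprop.
    """

    threshold: float = 1.0
    leak: float = 1.0
    reset_mode: str = "hard"
    n_steps: int = 20
    surrogate_slope: float = 5.0

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ValueError(f"threshold must be > 0, got {self.threshold}")
        if not 0 < self.leak <= 1:
            raise ValueError(f"leak must be in (0, 1], got {self.leak}")
        if self.reset_mode not in _RESET_MODES:
            raise ValueError(
                f"reset_mode must be one of {_RESET_MODES}, got {self.reset_mode!r}"
            )
        if self.n_steps < 1:
            raise ValueError(f"n_steps must be >= 1, got {self.n_steps}")
        if not self.surrogate_slope > 0:
            raise ValueError("surrogate_slope must be > 0")


@dataclass
class LIFState:
    """Per-unit membrane potentials of a LIF layer."""

    membrane: np.ndarray

    @classmethod
    def zeros(cls, shape) -> "LIFState":
        return cls(membrane=np.zeros(shape, dtype=float))


def lif_step(state: LIFState, current: np.ndarray, params: LIFParams):
    """Advance a LIF layer one step.

    Returns ``(new_state, spikes)`` where ``spikes`` is a float 0/1 array
    of the same shape as the membrane.
    """
    current = np.asarray(current, dtype=float)
    if current.shape != state.membrane.shape:
        raise ValueError(
            f"current shape {current.shape} does not match membrane shape "
            f"{state.membrane.shape}"
        )
    v = params.leak * state.membrane + current
    spikes = (v >= params.threshold).astype(float)
    if params.reset_mode == "hard":
        v_post = v * (1.0 - spikes)
    else:
        v_post = v - params.threshold * spikes
    if not np.all(np.isfinite(v_post)):
        raise FloatingPointError("non-finite membrane potential after lif_step")
    return LIFState(membrane=v_post), spikes


def lif_run(current_sequence: np.ndarray, params: LIFParams) -> np.ndarray:
    """Unroll :func:`lif_step` over the time window from a zero state.

    ``current_sequence`` has shape ``(n_steps, ...)``; the returned spike
    train has the same shape and is binary.
    """
    currents = np.asarray(current_sequence, dtype=float)
    if currents.shape[0] != params.n_steps:
        raise ValueError(
            f"current sequence length {currents.shape[0]} != n_steps {params.n_steps}"
        )
    state = LIFState.zeros(currents.shape[1:])
    out = np.empty_like(currents)
    for t in range(params.n_steps):
        state, out[t] = lif_step(state, currents[t], params)
    return out


def rate_encode(analog: np.ndarray, params: LIFParams) -> np.ndarray:
    """Constant-current coding: repeat each analog value at every step."""
    analog = np.asarray(analog, dtype=float)
    if not np.all(np.isfinite(analog)):
        raise ValueError("rate_encode requires finite input values")
    return np.broadcast_to(analog, (params.n_steps, *analog.shape)).copy()


def spike_rate(spike_train: np.ndarray) -> np.ndarray:
    """Mean firing rate over the time axis (axis 0); values lie in [0, 1]."""
    train = np.asarray(spike_train, dtype=float)
    if not np.isin(train, (0.0, 1.0)).all():
        raise ValueError("spike train must be binary 0/1")
    return train.mean(axis=0)


def surrogate_grad(v: np.ndarray, params: LIFParams) -> np.ndarray:
    """Backward stand-in for d(spike)/d(membrane): a scaled sigmoid bump.

    ``slope * sigma(slope (v - threshold)) * (1 - sigma(...))`` — finite
    everywhere, maximal at the threshold, nonzero in its neighbourhood.
    """
    z = params.surrogate_slope * (np.asarray(v, dtype=float) - params.threshold)
    sig = 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))
    return params.surrogate_slope * sig * (1.0 - sig)


def lif_forward_cached(currents: np.ndarray, params: LIFParams):
    """Forward pass keeping pre-reset potentials for BPTT.

    Returns ``(spikes, v_pre)``, both of shape ``(n_steps, ...)``.
    Semantically identical to :func:`lif_run`.
    """
    currents = np.asarray(currents, dtype=float)
    T = params.n_steps
    if currents.shape[0] != T:
        raise ValueError("current sequence length mismatch")
    spikes = np.empty_like(currents)
    v_pre = np.empty_like(currents)
    v_post = np.zeros(currents.shape[1:], dtype=float)
    for t in range(T):
        v = params.leak * v_post + currents[t]
        s = (v >= params.threshold).astype(float)
        v_pre[t] = v
        spikes[t] = s
        if params.reset_mode == "hard":
            v_post = v * (1.0 - s)
        else:
            v_post = v - params.threshold * s
    return spikes, v_pre


def lif_backward(
    d_spikes: np.ndarray,
    spikes: np.ndarray,
    v_pre: np.ndarray,
    params: LIFParams,
) -> np.ndarray:
    """Backprop-through-time through a cached LIF forward pass.

    ``d_spikes`` is dLoss/d(spike train).  Returns dLoss/d(current) with
    the same ``(n_steps, ...)`` shape.  The reset is detached: the
    spike indicator inside the reset is treated as a constant, so the
    hard reset gates the recurrent gradient by ``(1 - s[t])`` and the
    subtract reset passes it through unchanged.
    """
    T = params.n_steps
    d_current = np.zeros_like(v_pre)
    d_v_next = np.zeros(v_pre.shape[1:], dtype=float)  # dL/dV_pre[t+1]
    for t in range(T - 1, -1, -1):
        if params.reset_mode == "hard":
            carry = params.leak * d_v_next * (1.0 - spikes[t])
        else:
            carry = params.leak * d_v_next
        d_v = d_spikes[t] * surrogate_grad(v_pre[t], params) + carry
        d_current[t] = d_v
        d_v_next = d_v
    return d_current
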