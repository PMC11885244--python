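"""The multiscale-fusion spiking network (MFSNN) and its ANN twin.

Architecture
------------
The ``Nc``-channel binned spike-count input is split into ``Ns``
contiguous blocks of ``C = Nc / Ns`` channels, one per sub-encoder.  Each
sub-encoder fuses a linear time-compression branch (LT), a spiking
channel-attention branch (CA) and a depthwise causal dilated temporal
convolution branch (TCN) into a ``C x T'`` feature; the ``Ns`` features
are concatenated back to ``Nc x T'`` and fed to a spiking classifier:
the flattened feature drives a LIF layer as a constant current for the
LIF time window, and the layer's spike rates feed one fully connected
readout producing the class logits.

The ANN twin (``mode="ann"``) has the identical topology and parameter
shapes with every LIF replaced by a rectifier (and a logistic squashing
for the attention weights so they stay in ``[0, 1]``); it is the
multiply-accumulate comparator for the energy analysis.

Training support is built in: the forward pass can cache every
intermediate, and :meth:`MFSNN.backward` implements the exact adjoint of
the forward computation, using surrogate gradients (see
:mod:`mfsnn.lif`) through the spiking nonlinearities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import yaml

from .lif import LIFParams, lif_backward, lif_forward_cached, rate_encode, lif_run, spike_rate
from .sub_encoder import SubEncoderConfig

__all__ = [
    "ConfigError",
    "ModelConfig",
    "MFSNN",
    "split_channels",
    "concat_features",
    "classify",
    "build_mfann",
    "ablate",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_FORMAT_VERSION = 1


class ConfigError(ValueError):
    """Raised when a configuration violates a structural invariant."""


@dataclass(frozen=True)
class ModelConfig:
    """Complete architecture description.

    ``n_channels`` must be divisible by ``n_subencoders``; each
    sub-encoder then owns ``C = n_channels // n_subencoders`` channels,
    which must match ``sub_encoder.C``.  At least one of the TCN and LT
    branches must be enabled so the fused feature is time-resolved.
    """

    n_channels: int = 128
    n_subencoders: int = 16
    n_classes: int = 4
    sub_encoder: SubEncoderConfig = field(default_factory=SubEncoderConfig)
    classifier_lif: LIFParams = field(default_factory=LIFParams)
    mode: str = "snn"
    use_ca: bool = True
    use_tcn: bool = True
    use_lt: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels % self.n_subencoders != 0:
            raise ConfigError(
                f"n_channels={self.n_channels} is not divisible by "
                f"n_subencoders={self.n_subencoders}"
            )
        if self.sub_encoder.C != self.n_channels // self.n_subencoders:
            raise ConfigError(
                f"sub_encoder.C={self.sub_encoder.C} != n_channels/n_subencoders="
                f"{self.n_channels // self.n_subencoders}"
            )
        if self.n_classes < 2:
            raise ConfigError("n_classes must be >= 2")
        if self.mode not in ("snn", "ann"):
            raise ConfigError(f"mode must be 'snn' or 'ann', got {self.mode!r}")
        if not (self.use_tcn or self.use_lt):
            raise ConfigError(
                "at least one of use_tcn/use_lt must be enabled "
                "(the fused feature must be time-resolved)"
            )

    @classmethod
    def build(
        cls,
        n_channels: int = 128,
        n_subencoders: int = 16,
        n_classes: int = 4,
        T: int = 20,
        T_prime: int = 5,
        kernel_size: int = 3,
        dilation: int = 2,
        bottleneck_ratio: int = 2,
        lif: LIFParams | None = None,
        **kwargs,
    ) -> "ModelConfig":
        """Construct a config from scalar hyperparameters."""
        lif = lif or LIFParams()
        if n_channels % n_subencoders != 0:
            raise ConfigError(
                f"n_channels={n_channels} is not divisible by "
                f"n_subencoders={n_subencoders}"
            )
        sub = SubEncoderConfig(
            C=n_channels // n_subencoders,
            T=T,
            T_prime=T_prime,
            kernel_size=kernel_size,
            dilation=dilation,
            bottleneck_ratio=bottleneck_ratio,
            lif_params=lif,
        )
        return cls(
            n_channels=n_channels,
            n_subencoders=n_subencoders,
            n_classes=n_classes,
            sub_encoder=sub,
            classifier_lif=lif,
            **kwargs,
        )

    @property
    def C(self) -> int:
        return self.n_channels // self.n_subencoders

    @property
    def n_features(self) -> int:
        """Flattened classifier input size Nc * T'."""
        return self.n_channels * self.sub_encoder.T_prime

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        sub = dict(d.pop("sub_encoder"))
        sub_lif = LIFParams(**sub.pop("lif_params"))
        d["sub_encoder"] = SubEncoderConfig(lif_params=sub_lif, **sub)
        d["classifier_lif"] = LIFParams(**d.pop("classifier_lif"))
        return cls(**d)


# ---------------------------------------------------------------------------
# structural operations (also exposed for direct use / testing)

def split_channels(x: np.ndarray, n_subencoders: int) -> list[np.ndarray]:
    """Split the channel axis into contiguous, order-preserving blocks.

    Works on ``(Nc, T)`` or batched ``(B, Nc, T)`` arrays.
    """
    x = np.asarray(x)
    axis = x.ndim - 2
    nc = x.shape[axis]
    if nc % n_subencoders != 0:
        raise ConfigError(
            f"cannot split {nc} channels into {n_subencoders} equal blocks"
        )
    return [np.asarray(b) for b in np.split(x, n_subencoders, axis=axis)]


def concat_features(blocks: list[np.ndarray]) -> np.ndarray:
    """Concatenate sub-encoder outputs along the channel axis."""
    if not blocks:
        raise ValueError("no blocks to concatenate")
    axis = blocks[0].ndim - 2
    t_prime = {b.shape[-1] for b in blocks}
    if len(t_prime) != 1:
        raise ValueError(f"ragged block time lengths: {sorted(t_prime)}")
    return np.concatenate(blocks, axis=axis)


def classify(
    e_out: np.ndarray,
    weight: np.ndarray,
    bias: np.ndarray,
    lif_params: LIFParams,
) -> np.ndarray:
    """Spiking classifier on a single fused feature ``(Nc, T')``.

    The flattened feature is injected as a constant current into a LIF
    layer for the time window; the per-unit spike rates feed one fully
    connected layer.  Returns the ``K`` logits.
    """
    flat = np.asarray(e_out, dtype=float).reshape(-1)
    if weight.shape[1] != flat.size:
        raise ValueError(
            f"classifier weight expects {weight.shape[1]} features, got {flat.size}"
        )
    spikes = lif_run(rate_encode(flat, lif_params), lif_params)
    rates = spike_rate(spikes)
    return weight @ rates + bias


# ---------------------------------------------------------------------------

def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


class MFSNN:
    """The network, its parameters, and its training adjoint.

    Parameters are plain numpy arrays in ``self.params`` keyed as
    ``enc{i}/Ml``, ``enc{i}/tcn_w``, ``enc{i}/tcn_b``, ``enc{i}/ca_W1``,
    ``enc{i}/ca_b1``, ``enc{i}/ca_W2``, ``enc{i}/ca_b2`` (only for
    enabled branches) plus ``clf_W`` and ``clf_b``.  All randomness in
    initialisation flows from ``config.seed``.
    """

    def __init__(self, config: ModelConfig, params: dict[str, np.ndarray] | None = None):
        self.config = config
        self.params = params if params is not None else self._init_params()
        self._cache: dict | None = None

    # -- initialisation ----------------------------------------------------
    def _init_params(self) -> dict[str, np.ndarray]:
        cfg = self.config
        sub = cfg.sub_encoder
        rng = np.random.default_rng(cfg.seed)
        C, T, Tp, k = sub.C, sub.T, sub.T_prime, sub.kernel_size
        H = C // sub.bottleneck_ratio
        p = sub.pool_window
        params: dict[str, np.ndarray] = {}
        for i in range(cfg.n_subencoders):
            if cfg.use_lt:
                # start LT near a block-averaging map so early features are
                # non-negative (keeps the downstream LIF units responsive)
                base = np.zeros((T, Tp))
                for t in range(T):
                    base[t, t // p] = 1.0 / p
                params[f"enc{i}/Ml"] = base + 0.02 * rng.standard_normal((T, Tp))
            if cfg.use_tcn:
                params[f"enc{i}/tcn_w"] = 0.2 * rng.standard_normal((C, k))
                params[f"enc{i}/tcn_b"] = np.zeros(C)
            if cfg.use_ca:
                params[f"enc{i}/ca_W1"] = rng.standard_normal((H, C)) / np.sqrt(C)
                params[f"enc{i}/ca_b1"] = 0.5 * np.ones(H)
                params[f"enc{i}/ca_W2"] = rng.standard_normal((C, H)) / np.sqrt(H)
                params[f"enc{i}/ca_b2"] = 0.5 * np.ones(C)
        nf = cfg.n_features
        params["clf_W"] = rng.standard_normal((cfg.n_classes, nf)) / np.sqrt(nf)
        params["clf_b"] = np.zeros(cfg.n_classes)
        return params

    def copy(self) -> "MFSNN":
        return MFSNN(self.config, {k: v.copy() for k, v in self.params.items()})

    @property
    def n_parameters(self) -> int:
        return sum(v.size for v in self.params.values())

    # -- forward -----------------------------------------------------------
    def forward(self, x: np.ndarray, want_cache: bool = False) -> np.ndarray:
        """Batched forward pass: ``(B, Nc, T)`` -> logits ``(B, K)``.

        With ``want_cache`` the intermediates needed by :meth:`backward`
        and by the energy profiler are stored on the instance.
        """
        cfg = self.config
        sub = cfg.sub_encoder
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1:] != (cfg.n_channels, sub.T):
            raise ValueError(
                f"expected input (B, {cfg.n_channels}, {sub.T}), got {x.shape}"
            )
        B = x.shape[0]
        C, T, Tp = sub.C, sub.T, sub.T_prime
        k, d, p = sub.kernel_size, sub.dilation, sub.pool_window
        lif = sub.lif_params
        Tw = lif.n_steps
        cache: dict = {"x": x, "enc": []}

        e_blocks = []
        for i in range(cfg.n_subencoders):
            xi = x[:, i * C : (i + 1) * C, :]
            ci: dict = {"xi": xi}

            lt = None
            if cfg.use_lt:
                lt = np.einsum("bct,tu->bcu", xi, self.params[f"enc{i}/Ml"])

            w_attn = None
            if cfg.use_ca:
                f = xi.mean(axis=2)  # (B, C)
                W1 = self.params[f"enc{i}/ca_W1"]
                W2 = self.params[f"enc{i}/ca_W2"]
                u1 = f @ W1.T + self.params[f"enc{i}/ca_b1"]  # (B, H)
                if cfg.mode == "snn":
                    cur1 = np.broadcast_to(u1, (Tw, *u1.shape)).copy()
                    s1, v1 = lif_forward_cached(cur1, lif)
                    cur2 = np.einsum("tbh,ch->tbc", s1, W2) + self.params[f"enc{i}/ca_b2"]
                    s2, v2 = lif_forward_cached(cur2, lif)
                    w_attn = s2.mean(axis=0)  # (B, C) in [0,1]
                    ci.update(f=f, u1=u1, s1=s1, v1=v1, s2=s2, v2=v2)
                else:
                    a1 = _relu(u1)
                    z2 = a1 @ W2.T + self.params[f"enc{i}/ca_b2"]
                    w_attn = _sigmoid(z2)
                    ci.update(f=f, u1=u1, a1=a1, w=w_attn)
                ci["w_attn"] = w_attn

            tcn = None
            if cfg.use_tcn:
                wk = self.params[f"enc{i}/tcn_w"]  # (C, k)
                bk = self.params[f"enc{i}/tcn_b"]
                padded = np.concatenate(
                    [np.zeros((B, C, (k - 1) * d)), xi], axis=2
                )
                conv = np.broadcast_to(bk[None, :, None], (B, C, T)).astype(float).copy()
                for j in range(k):
                    conv += wk[:, j][None, :, None] * padded[:, :, j * d : j * d + T]
                tcn = conv.reshape(B, C, Tp, p).mean(axis=3)
                ci.update(padded=padded, tcn=tcn)

            if cfg.use_tcn and cfg.use_lt:
                scale = w_attn[:, :, None] if cfg.use_ca else 1.0
                ei = lt + scale * tcn
            elif cfg.use_tcn:
                scale = w_attn[:, :, None] if cfg.use_ca else 1.0
                ei = scale * tcn
            else:
                ei = lt
            ci["lt"] = lt
            e_blocks.append(ei)
            cache["enc"].append(ci)

        e_out = np.concatenate(e_blocks, axis=1)  # (B, Nc, T')
        flat = e_out.reshape(B, -1)
        clf_lif = cfg.classifier_lif
        if cfg.mode == "snn":
            cur3 = np.broadcast_to(flat, (clf_lif.n_steps, *flat.shape)).copy()
            s3, v3 = lif_forward_cached(cur3, clf_lif)
            rates = s3.mean(axis=0)
            cache.update(s3=s3, v3=v3)
        else:
            rates = _relu(flat)
        logits = rates @ self.params["clf_W"].T + self.params["clf_b"]
        cache.update(e_out=e_out, flat=flat, rates=rates)
        self._cache = cache if want_cache else None
        return logits

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Predicted class per trial; argmax ties break to the lowest index."""
        return np.argmax(self.forward(x), axis=1)

    # -- backward ----------------------------------------------------------
    def backward(self, d_logits: np.ndarray) -> dict[str, np.ndarray]:
        """Adjoint of :meth:`forward`; requires a cached forward pass.

        Returns gradients keyed like ``self.params``.  Spiking
        nonlinearities are differentiated with the surrogate described
        in :mod:`mfsnn.lif`.
        """
        if self._cache is None:
            raise RuntimeError("backward called without a cached forward pass")
        cfg = self.config
        sub = cfg.sub_encoder
        cache = self._cache
        B = cache["x"].shape[0]
        C, T, Tp = sub.C, sub.T, sub.T_prime
        k, d, p = sub.kernel_size, sub.dilation, sub.pool_window
        lif = sub.lif_params
        Tw = lif.n_steps
        grads: dict[str, np.ndarray] = {}

        rates = cache["rates"]
        grads["clf_W"] = np.einsum("bk,bn->kn", d_logits, rates)
        grads["clf_b"] = d_logits.sum(axis=0)
        d_rates = d_logits @ self.params["clf_W"]  # (B, Nf)

        clf_lif = cfg.classifier_lif
        if cfg.mode == "snn":
            ds3 = np.broadcast_to(
                d_rates / clf_lif.n_steps, (clf_lif.n_steps, *d_rates.shape)
            )
            dI3 = lif_backward(ds3, cache["s3"], cache["v3"], clf_lif)
            d_flat = dI3.sum(axis=0)
        else:
            d_flat = d_rates * (cache["flat"] > 0)
        d_eout = d_flat.reshape(B, cfg.n_channels, Tp)

        for i in range(cfg.n_subencoders):
            ci = cache["enc"][i]
            xi = ci["xi"]
            d_ei = d_eout[:, i * C : (i + 1) * C, :]

            if cfg.use_lt:
                grads[f"enc{i}/Ml"] = np.einsum("bct,bcu->tu", xi, d_ei)

            d_w_attn = None
            if cfg.use_tcn:
                if cfg.use_ca:
                    d_tcn = d_ei * ci["w_attn"][:, :, None]
                    d_w_attn = (d_ei * ci["tcn"]).sum(axis=2)  # (B, C)
                else:
                    d_tcn = d_ei
                # pooling adjoint: spread evenly over each window
                d_conv = np.repeat(d_tcn / p, p, axis=2)  # (B, C, T)
                padded = ci["padded"]
                wk = self.params[f"enc{i}/tcn_w"]
                d_wk = np.empty_like(wk)
                for j in range(k):
                    d_wk[:, j] = (d_conv * padded[:, :, j * d : j * d + T]).sum(axis=(0, 2))
                grads[f"enc{i}/tcn_w"] = d_wk
                grads[f"enc{i}/tcn_b"] = d_conv.sum(axis=(0, 2))

            if cfg.use_ca:
                if d_w_attn is None:  # attention weight unused downstream
                    for name in ("ca_W1", "ca_b1", "ca_W2", "ca_b2"):
                        grads[f"enc{i}/{name}"] = np.zeros_like(
                            self.params[f"enc{i}/{name}"]
                        )
                    continue
                W2 = self.params[f"enc{i}/ca_W2"]
                f = ci["f"]
                if cfg.mode == "snn":
                    ds2 = np.broadcast_to(d_w_attn / Tw, (Tw, *d_w_attn.shape))
                    dI2 = lif_backward(ds2, ci["s2"], ci["v2"], lif)
                    grads[f"enc{i}/ca_W2"] = np.einsum("tbc,tbh->ch", dI2, ci["s1"])
                    grads[f"enc{i}/ca_b2"] = dI2.sum(axis=(0, 1))
                    ds1 = np.einsum("tbc,ch->tbh", dI2, W2)
                    dI1 = lif_backward(ds1, ci["s1"], ci["v1"], lif)
                    du1 = dI1.sum(axis=0)  # (B, H)
                else:
                    w = ci["w"]
                    dz2 = d_w_attn * w * (1.0 - w)
                    grads[f"enc{i}/ca_W2"] = dz2.T @ ci["a1"]
                    grads[f"enc{i}/ca_b2"] = dz2.sum(axis=0)
                    da1 = dz2 @ W2
                    du1 = da1 * (ci["u1"] > 0)
                grads[f"enc{i}/ca_W1"] = du1.T @ f
                grads[f"enc{i}/ca_b1"] = du1.sum(axis=0)

        return grads


def build_mfann(config: ModelConfig) -> MFSNN:
    """The non-spiking twin: identical topology, rectifier nonlinearities.

    Parameter shapes (and, with the same seed, initial values) match the
    spiking model exactly, so layer-by-layer FLOPs profiles coincide.
    """
    return MFSNN(replace(config, mode="ann"))


def ablate(config: ModelConfig, drop: str) -> ModelConfig:
    """Return a config with one branch removed: ``drop`` in {CA, TCN, LT}.

    Dropping CA pins the attention weights to 1; dropping TCN or LT
    removes that term from the fusion.  Dropping both TCN and LT is a
    configuration error (raised by ``ModelConfig``).
    """
    key = drop.strip().lower()
    if key == "ca":
        return replace(config, use_ca=False)
    if key == "tcn":
        return replace(config, use_tcn=False)
    if key == "lt":
        return replace(config, use_lt=False)
    raise ValueError(f"unknown ablation {drop!r}; expected one of CA, TCN, LT")


# ---------------------------------------------------------------------------
# checkpointing

def save_checkpoint(model: MFSNN, path) -> None:
    """Single-archive checkpoint: config as YAML text + parameter arrays."""
    payload = {
        "__format_version__": np.array(CHECKPOINT_FORMAT_VERSION),
        "__config_yaml__": np.frombuffer(
            yaml.safe_dump(model.config.to_dict()).encode("utf-8"), dtype=np.uint8
        ),
    }
    for k, v in model.params.items():
        payload["param:" + k] = v
    with open(path, "wb") as fh:
        np.savez(fh, **payload)


def load_checkpoint(path) -> MFSNN:
    with np.load(path) as data:
        version = int(data["__format_version__"])
        if version != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint format version {version}")
        cfg_yaml = bytes(data["__config_yaml__"]).decode("utf-8")
        config = ModelConfig.from_dict(yaml.safe_load(cfg_yaml))
        params = {
            k[len("param:"):]: np.array(data[k])
            for k in data.files
            if k.startswith("param:")
        }
    return MFSNN(config, params)
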