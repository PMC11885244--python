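"""Theoretical energy accounting: FLOPs, spike rates, SOPs, picojoules.

A conventional layer costs one multiply-accumulate (MAC) per weight use;
a spike-driven layer replaces each MAC by an accumulate (AC) that fires
only when its input spikes, so its operation count is

    SOPs(l) = Rate x T x FLOPs(l)

where ``Rate`` is the mean firing rate of the spike train feeding layer
``l``, ``T`` the LIF time window, and ``FLOPs(l)`` the layer's MAC count.
With 45 nm process constants E_MAC = 4.6 pJ and E_AC = 0.9 pJ the
spiking network's energy for the encoder is

    E = E_AC x sum_i (SOP_LT_i + SOP_CA_i + SOP_TCN_i)

summed over the sub-encoders; the ANN twin costs E_MAC x sum FLOPs over
the same layers.  The classifier is profiled too but kept out of the
headline encoder totals, matching the encoder-only accounting
convention.  A layer is cheaper spiking than analog exactly when
``Rate x T < E_MAC / E_AC`` (about 5.11) — the break-even law the tests
verify.

FLOP counting conventions (MAC-only):
  * time-compression matrix (C,T)x(T,T')  -> C*T*T' MACs
  * depthwise conv, kernel k, length T    -> C*T*k MACs
  * 1x1 conv C_in -> C_out on a 1-vector  -> C_in*C_out MACs
  * attention scaling of the TCN feature  -> C*T' MACs
  * fully connected n_in -> n_out         -> n_in*n_out MACs
  * pooling and additions                 -> 0 (no multiplies)

First-layer rate convention: the raw input is itself a spike train, but
the model consumes binned counts; a count of ``n`` in a ``bin_ms`` bin is
treated as ``n`` spikes over ``bin_ms`` 1 ms steps, i.e. a per-step spike
probability ``n / bin_ms`` (clipped to [0, 1]).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .model import MFSNN, ModelConfig

__all__ = [
    "EnergyConstants",
    "LayerProfile",
    "EnergyReport",
    "count_flops",
    "sops",
    "input_rate_convention",
    "measure_rates",
    "energy_mfsnn",
    "energy_mfann",
    "reduction",
]


@dataclass(frozen=True)
class EnergyConstants:
    """Per-operation energies on a 45 nm process."""

    E_MAC: float = 4.6  # pJ per multiply-accumulate
    E_AC: float = 0.9   # pJ per accumulate
    process: str = "45nm"

    def __post_init__(self) -> None:
        if self.E_MAC <= 0 or self.E_AC <= 0:
            raise ValueError("operation energies must be positive")


@dataclass
class LayerProfile:
    name: str
    branch: str           # LT | CA | TCN | classifier
    flops: int
    rate: float | None    # None in ANN mode
    T: int | None
    sops: float | None
    energy_pJ: float


@dataclass
class EnergyReport:
    mode: str
    layers: list[LayerProfile]
    encoder_total_pJ: float
    classifier_pJ: float

    @property
    def total_pJ(self) -> float:
        return self.encoder_total_pJ + self.classifier_pJ

    def branch_subtotals(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for layer in self.layers:
            out[layer.branch] = out.get(layer.branch, 0.0) + layer.energy_pJ
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "layer": l.name,
                "branch": l.branch,
                "FLOPs": l.flops,
                "rate": l.rate,
                "T": l.T,
                "SOPs": l.sops,
                "energy_pJ": l.energy_pJ,
                "mode": self.mode,
            }
            for l in self.layers
        ]
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        return json.dumps(
            {
                "mode": self.mode,
                "encoder_total_pJ": self.encoder_total_pJ,
                "classifier_pJ": self.classifier_pJ,
                "total_pJ": self.total_pJ,
                "layers": [asdict(l) for l in self.layers],
            },
            indent=2,
            sort_keys=True,
        )


# ---------------------------------------------------------------------------

def count_flops(kind: str, **dims) -> int:
    """MAC count of one layer. ``kind`` in {linear_transform, depthwise_conv,
    conv1x1, scale, fc}."""
    if kind == "linear_transform":
        return dims["C"] * dims["T"] * dims["T_prime"]
    if kind == "depthwise_conv":
        return dims["C"] * dims["T"] * dims["k"]
    if kind == "conv1x1":
        return dims["c_in"] * dims["c_out"]
    if kind == "scale":
        return dims["C"] * dims["T_prime"]
    if kind == "fc":
        return dims["n_in"] * dims["n_out"]
    raise ValueError(f"unknown layer kind {kind!r}")


def sops(rate: float, T: int, flops: int) -> float:
    """Synaptic operations of one spiking layer: the literal product."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must be in [0,1], got {rate}")
    if T < 1 or flops < 0:
        raise ValueError("T must be >= 1 and flops >= 0")
    return rate * T * flops


def input_rate_convention(x: np.ndarray, bin_ms: float) -> float:
    """Per-step spike probability of a binned-count input block."""
    return float(np.clip(np.mean(np.asarray(x, dtype=float)) / bin_ms, 0.0, 1.0))


def reduction(e_snn: float, e_ann: float) -> float:
    """Energy reduction percent: 100 x (1 - E_snn / E_ann)."""
    if e_ann <= 0:
        raise ValueError("ANN energy must be positive")
    return 100.0 * (1.0 - e_snn / e_ann)


# ---------------------------------------------------------------------------

def _layer_specs(config: ModelConfig) -> list[tuple[str, str, int]]:
    """(name, branch, flops) for every counted layer of one model."""
    sub = config.sub_encoder
    C, T, Tp, k = sub.C, sub.T, sub.T_prime, sub.kernel_size
    H = C // sub.bottleneck_ratio
    specs: list[tuple[str, str, int]] = []
    for i in range(config.n_subencoders):
        if config.use_lt:
            specs.append((f"enc{i}/LT", "LT", count_flops("linear_transform", C=C, T=T, T_prime=Tp)))
        if config.use_ca:
            specs.append((f"enc{i}/CA_compress", "CA", count_flops("conv1x1", c_in=C, c_out=H)))
            specs.append((f"enc{i}/CA_expand", "CA", count_flops("conv1x1", c_in=H, c_out=C)))
            if config.use_tcn:
                specs.append((f"enc{i}/CA_scale", "CA", count_flops("scale", C=C, T_prime=Tp)))
        if config.use_tcn:
            specs.append((f"enc{i}/TCN_conv", "TCN", count_flops("depthwise_conv", C=C, T=T, k=k)))
    specs.append((
        "classifier/FC",
        "classifier",
        count_flops("fc", n_in=config.n_features, n_out=config.n_classes),
    ))
    return specs


def measure_rates(model: MFSNN, batch: np.ndarray, bin_ms: float = 50.0) -> dict[str, float]:
    """Mean input firing rate for every counted layer, from one batch.

    Layers fed by analog binned counts (LT, TCN conv, the attention
    compressor whose input is the pooled count summary) use the
    binned-count convention; layers fed by actual spike trains (the
    attention expander, the attention scaling, the classifier readout)
    use the measured mean of the binary train.
    """
    if model.config.mode != "snn":
        raise ValueError("rates are only defined for the spiking model")
    batch = np.asarray(batch, dtype=float)
    if batch.ndim == 2:
        batch = batch[None]
    if batch.shape[0] == 0:
        raise ValueError("empty batch")
    model.forward(batch, want_cache=True)
    cache = model._cache
    cfg = model.config
    C = cfg.C
    rates: dict[str, float] = {}
    for i in range(cfg.n_subencoders):
        ci = cache["enc"][i]
        in_rate = input_rate_convention(ci["xi"], bin_ms)
        if cfg.use_lt:
            rates[f"enc{i}/LT"] = in_rate
        if cfg.use_tcn:
            rates[f"enc{i}/TCN_conv"] = in_rate
        if cfg.use_ca:
            rates[f"enc{i}/CA_compress"] = input_rate_convention(ci["f"], bin_ms)
            rates[f"enc{i}/CA_expand"] = float(ci["s1"].mean())
            if cfg.use_tcn:
                rates[f"enc{i}/CA_scale"] = float(ci["s2"].mean())
    rates["classifier/FC"] = float(cache["s3"].mean())
    return rates


def energy_mfsnn(
    model: MFSNN,
    batch: np.ndarray,
    constants: EnergyConstants = EnergyConstants(),
    bin_ms: float = 50.0,
) -> EnergyReport:
    """SOP-based energy of the spiking model, measured on a batch.

    The encoder total is ``E_AC x sum_i (SOP_LT_i + SOP_CA_i +
    SOP_TCN_i)``; the classifier line is reported separately.
    """
    cfg = model.config
    T = cfg.sub_encoder.lif_params.n_steps
    rates = measure_rates(model, batch, bin_ms)
    layers = []
    encoder_total = 0.0
    classifier_pJ = 0.0
    for name, branch, flops in _layer_specs(cfg):
        r = rates[name]
        s = sops(r, T, flops)
        e = s * constants.E_AC
        layers.append(LayerProfile(name, branch, flops, r, T, s, e))
        if branch == "classifier":
            classifier_pJ += e
        else:
            encoder_total += e
    return EnergyReport("snn", layers, encoder_total, classifier_pJ)


def energy_mfann(
    model_or_config,
    constants: EnergyConstants = EnergyConstants(),
) -> EnergyReport:
    """MAC-based energy of the ANN twin: input-independent, E_MAC per FLOP."""
    cfg = model_or_config.config if isinstance(model_or_config, MFSNN) else model_or_config
    layers = []
    encoder_total = 0.0
    classifier_pJ = 0.0
    for name, branch, flops in _layer_specs(cfg):
        e = flops * constants.E_MAC
        layers.append(LayerProfile(name, branch, flops, None, None, None, e))
        if branch == "classifier":
            classifier_pJ += e
        else:
            encoder_total += e
    return EnergyReport("ann", layers, encoder_total, classifier_pJ)
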