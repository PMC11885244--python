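"""Supervised training and the cross-day evaluation protocol.

Training minimises the softmax cross-entropy of the logits with Adam
(batch size 32 by default) under a cosine-annealed learning rate running
from 0.01 down to 0.0001 over the epoch budget.  Every run is a pure
function of (data, configs, seeds).

Cross-day evaluation mirrors the experimental protocol of chronic-BCI
studies: train on one session, then for each later session fine-tune a
copy of the model on a small stratified fraction ``f`` of that session's
trials ("mini-batch supervised generalization") and test on the
untouched remainder.  :func:`cross_day_protocol` sweeps test sessions x
fractions x seeds and returns the full accuracy grid with split
manifests, so leakage between fine-tune and test trials is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .model import MFSNN
from .synth import SessionData

__all__ = [
    "TrainConfig",
    "FinetuneConfig",
    "ProtocolResult",
    "Adam",
    "cosine_lr",
    "softmax_cross_entropy",
    "train",
    "evaluate",
    "single_day_split",
    "stratified_subset",
    "finetune",
    "cross_day_protocol",
]


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 32
    lr_max: float = 0.01
    lr_min: float = 0.0001
    epochs: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not self.lr_min < self.lr_max:
            raise ValueError("lr_min must be < lr_max")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


@dataclass(frozen=True)
class FinetuneConfig:
    """Mini-batch adaptation to a new session.

    ``fraction`` of the session's trials (stratified by class, floor per
    total count) are used for fine-tuning; the rest are reserved for
    testing.  ``scope`` selects which parameters adapt.
    """

    fraction: float = 0.08
    scope: str = "all"  # "all" | "classifier"
    epochs: int = 20
    # gentle enough that a handful of trials cannot drag the model off the
    # pre-trained solution, yet 20 steps suffice to adapt to a drifted session
    lr: float = 0.0003
    batch_size: int = 32
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.fraction <= 1:
            raise ValueError(f"fraction must be in [0,1], got {self.fraction}")
        if self.scope not in ("all", "classifier"):
            raise ValueError("scope must be 'all' or 'classifier'")


@dataclass
class ProtocolResult:
    """Accuracy grid of a cross-day experiment plus split manifests."""

    records: pd.DataFrame
    manifests: list[dict] = field(default_factory=list)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------

class Adam:
    """Adaptive-moment gradient descent over a dict of parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], beta1=0.9, beta2=0.999, eps=1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict, lr: float, keys=None) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k in keys if keys is not None else params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= lr * mhat / (np.sqrt(vhat) + self.eps)


def cosine_lr(epoch: int, config: TrainConfig) -> float:
    """Cosine annealing from lr_max (epoch 0) to lr_min (last epoch)."""
    if config.epochs <= 1:
        return config.lr_max
    frac = epoch / (config.epochs - 1)
    return config.lr_min + 0.5 * (config.lr_max - config.lr_min) * (
        1 + np.cos(np.pi * frac)
    )


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    expz = np.exp(z)
    probs = expz / expz.sum(axis=1, keepdims=True)
    n = labels.shape[0]
    loss = -np.mean(np.log(probs[np.arange(n), labels] + 1e-12))
    d_logits = probs.copy()
    d_logits[np.arange(n), labels] -= 1.0
    return loss, d_logits / n


def _as_arrays(data) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, SessionData):
        return data.spikes.astype(float), data.labels.astype(int)
    x, y = data
    return np.asarray(x, dtype=float), np.asarray(y, dtype=int)


def _check_labels(y: np.ndarray, k: int) -> None:
    if y.size == 0:
        raise ValueError("empty training data")
    if y.min() < 0 or y.max() >= k:
        raise ValueError(f"labels must lie in [0, {k}), got range [{y.min()}, {y.max()}]")


def train(
    model: MFSNN,
    data,
    config: TrainConfig,
    optimizer: Adam | None = None,
    param_keys=None,
    lr_override: float | None = None,
) -> tuple[MFSNN, list[dict]]:
    """Train in place; returns the model and a per-epoch history.

    ``data`` is a :class:`SessionData` or an ``(x, y)`` pair.  The
    learning rate follows cosine annealing unless ``lr_override`` pins
    it (used by fine-tuning).  ``param_keys`` restricts the update to a
    subset of parameters (e.g. the classifier).
    """
    x, y = _as_arrays(data)
    _check_labels(y, model.config.n_classes)
    history: list[dict] = []
    if config.epochs == 0:
        return model, history
    rng = np.random.default_rng(config.seed)
    opt = optimizer or Adam(model.params)
    n = x.shape[0]
    for epoch in range(config.epochs):
        lr = lr_override if lr_override is not None else cosine_lr(epoch, config)
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = model.forward(x[idx], want_cache=True)
            loss, d_logits = softmax_cross_entropy(logits, y[idx])
            grads = model.backward(d_logits)
            opt.step(model.params, grads, lr, keys=param_keys)
            losses.append(loss * idx.size)
            correct += int((np.argmax(logits, axis=1) == y[idx]).sum())
        history.append(
            {
                "epoch": epoch,
                "lr": float(lr),
                "loss": float(np.sum(losses) / n),
                "accuracy": 100.0 * correct / n,
            }
        )
    return model, history


def evaluate(model: MFSNN, data) -> float:
    """Accuracy in percent over a trial set."""
    x, y = _as_arrays(data)
    if y.size == 0:
        raise ValueError("cannot evaluate on an empty trial set")
    preds = model.predict(x)
    return 100.0 * float((preds == y).mean())


# ---------------------------------------------------------------------------
# splits

def single_day_split(session: SessionData, seed: int, train_frac: float = 0.8):
    """Stratified 8:2 split of one session into train/test index arrays."""
    y = np.asarray(session.labels, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 5:
        raise ValueError(
            f"need >= 5 trials per class for an 8:2 split; class sizes {dict(zip(classes.tolist(), counts.tolist()))}"
        )
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for c in classes:
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        cut = int(np.floor(train_frac * idx.size))
        train_idx.append(idx[:cut])
        test_idx.append(idx[cut:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def stratified_subset(labels: np.ndarray, fraction: float, seed: int, stratified=True):
    """Pick ``floor(fraction * n)`` trial indices, class-stratified.

    Returns ``(subset, rest, warnings)``; a class that receives zero
    fine-tune trials is recorded as a warning, not an error.
    """
    y = np.asarray(labels, dtype=int)
    n = y.size
    n_pick = int(np.floor(fraction * n))
    rng = np.random.default_rng(seed)
    warnings: list[str] = []
    if n_pick == 0:
        return np.array([], dtype=int), np.arange(n), [
            f"fraction {fraction} selects 0 of {n} trials"
        ]
    if not stratified:
        perm = rng.permutation(n)
        pick = np.sort(perm[:n_pick])
        return pick, np.sort(perm[n_pick:]), warnings
    classes = np.unique(y)
    quota = np.full(classes.size, n_pick // classes.size)
    quota[: n_pick % classes.size] += 1
    picks = []
    for c, q in zip(classes, quota):
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        take = min(q, idx.size)
        if take == 0:
            warnings.append(f"class {c} received zero fine-tune trials")
        picks.append(idx[:take])
    pick = np.sort(np.concatenate(picks))
    rest = np.sort(np.setdiff1d(np.arange(n), pick))
    return pick, rest, warnings


def finetune(model: MFSNN, new_session: SessionData, config: FinetuneConfig):
    """Adapt a trained model to a new session on a small labelled subset.

    Returns ``(model, manifest)``; the manifest records the exact trial
    indices used for fine-tuning and those reserved for testing.
    """
    pick, rest, warnings = stratified_subset(
        new_session.labels, config.fraction, config.seed, config.stratified
    )
    manifest = {
        "session_id": new_session.session_id,
        "fraction": config.fraction,
        "seed": config.seed,
        "scope": config.scope,
        "finetune_indices": pick.tolist(),
        "test_indices": rest.tolist(),
        "warnings": warnings,
    }
    if pick.size == 0:
        return model, manifest
    keys = None
    if config.scope == "classifier":
        keys = [k for k in model.params if k.startswith("clf_")]
    tc = TrainConfig(
        batch_size=config.batch_size,
        lr_max=config.lr,
        lr_min=config.lr / 10.0,
        epochs=config.epochs,
        seed=config.seed,
    )
    x = new_session.spikes[pick].astype(float)
    y = new_session.labels[pick].astype(int)
    train(model, (x, y), tc, param_keys=keys, lr_override=config.lr)
    return model, manifest


def cross_day_protocol(
    sessions: list[SessionData],
    train_day: int,
    test_days: list[int],
    fractions: list[float],
    seeds: list[int],
    train_config: TrainConfig | None = None,
    finetune_config: FinetuneConfig | None = None,
    model_factory=None,
) -> ProtocolResult:
    """Train on one day; fine-tune/evaluate on every (day, fraction, seed).

    ``model_factory(seed) -> MFSNN`` builds a fresh model per seed.  For
    each combination a copy of the trained model is fine-tuned on the
    chosen fraction of the test day and evaluated on that day's untouched
    remainder; fractions of 0 give zero-shot transfer.
    """
    if len(sessions) < 2:
        raise ValueError("cross-day protocol needs at least 2 sessions")
    if train_day in test_days:
        raise ValueError(f"train_day {train_day} must not be among test_days")
    if model_factory is None:
        raise ValueError("model_factory is required")
    tc = train_config or TrainConfig()
    fc = finetune_config or FinetuneConfig()
    rows, manifests = [], []
    for seed in seeds:
        base = model_factory(seed)
        train(base, sessions[train_day], dataclass_replace(tc, seed=seed))
        for day in test_days:
            for f in fractions:
                m = base.copy()
                m, manifest = finetune(
                    m,
                    sessions[day],
                    dataclass_replace(fc, fraction=f, seed=seed),
                )
                test_idx = np.asarray(manifest["test_indices"], dtype=int)
                acc = evaluate(
                    m,
                    (
                        sessions[day].spikes[test_idx].astype(float),
                        sessions[day].labels[test_idx].astype(int),
                    ),
                )
                rows.append(
                    {
                        "train_session": sessions[train_day].session_id,
                        "test_session": sessions[day].session_id,
                        "fraction": f,
                        "seed": seed,
                        "n_finetune": len(manifest["finetune_indices"]),
                        "accuracy": acc,
                    }
                )
                manifests.append(manifest)
    return ProtocolResult(records=pd.DataFrame(rows), manifests=manifests)


def dataclass_replace(cfg, **kw):
    from dataclasses import replace

    return replace(cfg, **kw)


def finetune_duration_bounds(
    n_trials: int = 300,
    fraction: float = 0.08,
    trial_seconds: tuple[float, float] = (2.0, 4.0),
) -> tuple[float, float]:
    """Recording time needed for fine-tuning, in seconds.

    With ~300 trials per day of 2-4 s each, adapting on an 8% fraction
    costs only floor(0.08 x 300) = 24 trials, i.e. 48-96 s of new-session
    data — the practical calibration burden of cross-day decoding.
    """
    n_ft = int(np.floor(fraction * n_trials))
    return (n_ft * trial_seconds[0], n_ft * trial_seconds[1])
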