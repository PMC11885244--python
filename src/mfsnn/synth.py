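"""Synthetic multi-session benchmark for cross-day spike-train decoding.

The generator emulates the statistical structure of trial-based motor
cortex (M1) recordings in the two paradigms the decoder targets:

* ``grasp_touch_4`` — four hand-action classes (right/left x touch/grasp),
  128 channels, ~300 trials per session.  Each channel carries a fixed
  random loading per class: ``r_c(class) = max(0, b_c + L[c, class])``.
* ``center_out_8`` — eight reach directions, 192 channels (two 96-channel
  arrays), ~2,000 trials per session.  Channels are cosine-tuned, the
  classic M1 rate model: ``r_c(theta) = max(0, b_c + m_c cos(theta -
  theta_c))``.

Rates are shaped in time by a per-bin phase profile (baseline then ramp
to full modulation, mimicking the reach/action phases of a trial) and
spike counts are drawn independently per bin as Poisson with mean
``rate * bin_width``.

Between-session non-stationarity — electrode drift, impedance changes,
plasticity — is modelled by :func:`apply_drift`: per-channel log-normal
gain, channel dropout (a channel loses its tuning), preferred-direction /
loading jitter and additive baseline shifts.  Each later session of a
benchmark is an independent drift of the base population, so the
distance from session 1 is controlled by one spec rather than a random
walk (a ``random_walk`` flag chains drifts instead).

Everything is a pure function of the specs and seeds; provenance stored
with each session suffices to regenerate it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np


def _jsonify(obj):
    """Canonicalise provenance so HDF5 JSON round-trips are exact."""
    return json.loads(json.dumps(obj))

__all__ = [
    "PopulationSpec",
    "DriftSpec",
    "Population",
    "SessionData",
    "PARADIGM_CLASSES",
    "make_population",
    "rate_profile",
    "simulate_session",
    "apply_drift",
    "make_cross_day_benchmark",
    "default_phase_profile",
]

PARADIGM_CLASSES = {"grasp_touch_4": 4, "center_out_8": 8}


def default_phase_profile(n_bins: int) -> np.ndarray:
    """Per-bin envelope: baseline half-gain, ramping to full action gain.

    First quarter of the trial sits at 0.5 (baseline/preparation), then a
    linear ramp reaches 1.0 at the midpoint (reach), and the second half
    stays at 1.0 (task action).
    """
    q, h = n_bins // 4, n_bins // 2
    prof = np.ones(n_bins)
    prof[:q] = 0.5
    if h > q:
        prof[q:h] = np.linspace(0.5, 1.0, h - q, endpoint=False)
    return prof


@dataclass(frozen=True)
class PopulationSpec:
    """Generative parameters of a tuned recording population.

    Rates are in spikes/s; ``bin_ms`` is the count bin width and
    ``n_bins`` the number of bins per trial, so the analysis window is
    ``n_bins * bin_ms`` ms (default 20 x 50 ms = 1 s of task action).
    """

    n_channels: int = 128
    paradigm: str = "grasp_touch_4"
    baseline_range: tuple[float, float] = (5.0, 20.0)
    modulation_range: tuple[float, float] = (3.0, 12.0)
    loading_sigma: float = 8.0
    bin_ms: float = 50.0
    n_bins: int = 20
    phase_profile: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.paradigm not in PARADIGM_CLASSES:
            raise ValueError(
                f"unknown paradigm {self.paradigm!r}; "
                f"expected one of {sorted(PARADIGM_CLASSES)}"
            )
        if self.n_channels < 1 or self.n_bins < 1 or self.bin_ms <= 0:
            raise ValueError("n_channels, n_bins must be >= 1 and bin_ms > 0")
        lo, hi = self.baseline_range
        if lo < 0 or hi < lo:
            raise ValueError(f"invalid baseline_range {self.baseline_range}")
        lo, hi = self.modulation_range
        if lo < 0 or hi < lo:
            raise ValueError(f"invalid modulation_range {self.modulation_range}")
        if self.phase_profile is not None and len(self.phase_profile) != self.n_bins:
            raise ValueError("phase_profile length must equal n_bins")

    @property
    def n_classes(self) -> int:
        return PARADIGM_CLASSES[self.paradigm]

    @property
    def phase(self) -> np.ndarray:
        if self.phase_profile is not None:
            return np.asarray(self.phase_profile, dtype=float)
        return default_phase_profile(self.n_bins)


@dataclass(frozen=True)
class DriftSpec:
    """Magnitudes of the session-to-session distribution shift.

    ``gain_sigma`` is the log-scale SD of a per-channel multiplicative
    gain; ``dropout_prob`` the chance a channel loses its tuning
    (modulation set to zero — an electrode that drifted off its unit);
    ``tuning_jitter`` the SD in radians of preferred-direction (or,
    scaled by the loading SD, class-loading) perturbation;
    ``baseline_shift_sigma`` an additive baseline change in spikes/s.
    """

    gain_sigma: float = 0.15
    dropout_prob: float = 0.15
    tuning_jitter: float = 0.4
    baseline_shift_sigma: float = 2.0

    def __post_init__(self) -> None:
        if min(self.gain_sigma, self.tuning_jitter, self.baseline_shift_sigma) < 0:
            raise ValueError("drift magnitudes must be >= 0")
        if not 0 <= self.dropout_prob <= 1:
            raise ValueError(f"dropout_prob must be in [0,1], got {self.dropout_prob}")

    def scaled(self, level: float) -> "DriftSpec":
        """Spec with every magnitude multiplied by ``level`` (dropout capped at 1)."""
        return DriftSpec(
            gain_sigma=self.gain_sigma * level,
            dropout_prob=min(1.0, self.dropout_prob * level),
            tuning_jitter=self.tuning_jitter * level,
            baseline_shift_sigma=self.baseline_shift_sigma * level,
        )


@dataclass
class Population:
    """Sampled per-channel tuning: the generative state of one session."""

    spec: PopulationSpec
    baseline: np.ndarray          # (n_channels,) spikes/s
    modulation: np.ndarray        # (n_channels,) spikes/s (center-out)
    preferred: np.ndarray | None  # (n_channels,) radians, center-out only
    loadings: np.ndarray | None   # (n_channels, K) spikes/s, grasp/touch only


@dataclass
class SessionData:
    """One recording session: counts (trials x channels x bins) + labels."""

    spikes: np.ndarray
    labels: np.ndarray
    session_id: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spikes = np.asarray(self.spikes)
        self.labels = np.asarray(self.labels)
        if self.spikes.ndim != 3:
            raise ValueError("spikes must be (trials, channels, bins)")
        if self.labels.shape != (self.spikes.shape[0],):
            raise ValueError("labels must have one entry per trial")
        if self.spikes.size and self.spikes.min() < 0:
            raise ValueError("spike counts must be non-negative")

    @property
    def n_trials(self) -> int:
        return self.spikes.shape[0]

    @property
    def n_channels(self) -> int:
        return self.spikes.shape[1]

    @property
    def n_bins(self) -> int:
        return self.spikes.shape[2]

    def equals(self, other: "SessionData") -> bool:
        return (
            np.array_equal(self.spikes, other.spikes)
            and np.array_equal(self.labels, other.labels)
            and self.session_id == other.session_id
        )


# ---------------------------------------------------------------------------

def make_population(spec: PopulationSpec, seed: int) -> Population:
    """Sample per-channel tuning parameters; reproducible from the seed."""
    rng = np.random.default_rng(seed)
    b = rng.uniform(*spec.baseline_range, size=spec.n_channels)
    if spec.paradigm == "center_out_8":
        m = rng.uniform(*spec.modulation_range, size=spec.n_channels)
        theta = rng.uniform(0.0, 2.0 * np.pi, size=spec.n_channels)
        return Population(spec, b, m, theta, None)
    loadings = spec.loading_sigma * rng.standard_normal(
        (spec.n_channels, spec.n_classes)
    )
    return Population(spec, b, np.zeros(spec.n_channels), None, loadings)


def rate_profile(pop: Population, condition: int, bin_index: int | None = None):
    """Expected firing rates (spikes/s) per channel for one condition.

    With ``bin_index`` given, a single ``(n_channels,)`` vector; without,
    the full ``(n_channels, n_bins)`` rate matrix.  Center-out uses
    cosine tuning; grasp/touch adds the class loading.  Rates are
    clipped at zero before the phase envelope is applied.
    """
    spec = pop.spec
    if not 0 <= condition < spec.n_classes:
        raise ValueError(
            f"condition {condition} invalid for paradigm {spec.paradigm!r} "
            f"({spec.n_classes} classes)"
        )
    if spec.paradigm == "center_out_8":
        theta = 2.0 * np.pi * condition / spec.n_classes
        base = pop.baseline + pop.modulation * np.cos(theta - pop.preferred)
    else:
        base = pop.baseline + pop.loadings[:, condition]
    base = np.maximum(base, 0.0)
    phase = spec.phase
    if bin_index is not None:
        return base * phase[bin_index]
    return base[:, None] * phase[None, :]


def simulate_session(
    pop: Population,
    n_trials: int,
    seed: int,
    session_id: str = "session_0",
) -> SessionData:
    """Draw one session of Poisson spike counts with balanced conditions."""
    spec = pop.spec
    K = spec.n_classes
    if n_trials < K:
        raise ValueError(f"need at least {K} trials (one per class), got {n_trials}")
    rng = np.random.default_rng(seed)
    labels = np.arange(n_trials) % K
    rng.shuffle(labels)
    bin_s = spec.bin_ms / 1000.0
    means = np.stack([rate_profile(pop, c) * bin_s for c in range(K)])  # (K, Ch, T)
    counts = rng.poisson(means[labels]).astype(np.int16)
    return SessionData(
        spikes=counts,
        labels=labels.astype(np.int8),
        session_id=session_id,
        provenance=_jsonify({"population_spec": asdict(spec), "seed": int(seed)}),
    )


def apply_drift(pop: Population, drift: DriftSpec, seed: int) -> Population:
    """Independent per-channel drift; the input population is untouched."""
    spec = pop.spec
    rng = np.random.default_rng(seed)
    n = spec.n_channels
    gain = np.exp(drift.gain_sigma * rng.standard_normal(n))
    dropped = rng.random(n) < drift.dropout_prob
    baseline = np.maximum(
        0.0, pop.baseline * gain + drift.baseline_shift_sigma * rng.standard_normal(n)
    )
    if spec.paradigm == "center_out_8":
        modulation = pop.modulation * gain
        modulation[dropped] = 0.0
        preferred = pop.preferred + drift.tuning_jitter * rng.standard_normal(n)
        return Population(spec, baseline, modulation, preferred, None)
    loadings = pop.loadings * gain[:, None]
    # loading jitter: tuning_jitter (radians for center-out) reinterpreted as
    # a fraction of the loading SD for the discrete-class paradigm
    loadings = loadings + (
        drift.tuning_jitter * spec.loading_sigma
        * rng.standard_normal(loadings.shape)
    )
    loadings[dropped] = 0.0
    return Population(spec, baseline, np.zeros(n), None, loadings)


def make_cross_day_benchmark(
    pop_spec: PopulationSpec,
    n_sessions: int,
    trials_per_session: int,
    drift: DriftSpec,
    seed: int,
    random_walk: bool = False,
) -> list[SessionData]:
    """Multi-day benchmark: session 0 from the base population, later
    sessions from drifted copies (independent drifts of the base by
    default; chained drifts with ``random_walk``)."""
    if n_sessions < 2:
        raise ValueError("a cross-day benchmark needs at least 2 sessions")
    rng = np.random.default_rng(seed)
    pop_seed = int(rng.integers(2**31))
    base = make_population(pop_spec, pop_seed)
    sessions = []
    current = base
    for s in range(n_sessions):
        if s > 0:
            drift_seed = int(rng.integers(2**31))
            source = current if random_walk else base
            current = apply_drift(source, drift, drift_seed)
        else:
            drift_seed = None
        sess_seed = int(rng.integers(2**31))
        sess = simulate_session(current, trials_per_session, sess_seed, f"session_{s}")
        sess.provenance.update(
            _jsonify(
                dict(
                    benchmark_seed=int(seed),
                    population_seed=pop_seed,
                    drift_seed=drift_seed,
                    drift_spec=asdict(drift),
                    random_walk=bool(random_walk),
                    session_index=s,
                )
            )
        )
        sessions.append(sess)
    return sessions
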