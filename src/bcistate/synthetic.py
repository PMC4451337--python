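"""Synthetic EEG sessions with a planted mental-state / separability structure.

This module emulates the experimental protocol of a two-class active BCI
study: training sessions of cued mental-task trials, and online maze
sessions in which 2--4 candidate directions are each probed with a 5-s task
period and the user's fatigue / frustration / attention ratings are sampled
once per intersection.

The planted structure is fully known, which makes every downstream stage
testable:

* background EEG is per-channel AR(1) noise (coefficient ~0.95), giving a
  1/f-like spectral decay;
* the active class adds band-limited sinusoids (random phase per trial)
  inside ``base_band`` on a fixed subset of central channels, so the planted
  discriminative features are exactly band powers;
* each participant carries a multiplicative effect-size factor (session
  heterogeneity), and online trials are further scaled by a configurable
  *response surface* mapping the (fatigue, frustration, attention) cube to a
  separability multiplier in [0, 2];
* ratings follow a reflected bounded random walk, one sample per
  intersection.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.signal import lfilter

STATES = ("fatigue", "frustration", "attention")
REST = "rest"
TASKS = ("word_gen", "motor_imagery", "music_imagery", "mental_arith")

# Relative effect strength of the four candidate mental tasks. Word
# generation is the strongest, mirroring the fact that most participants in
# comparable studies end up selecting it.
TASK_FACTORS = {
    "word_gen": 1.0,
    "motor_imagery": 0.85,
    "music_imagery": 0.6,
    "mental_arith": 0.75,
}


# ---------------------------------------------------------------------------
# Response surfaces
# ---------------------------------------------------------------------------

class ResponseSurface:
    """Maps a mental-state triple in [0,1]^3 to a separability multiplier.

    The multiplier scales the amplitude of the planted active-class
    oscillation; it is clipped to [0, 2].
    """

    def __call__(self, fatigue: float, frustration: float, attention: float) -> float:
        raise NotImplementedError

    def evaluate(self, ratings: np.ndarray) -> np.ndarray:
        """Vectorised evaluation over an (n, 3) array of ratings."""
        r = np.atleast_2d(np.asarray(ratings, dtype=float))
        out = np.array([self(*row) for row in r])
        return out

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["kind"] = type(self).__name__
        return d


@dataclass
class ConstantSurface(ResponseSurface):
    """State-independent multiplier (the null: no planted state effect)."""

    value: float = 1.0

    def __call__(self, fatigue, frustration, attention):
        return float(np.clip(self.value, 0.0, 2.0))


@dataclass
class GaussianBumpSurface(ResponseSurface):
    """Isotropic Gaussian bump over two of the three states.

    multiplier = floor + (peak - floor) * exp(-d^2 / (2 width^2)) where d is
    the Euclidean distance from ``center`` in the plane spanned by ``axes``.
    """

    center: tuple = (0.6, 0.4)
    width: float = 0.2
    floor: float = 0.3
    peak: float = 1.6
    axes: tuple = ("fatigue", "frustration")

    def __call__(self, fatigue, frustration, attention):
        vals = {"fatigue": fatigue, "frustration": frustration, "attention": attention}
        d2 = sum((vals[a] - c) ** 2 for a, c in zip(self.axes, self.center))
        m = self.floor + (self.peak - self.floor) * np.exp(-d2 / (2.0 * self.width ** 2))
        return float(np.clip(m, 0.0, 2.0))


@dataclass
class LinearSurface(ResponseSurface):
    """Multiplier linear in a single state: low at rating 0, high at 1."""

    state: str = "attention"
    low: float = 0.3
    high: float = 1.5

    def __call__(self, fatigue, frustration, attention):
        vals = {"fatigue": fatigue, "frustration": frustration, "attention": attention}
        m = self.low + (self.high - self.low) * vals[self.state]
        return float(np.clip(m, 0.0, 2.0))


_SURFACES = {c.__name__: c for c in (ConstantSurface, GaussianBumpSurface, LinearSurface)}


def surface_from_dict(d: dict) -> ResponseSurface:
    d = dict(d)
    kind = d.pop("kind")
    cls = _SURFACES[kind]
    for key in ("center", "axes"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    return cls(**d)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    Defaults follow the emulated protocol: 256 Hz sampling, 15 channels,
    5-s task periods, two training sessions of 150 trials (30 per class over
    rest + four candidate tasks), three online maze sessions.

    ``effect_amplitude`` is the amplitude (uV) of the planted band-limited
    oscillation at multiplier 1; the default is calibrated so that two-class
    training cross-validation accuracy lands in the low-70% range typical of
    active mental-task BCIs.
    """

    n_participants: int = 10
    n_training_sessions: int = 2
    n_online_sessions: int = 3
    intersections_per_session: int = 50
    sampling_rate: float = 256.0
    trial_duration: float = 5.0
    n_channels: int = 15
    base_band: tuple = (10.0, 12.0)
    effect_amplitude: float = 0.27
    ar_coeff: float = 0.95
    noise_std: float = 1.0
    active_channels: tuple = (5, 6, 7, 8, 9)
    active_task: str = "word_gen"
    participant_sd: float = 0.35           # lognormal sigma of per-participant factor
    online_drift: float = 0.8              # test-session attenuation vs training
    k_probs: tuple = (0.2, 0.4, 0.4)       # P(K=2), P(K=3), P(K=4)
    state_walk: float = 0.08               # random-walk step sd per intersection
    response_surface: ResponseSurface = field(default_factory=ConstantSurface)
    session_time_limit_min: Optional[float] = None  # protocol mode: cap session length
    seed: int = 0

    def __post_init__(self):
        if min(self.n_participants, self.n_training_sessions, self.n_channels) <= 0:
            raise ValueError("counts must be positive")
        if self.sampling_rate <= 0 or self.trial_duration <= 0:
            raise ValueError("sampling_rate and trial_duration must be positive")
        if not (0 <= self.base_band[0] < self.base_band[1] < self.sampling_rate / 2):
            raise ValueError("base_band must lie inside (0, Nyquist)")
        if self.effect_amplitude < 0 or self.noise_std <= 0:
            raise ValueError("invalid amplitude/noise parameters")
        if abs(sum(self.k_probs) - 1.0) > 1e-9:
            raise ValueError("k_probs must sum to 1")
        if max(self.active_channels) >= self.n_channels:
            raise ValueError("active_channels out of range")

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate * self.trial_duration))

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["response_surface"] = self.response_surface.to_dict()
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "seed" not in d:
            raise ValueError("config file must specify a seed")
        if "response_surface" in d and isinstance(d["response_surface"], dict):
            d["response_surface"] = surface_from_dict(d["response_surface"])
        for key in ("base_band", "active_channels", "k_probs"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# Trial containers
# ---------------------------------------------------------------------------

@dataclass
class Trial:
    """One labelled 5-s task period: channels x samples signal in uV."""

    participant_id: int
    session_id: int
    signal: np.ndarray
    label: str                      # "rest" or "active"
    task: str                       # candidate-task name or "rest"
    intersection_id: Optional[int] = None
    period_index: Optional[int] = None
    ratings: Optional[tuple] = None  # (fatigue, frustration, attention)


@dataclass
class Intersection:
    """One maze choice point: K task periods, exactly one active."""

    participant_id: int
    session_id: int
    intersection_id: int
    trials: list
    true_index: int
    ratings: tuple

    @property
    def n_directions(self) -> int:
        return len(self.trials)


# ---------------------------------------------------------------------------
# Signal synthesis
# ---------------------------------------------------------------------------

def _rng(config: GeneratorConfig, *stream) -> np.random.Generator:
    # Independent, reproducible stream per (seed, participant, session, tag).
    return np.random.default_rng([int(config.seed) & 0x7FFFFFFF, *stream])


def _ar1_noise(rng, n_trials, n_channels, n_samples, coeff, std, burn=256):
    eps = std * rng.standard_normal((n_trials, n_channels, n_samples + burn))
    x = lfilter([1.0], [1.0, -coeff], eps, axis=-1)
    return x[..., burn:]


def _planted_bin_freqs(config: GeneratorConfig) -> np.ndarray:
    """One oscillation frequency per 1-Hz bin inside base_band.

    Frequencies snap to exact DFT bins of the trial window so planted power
    falls entirely inside the intended 1-Hz band (no spectral leakage).
    """
    lo, hi = config.base_band
    n = config.n_samples
    df = config.sampling_rate / n
    freqs = []
    for b in range(int(np.floor(lo)), int(np.ceil(hi))):
        f = np.round((b + 0.5) / df) * df
        if lo <= f < hi:
            freqs.append(f)
    return np.asarray(freqs)


def _synthesize_signals(config, rng, amplitudes):
    """Batch-synthesize len(amplitudes) trials.

    ``amplitudes`` holds per-trial oscillation amplitudes (0 for rest).
    Returns (n_trials, n_channels, n_samples) float64 in uV.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    n_trials = amplitudes.size
    n, c = config.n_samples, config.n_channels
    x = _ar1_noise(rng, n_trials, c, n, config.ar_coeff, config.noise_std)
    freqs = _planted_bin_freqs(config)
    t = np.arange(n) / config.sampling_rate
    active = np.nonzero(amplitudes > 0)[0]
    if active.size and freqs.size:
        # random phase per (trial, frequency); same waveform added to all
        # active channels of the trial
        phases = rng.uniform(0, 2 * np.pi, size=(n_trials, freqs.size))
        for i in active:
            wave = np.zeros(n)
            for f, ph in zip(freqs, phases[i]):
                wave += np.sin(2 * np.pi * f * t + ph)
            x[i, list(config.active_channels), :] += amplitudes[i] * wave
    return x


def participant_effect_factors(config: GeneratorConfig) -> np.ndarray:
    """Per-participant multiplicative effect-size factor (drawn once)."""
    rng = _rng(config, 0, 0, 0)
    f = np.exp(rng.normal(0.0, config.participant_sd, size=config.n_participants))
    return np.clip(f, 0.3, 2.5)


# ---------------------------------------------------------------------------
# Session generators
# ---------------------------------------------------------------------------

def generate_training_session(config: GeneratorConfig, participant_id: int,
                              session_id: int) -> list:
    """One cued training session: 150 trials, 30 per class (rest + 4 tasks).

    Trial order is shuffled within the session. Rest trials carry no planted
    oscillation; each candidate task carries its task factor times the
    participant's effect factor times ``effect_amplitude``.
    """
    if not (0 <= participant_id < config.n_participants):
        raise ValueError("participant_id out of range")
    rng = _rng(config, 1, participant_id, session_id)
    factor = participant_effect_factors(config)[participant_id]
    classes = [REST, *TASKS]
    tasks = np.repeat(classes, 30)
    rng.shuffle(tasks)
    amps = np.array([
        0.0 if task == REST
        else config.effect_amplitude * factor * TASK_FACTORS[task]
        for task in tasks
    ])
    signals = _synthesize_signals(config, rng, amps)
    return [
        Trial(participant_id=participant_id, session_id=session_id,
              signal=signals[i], task=tasks[i],
              label=REST if tasks[i] == REST else "active")
        for i in range(len(tasks))
    ]


def two_class_training_trials(config: GeneratorConfig, participant_id: int) -> list:
    """Training trials for the retained two-class problem.

    Pools the participant's training sessions and keeps the rest task and
    the selected active task (60 + 60 over two sessions).
    """
    out = []
    for s in range(config.n_training_sessions):
        for tr in generate_training_session(config, participant_id, s):
            if tr.task in (REST, config.active_task):
                out.append(tr)
    return out


def generate_online_session(config: GeneratorConfig, participant_id: int,
                            session_id: int,
                            surface: Optional[ResponseSurface] = None) -> list:
    """One online maze session: a list of :class:`Intersection`.

    Each intersection probes K ~ {2,3,4} directions with one 5-s task
    period per direction; exactly one (the intended direction) is active.
    Ratings evolve as a reflected random walk and are sampled once per
    intersection; all task periods of the intersection inherit them. The
    active oscillation amplitude is scaled by the response surface at the
    intersection's ratings and by the online drift factor.
    """
    surface = surface if surface is not None else config.response_surface
    rng = _rng(config, 2, participant_id, session_id)
    factor = participant_effect_factors(config)[participant_id]
    n_int = config.intersections_per_session

    ks = rng.choice([2, 3, 4], size=n_int, p=list(config.k_probs))
    if config.session_time_limit_min is not None:
        # protocol mode: each direction costs a 5-s task period plus a 5-s
        # break, plus ~10 s per intersection for the rating prompt and the
        # displayed move; the session stops at the time budget
        seconds = np.cumsum(ks * (config.trial_duration + 5.0) + 10.0)
        n_int = int(np.searchsorted(seconds,
                                    config.session_time_limit_min * 60.0,
                                    side="right"))
        if n_int == 0:
            raise ValueError("session time limit too short for one intersection")
        ks = ks[:n_int]
    true_idx = np.array([rng.integers(k) for k in ks])

    ratings = np.empty((n_int, 3))
    state = rng.uniform(0.0, 1.0, size=3)
    for i in range(n_int):
        state = state + rng.normal(0.0, config.state_walk, size=3)
        state = np.abs(state)
        state = np.where(state > 1.0, 2.0 - state, state)
        state = np.clip(state, 0.0, 1.0)
        ratings[i] = state

    # flatten task periods, batch-synthesize, then regroup
    amps, owner = [], []
    for i in range(n_int):
        mult = surface(*ratings[i])
        for j in range(ks[i]):
            is_active = j == true_idx[i]
            amps.append(config.effect_amplitude * factor * config.online_drift * mult
                        if is_active else 0.0)
            owner.append((i, j))
    signals = _synthesize_signals(config, rng, np.asarray(amps))

    intersections = []
    pos = 0
    for i in range(n_int):
        trials = []
        for j in range(ks[i]):
            is_active = j == true_idx[i]
            trials.append(Trial(
                participant_id=participant_id, session_id=session_id,
                signal=signals[pos],
                label="active" if is_active else REST,
                task=config.active_task if is_active else REST,
                intersection_id=i, period_index=j,
                ratings=tuple(ratings[i]),
            ))
            pos += 1
        intersections.append(Intersection(
            participant_id=participant_id, session_id=session_id,
            intersection_id=i, trials=trials,
            true_index=int(true_idx[i]), ratings=tuple(ratings[i]),
        ))
    return intersections


# ---------------------------------------------------------------------------
# Tabular export
# ---------------------------------------------------------------------------

def trials_to_long_frame(trials: Sequence[Trial]) -> pd.DataFrame:
    """Long-format signal table: one row per (trial, channel, sample)."""
    rows = []
    for t_idx, tr in enumerate(trials):
        c, n = tr.signal.shape
        rows.append(pd.DataFrame({
            "participant": tr.participant_id,
            "session": tr.session_id,
            "trial": t_idx,
            "channel": np.repeat(np.arange(c), n),
            "sample_index": np.tile(np.arange(n), c),
            "value": tr.signal.ravel(),
        }))
    return pd.concat(rows, ignore_index=True)


def metadata_frame(trials: Sequence[Trial]) -> pd.DataFrame:
    """One row per task period: ids, label, task, ratings."""
    rows = []
    for t_idx, tr in enumerate(trials):
        fat, fru, att = tr.ratings if tr.ratings is not None else (np.nan,) * 3
        rows.append({
            "participant": tr.participant_id, "session": tr.session_id,
            "intersection": tr.intersection_id if tr.intersection_id is not None else -1,
            "trial": t_idx, "period_index": tr.period_index,
            "label": tr.label, "task": tr.task,
            "fatigue": fat, "frustration": fru, "attention": att,
        })
    return pd.DataFrame(rows)
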