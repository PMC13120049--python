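"""Synthetic multi-subject, multi-session surface-EMG cohort generator.

Real sEMG during an isometric gesture hold is well approximated, at the level a
feature/classifier pipeline sees, by band-limited stochastic activity whose
amplitude envelope depends on the gesture and on electrode placement.  The
generator emulates exactly that structure: each (gesture, channel) pair has a
target RMS amplitude drawn once per subject (the activation matrix), each hold
is band-limited Gaussian noise scaled to that target, and sessions perturb the
picture through per-channel log-normal gain shifts and adjacent-channel leakage
(re-donning the armband never reproduces placement exactly).  Optional mains
interference and a white noise floor complete the model.

Amplitudes are expressed in z-units (active channels target RMS near 1) so
that clipping thresholds in the 1e-6..1e-1 range interact meaningfully with
the signal after z-score normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "DEFAULT_GESTURES",
    "GeneratorConfig",
    "ActivationMatrix",
    "Recording",
    "make_activation_matrix",
    "generate_recording",
    "generate_cohort",
]

#: 13-gesture vocabulary: three hand postures, six wrist movements, four grasps.
DEFAULT_GESTURES: tuple[str, ...] = (
    "HR", "HO", "HC",              # hand rest / open / closed
    "WF", "WE", "WP", "WS", "UF", "RF",  # wrist flexion/extension/pronation/...
    "FP", "KP", "SG", "CG",        # fine pinch, key pinch, spherical, cylindrical
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-level generator settings.

    Defaults mirror a five-channel wearable acquisition protocol: nine
    subjects, three sessions on consecutive days, thirteen gestures held for
    10 s each at 1925.9259 Hz, with the stochastic carrier band-limited to
    20-450 Hz.
    """

    n_subjects: int = 9
    n_sessions: int = 3
    n_channels: int = 5
    gesture_labels: tuple[str, ...] = DEFAULT_GESTURES
    fs: float = 1925.9259
    trial_duration: float = 10.0
    band: tuple[float, float] = (20.0, 450.0)
    mains_freq: float = 60.0
    mains_amplitude: float = 0.0
    session_gain_sd: float = 0.1
    session_mix: float = 0.05
    noise_floor: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_sessions < 1 or self.n_channels < 1:
            raise ValueError("subject/session/channel counts must be positive")
        low, high = self.band
        if not (0 < low < high < self.fs / 2):
            raise ValueError(f"band must satisfy 0 < low < high < fs/2, got {self.band}")
        if self.trial_duration <= 0:
            raise ValueError("trial_duration must be positive")
        if len(set(self.gesture_labels)) != len(self.gesture_labels):
            raise ValueError("gesture_labels must be unique")
        if not (0 <= self.session_mix < 0.5):
            raise ValueError("session_mix must lie in [0, 0.5)")


@dataclass(frozen=True)
class ActivationMatrix:
    """Gesture x channel target-RMS matrix (z-units), rest row near the floor."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("activation matrix must be 2-D (gesture x channel)")
        if np.any(v < 0):
            raise ValueError("activation entries must be nonnegative")
        object.__setattr__(self, "values", v)

    @property
    def n_gestures(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


@dataclass
class Recording:
    """One subject-session labeled signal stream.

    ``signal`` is channel x sample; ``label_stream`` holds one gesture label
    per sample.  Channel names are 1-based in reports ("ch1".."chN").
    """

    subject_id: str
    session_id: str
    fs: float
    signal: np.ndarray
    label_stream: np.ndarray
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.label_stream = np.asarray(self.label_stream)
        if self.signal.ndim != 2:
            raise ValueError("signal must be channel x sample")
        if self.signal.shape[1] != self.label_stream.shape[0]:
            raise ValueError("signal and label_stream must share sample count")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not self.channel_names:
            self.channel_names = [f"ch{i + 1}" for i in range(self.signal.shape[0])]
        if len(self.channel_names) != self.signal.shape[0]:
            raise ValueError("channel_names length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


def make_activation_matrix(
    n_gestures: int,
    n_channels: int,
    seed: int,
    *,
    rest_row: int | None = 0,
    rest_level: float = 0.05,
    low: float = 0.2,
    high: float = 1.5,
) -> ActivationMatrix:
    """Draw a gesture x channel target-RMS matrix.

    Active entries are uniform on [low, high] z-units; the designated rest row
    (the rest gesture, first by default) sits at ``rest_level`` on every
    channel.  Deterministic for a fixed seed; rows are pairwise distinct with
    probability one, and a redraw guards the measure-zero collision case.
    """
    if n_gestures < 2 or n_channels < 1:
        raise ValueError("need n_gestures >= 2 and n_channels >= 1")
    if not (0 <= low < high):
        raise ValueError("need 0 <= low < high")
    rng = np.random.default_rng(seed)
    for _ in range(16):
        values = rng.uniform(low, high, size=(n_gestures, n_channels))
        if rest_row is not None:
            values[rest_row] = rest_level
        if not _has_duplicate_rows(values):
            return ActivationMatrix(values)
    raise RuntimeError("could not draw distinct activation rows")  # pragma: no cover


def _has_duplicate_rows(values: np.ndarray) -> bool:
    n = values.shape[0]
    return any(
        np.array_equal(values[i], values[j]) for i in range(n) for j in range(i + 1, n)
    )


def _band_noise(rng: np.random.Generator, n: int, band: tuple[float, float], fs: float) -> np.ndarray:
    """Band-limited Gaussian noise standardized to unit RMS."""
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _session_effects(
    config: GeneratorConfig, subject_index: int, session_index: int
) -> tuple[np.ndarray, float]:
    """Per-session channel gains (log-normal) and adjacent-channel leakage."""
    ss = np.random.SeedSequence(
        entropy=config.seed, spawn_key=(7001, subject_index, session_index)
    )
    rng = np.random.default_rng(ss)
    gains = np.exp(rng.normal(0.0, config.session_gain_sd, size=config.n_channels))
    mix = rng.uniform(0.0, config.session_mix) if config.session_mix > 0 else 0.0
    return gains, mix


def _mix_adjacent(x: np.ndarray, mix: float) -> np.ndarray:
    """Linear leakage from neighbouring channels: y_c = (1-mix)x_c + mix*mean(adjacent)."""
    if mix == 0.0 or x.shape[0] == 1:
        return x
    n_ch = x.shape[0]
    out = np.empty_like(x)
    for c in range(n_ch):
        neigh = [i for i in (c - 1, c + 1) if 0 <= i < n_ch]
        out[c] = (1.0 - mix) * x[c] + mix * np.mean(x[neigh], axis=0)
    return out


def generate_recording(
    config: GeneratorConfig,
    activation: ActivationMatrix,
    subject_id: str,
    session_id: str,
    *,
    subject_index: int = 0,
    session_index: int = 0,
) -> Recording:
    """Synthesize one session: one hold per gesture in seeded random order.

    Each hold, per channel, is unit-RMS band-limited Gaussian noise scaled by
    session-gain x activation[g, c], mixed with adjacent channels, plus a white
    noise floor and an optional mains sinusoid.
    """
    if activation.n_gestures != len(config.gesture_labels):
        raise ValueError("activation rows must match gesture_labels")
    if activation.n_channels != config.n_channels:
        raise ValueError("activation columns must match n_channels")

    n_hold = int(round(config.trial_duration * config.fs))
    gains, mix = _session_effects(config, subject_index, session_index)

    ss = np.random.SeedSequence(
        entropy=config.seed, spawn_key=(7002, subject_index, session_index)
    )
    rng = np.random.default_rng(ss)
    order = rng.permutation(activation.n_gestures)

    segments: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    for g in order:
        hold = np.empty((config.n_channels, n_hold))
        for c in range(config.n_channels):
            target = gains[c] * activation.values[g, c]
            if target > 0:
                hold[c] = target * _band_noise(rng, n_hold, config.band, config.fs)
            else:
                hold[c] = 0.0
        hold = _mix_adjacent(hold, mix)
        if config.noise_floor > 0:
            hold += config.noise_floor * rng.standard_normal(hold.shape)
        segments.append(hold)
        labels.append(np.full(n_hold, config.gesture_labels[g]))

    sig = np.concatenate(segments, axis=1)
    if config.mains_amplitude > 0:
        t = np.arange(sig.shape[1]) / config.fs
        sig = sig + config.mains_amplitude * np.sin(2 * np.pi * config.mains_freq * t)
    return Recording(
        subject_id=subject_id,
        session_id=session_id,
        fs=config.fs,
        signal=sig,
        label_stream=np.concatenate(labels),
    )


def subject_activation(config: GeneratorConfig, subject_index: int) -> ActivationMatrix:
    """Subject-specific activation matrix (subject index folded into the seed)."""
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(7000, subject_index))
    sub_seed = int(ss.generate_state(1)[0] % (2**31))
    return make_activation_matrix(
        len(config.gesture_labels), config.n_channels, seed=sub_seed
    )


def generate_cohort(config: GeneratorConfig) -> list[Recording]:
    """Generate n_subjects x n_sessions recordings, one hold per gesture each.

    Distinct subjects get distinct activation matrices; everything is
    deterministic (byte-for-byte) for a fixed config.
    """
    recordings: list[Recording] = []
    for s in range(config.n_subjects):
        activation = subject_activation(config, s)
        for k in range(config.n_sessions):
            recordings.append(
                generate_recording(
                    config,
                    activation,
                    subject_id=f"S{s + 1:02d}",
                    session_id=f"sess{k + 1}",
                    subject_index=s,
                    session_index=k,
                )
            )
    return recordings


def micro_config(**overrides) -> GeneratorConfig:
    """Small cohort preset (2 subjects, 4 gestures, 2 s holds) for demos/smoke runs."""
    defaults = dict(
        n_subjects=2,
        n_sessions=2,
        gesture_labels=("HR", "HO", "HC", "WF"),
        trial_duration=2.0,
    )
    defaults.update(overrides)
    return GeneratorConfig(**defaults)
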