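"""Filtering, windowing, and train-partition z-score normalization.

The pipeline order is fixed by construction: raw streams are filtered
(mains notch cascade, then Butterworth band-pass, both zero-phase), segmented
into overlapping labeled windows, and only then normalized with statistics
fitted on the training partition of each split — so normalization can never
leak validation/test information, and clipping (see :mod:`emgstress.degrade`)
operates in z-units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .synth import Recording

__all__ = [
    "PreprocessConfig",
    "WindowSet",
    "NormStats",
    "notch_filter",
    "bandpass_filter",
    "filter_recording",
    "window_stream",
    "window_recordings",
    "fit_norm_stats",
    "apply_norm",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Filter + windowing defaults: 20-450 Hz order-4 Butterworth, 60 Hz notch
    cascade (3 harmonics, Q=30), 250 ms windows with 50 ms hop."""

    band: tuple[float, float] = (20.0, 450.0)
    order: int = 4
    notch_freq: float = 60.0
    notch_harmonics: int = 3
    notch_q: float = 30.0
    win_ms: float = 250.0
    hop_ms: float = 50.0
    label_rule: str = "uniform-only"
    delta: float = 1e-8


@dataclass
class WindowSet:
    """Overlapping fixed-length windows with one gesture label each.

    ``windows`` is window x channel x sample; ``provenance`` records
    (subject, session, start sample) per window.
    """

    windows: np.ndarray
    labels: np.ndarray
    L: int
    H: int
    fs: float
    provenance: pd.DataFrame

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows)
        if not np.issubdtype(self.windows.dtype, np.floating):
            self.windows = self.windows.astype(float)
        self.labels = np.asarray(self.labels)
        if self.windows.ndim != 3:
            raise ValueError("windows must be window x channel x sample")
        if self.windows.shape[2] != self.L:
            raise ValueError("window length must equal L")
        if self.H < 1:
            raise ValueError("hop must be >= 1")
        if len(self.labels) != self.windows.shape[0]:
            raise ValueError("one label per window required")
        if len(self.provenance) != self.windows.shape[0]:
            raise ValueError("one provenance row per window required")

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def n_channels(self) -> int:
        return self.windows.shape[1]

    def select(self, idx: np.ndarray) -> "WindowSet":
        """Subset by window index (used by split plans)."""
        return WindowSet(
            windows=self.windows[idx],
            labels=self.labels[idx],
            L=self.L,
            H=self.H,
            fs=self.fs,
            provenance=self.provenance.iloc[np.asarray(idx)].reset_index(drop=True),
        )


@dataclass(frozen=True)
class NormStats:
    """Per-channel z-score statistics with a small stabilizer delta."""

    mu: np.ndarray
    sigma: np.ndarray
    delta: float = 1e-8

    def __post_init__(self) -> None:
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=float))
        object.__setattr__(self, "sigma", np.asarray(self.sigma, dtype=float))
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be nonnegative")
        if self.delta <= 0:
            raise ValueError("delta must be positive")


def _check_nyquist(freq: float, fs: float, what: str) -> None:
    if freq >= fs / 2:
        raise ValueError(f"{what} at {freq} Hz is at/above Nyquist ({fs / 2} Hz)")


def notch_filter(
    signal: np.ndarray,
    fs: float,
    mains: float = 60.0,
    n_harmonics: int = 3,
    q: float = 30.0,
) -> np.ndarray:
    """Zero-phase cascade of IIR notches at mains, 2x mains, ... n_harmonics x mains."""
    x = np.asarray(signal, dtype=float)
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    _check_nyquist(mains * n_harmonics, fs, "notch harmonic")
    sections = []
    for k in range(1, n_harmonics + 1):
        b, a = sps.iirnotch(mains * k, q, fs=fs)
        sections.append(sps.tf2sos(b, a))
    sos = np.vstack(sections)
    return sps.sosfiltfilt(sos, x, axis=-1)


def bandpass_filter(
    signal: np.ndarray, fs: float, low: float = 20.0, high: float = 450.0, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the sample axis."""
    if not (0 < low < high):
        raise ValueError("need 0 < low < high")
    _check_nyquist(high, fs, "band edge")
    x = np.asarray(signal, dtype=float)
    sos = sps.butter(order, (low, high), btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


def filter_recording(recording: Recording, cfg: PreprocessConfig = PreprocessConfig()) -> Recording:
    """Notch cascade then Butterworth band-pass; labels/metadata untouched."""
    x = notch_filter(
        recording.signal, recording.fs, cfg.notch_freq, cfg.notch_harmonics, cfg.notch_q
    )
    x = bandpass_filter(x, recording.fs, cfg.band[0], cfg.band[1], cfg.order)
    return Recording(
        subject_id=recording.subject_id,
        session_id=recording.session_id,
        fs=recording.fs,
        signal=x,
        label_stream=recording.label_stream.copy(),
        channel_names=list(recording.channel_names),
    )


def _label_runs(labels: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) of maximal constant-label runs."""
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    edges = np.concatenate(([0], change, [len(labels)]))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(len(edges) - 1)]


def window_stream(
    recording: Recording,
    win_ms: float = 250.0,
    hop_ms: float = 50.0,
    label_rule: str = "uniform-only",
    dtype: np.dtype | None = None,
) -> WindowSet:
    """Segment one recording into overlapping labeled windows.

    L = round(fs*win_ms/1000), H = round(fs*hop_ms/1000).  Under the default
    ``uniform-only`` rule each contiguous constant-label segment is windowed
    independently (windows that would span a label change are dropped), giving
    floor((T - L)/H) + 1 windows per segment of length T >= L.  ``majority``
    and ``center`` window the whole stream and label each window by vote or by
    its center sample.  ``dtype`` optionally narrows window storage (e.g.
    float32 for large sweeps); None keeps the signal dtype.
    """
    L = int(round(recording.fs * win_ms / 1000.0))
    H = int(round(recording.fs * hop_ms / 1000.0))
    if L < 2 or H < 1:
        raise ValueError("window/hop too short for this sampling rate")
    if recording.n_samples < L:
        raise ValueError("recording shorter than one window")
    if label_rule not in ("uniform-only", "majority", "center"):
        raise ValueError(f"unknown label_rule {label_rule!r}")

    sig = recording.signal
    lab = recording.label_stream
    starts: list[int] = []
    win_labels: list = []

    if label_rule == "uniform-only":
        for a, b in _label_runs(lab):
            if b - a < L:
                continue
            seg_starts = range(a, b - L + 1, H)
            starts.extend(seg_starts)
            win_labels.extend([lab[a]] * len(seg_starts))
    else:
        for s in range(0, recording.n_samples - L + 1, H):
            starts.append(s)
            if label_rule == "center":
                win_labels.append(lab[s + L // 2])
            else:  # majority
                vals, counts = np.unique(lab[s : s + L], return_counts=True)
                win_labels.append(vals[np.argmax(counts)])

    if not starts:
        import warnings

        warnings.warn("no windows produced (all spans straddle label changes)")
        windows = np.empty((0, sig.shape[0], L))
    else:
        view = np.lib.stride_tricks.sliding_window_view(sig, L, axis=-1)
        windows = view[:, np.asarray(starts), :].transpose(1, 0, 2)
        windows = windows.astype(dtype) if dtype is not None else windows.copy()

    prov = pd.DataFrame(
        {
            "subject": recording.subject_id,
            "session": recording.session_id,
            "start": np.asarray(starts, dtype=int),
        }
    )
    return WindowSet(
        windows=windows,
        labels=np.asarray(win_labels),
        L=L,
        H=H,
        fs=recording.fs,
        provenance=prov,
    )


def concat_window_sets(sets: list[WindowSet]) -> WindowSet:
    """Pool windows from several recordings (same L/H/fs)."""
    if not sets:
        raise ValueError("nothing to concatenate")
    first = sets[0]
    for ws in sets[1:]:
        if (ws.L, ws.H) != (first.L, first.H) or ws.fs != first.fs:
            raise ValueError("incompatible window sets")
    return WindowSet(
        windows=np.concatenate([ws.windows for ws in sets], axis=0),
        labels=np.concatenate([ws.labels for ws in sets]),
        L=first.L,
        H=first.H,
        fs=first.fs,
        provenance=pd.concat([ws.provenance for ws in sets], ignore_index=True),
    )


def window_recordings(
    recordings: list[Recording], cfg: PreprocessConfig = PreprocessConfig()
) -> WindowSet:
    """Filter each recording then window and pool — the canonical front half of
    the pipeline (filtering always precedes segmentation)."""
    sets = [
        window_stream(filter_recording(r, cfg), cfg.win_ms, cfg.hop_ms, cfg.label_rule)
        for r in recordings
    ]
    return concat_window_sets(sets)


def fit_norm_stats(train_windows: WindowSet, delta: float = 1e-8) -> NormStats:
    """Per-channel mean/SD over all training-window samples pooled."""
    if train_windows.n_windows == 0:
        raise ValueError("cannot fit normalization on an empty training set")
    w = train_windows.windows
    n = w.shape[0] * w.shape[2]
    mu = w.mean(axis=(0, 2), dtype=np.float64)
    # E[x^2] - mu^2 without materializing a squared copy; values are O(1)
    # z-units so the subtraction is well conditioned
    ex2 = np.einsum("wcl,wcl->c", w, w, dtype=np.float64) / n
    var = np.maximum(ex2 - mu**2, 0.0)
    # below the cancellation noise floor the channel is constant
    var[var < 1e-10 * np.maximum(ex2, np.finfo(np.float64).tiny)] = 0.0
    return NormStats(mu=mu, sigma=np.sqrt(var), delta=delta)


def apply_norm(windows: WindowSet, stats: NormStats) -> WindowSet:
    """x' = (x - mu) / (sigma + delta), per channel; polarity preserved."""
    if len(stats.mu) != windows.n_channels:
        raise ValueError("channel count mismatch between windows and stats")
    dtype = windows.windows.dtype  # keep float32 storage as float32
    mu = stats.mu.astype(dtype)[None, :, None]
    inv = (1.0 / (stats.sigma + stats.delta)).astype(dtype)[None, :, None]
    scaled = windows.windows - mu
    scaled *= inv
    return replace_windows(windows, scaled)


def replace_windows(ws: WindowSet, new_values: np.ndarray) -> WindowSet:
    """Same metadata, new window values (shape-checked by the constructor)."""
    return WindowSet(
        windows=new_values,
        labels=ws.labels,
        L=ws.L,
        H=ws.H,
        fs=ws.fs,
        provenance=ws.provenance,
    )
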