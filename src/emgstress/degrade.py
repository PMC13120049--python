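"""Degradation operators: symmetric amplitude clipping and channel dropout.

Clipping models acquisition front-end saturation: y[n] = sign(x[n]) *
min(|x[n]|, tau) limits the signal to [-tau, tau] while preserving polarity.
It is idempotent, a pointwise 1-Lipschitz contraction (hence never increases
waveform length), and never increases RMS.  Under a zero-mean Gaussian signal
x ~ N(0, sigma^2), the probability that a sample saturates is
P_sat = Pr(|x| > tau) = 2 Q(tau/sigma) with Q the Gaussian upper tail.

Channel dropout models electrode disconnection; the default "zero-signal"
mode flat-lines the channel before feature extraction, while "drop-columns"
removes the channel's feature columns after extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .features import FeatureMatrix
from .preprocess import WindowSet, replace_windows

__all__ = [
    "DegradationSpec",
    "clip_signal",
    "saturation_probability",
    "empirical_saturation_fraction",
    "apply_dropout",
    "intermittent_dropout",
]


@dataclass(frozen=True)
class DegradationSpec:
    """Declarative description of one degradation condition.

    ``tau`` (z-units) applies when ``kind == 'clip'``; ``channel`` (1-based)
    when ``kind == 'dropout'``.  ``scope`` controls whether clipping hits all
    partitions of a split or only the test partition.
    """

    kind: str = "none"
    tau: float | None = None
    channel: int | None = None
    dropout_mode: str = "zero-signal"
    scope: str = "all-partitions"

    def __post_init__(self) -> None:
        if self.kind not in ("none", "clip", "dropout"):
            raise ValueError(f"unknown degradation kind {self.kind!r}")
        if self.kind == "clip" and (self.tau is None or self.tau <= 0):
            raise ValueError("clip requires tau > 0")
        if self.kind == "dropout" and (self.channel is None or self.channel < 1):
            raise ValueError("dropout requires a 1-based channel index")
        if self.dropout_mode not in ("zero-signal", "drop-columns"):
            raise ValueError(f"unknown dropout_mode {self.dropout_mode!r}")
        if self.scope not in ("all-partitions", "test-only"):
            raise ValueError(f"unknown scope {self.scope!r}")

    @property
    def label(self) -> str:
        if self.kind == "clip":
            return f"clip(tau={self.tau:g})"
        if self.kind == "dropout":
            return f"dropout(ch={self.channel},{self.dropout_mode})"
        return "clean"

    def to_dict(self) -> dict:
        d = {"kind": self.kind}
        if self.kind == "clip":
            d["tau"] = self.tau
            d["scope"] = self.scope
        if self.kind == "dropout":
            d["channel"] = self.channel
            d["dropout_mode"] = self.dropout_mode
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DegradationSpec":
        return cls(**d)


def clip_signal(x: np.ndarray, tau: float) -> np.ndarray:
    """Symmetric saturation: sign(x) * min(|x|, tau), any shape."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    x = np.asarray(x)
    if not np.issubdtype(x.dtype, np.floating):
        x = x.astype(float)
    # single-pass equivalent of sign(x) * min(|x|, tau)
    return np.clip(x, -tau, tau)


def saturation_probability(tau: float, sigma: float) -> float:
    """P(|x| > tau) = 2 Q(tau/sigma) for x ~ N(0, sigma^2)."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    return float(2.0 * stats.norm.sf(tau / sigma))


def empirical_saturation_fraction(x: np.ndarray, tau: float) -> float:
    """Fraction of samples with |x| > tau."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    return float(np.count_nonzero(np.abs(x) > tau) / x.size)


def apply_dropout(data, spec: DegradationSpec):
    """Apply single-channel dropout to a WindowSet (zero-signal) or a
    FeatureMatrix (drop-columns), returning the same type."""
    if spec.kind != "dropout":
        raise ValueError("spec.kind must be 'dropout'")
    ch = spec.channel
    if isinstance(data, WindowSet):
        if spec.dropout_mode != "zero-signal":
            raise ValueError("WindowSet dropout requires zero-signal mode")
        if not (1 <= ch <= data.n_channels):
            raise ValueError(f"channel {ch} out of range 1..{data.n_channels}")
        values = data.windows.copy()
        values[:, ch - 1, :] = 0.0
        return replace_windows(data, values)
    if isinstance(data, FeatureMatrix):
        if spec.dropout_mode != "drop-columns":
            raise ValueError("FeatureMatrix dropout requires drop-columns mode")
        max_ch = max(c for c, _, _ in data.column_names)
        if not (1 <= ch <= max_ch):
            raise ValueError(f"channel {ch} out of range 1..{max_ch}")
        return data.drop_channel(ch)
    raise TypeError(f"cannot apply dropout to {type(data).__name__}")


def intermittent_dropout(*args, **kwargs):  # pragma: no cover - experimental stub
    """Bursty/intermittent channel loss — reserved for future work."""
    raise NotImplementedError(
        "intermittent/bursty dropout is an experimental placeholder; only "
        "persistent single-channel dropout is supported"
    )
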