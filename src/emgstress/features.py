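"""Per-window sEMG features and feature-matrix assembly.

The four lightweight time-domain descriptors that dominate myoelectric
pattern recognition:

* RMS  — sqrt(mean(x_i^2)), amplitude,
* VAR  — unbiased sample variance (N-1 denominator), variability,
* ZC   — count of adjacent-sample polarity changes with -x_i*x_{i+1} > eps
         (eps suppresses noise-induced crossings; default 0 keeps the count
         meaningful under deep clipping, where products shrink to ~tau^2),
* WL   — waveform length, sum |x_{i+1} - x_i|, joint amplitude/frequency proxy,

plus auxiliary descriptors: Yule-Walker autoregressive coefficients, sample
entropy SampEn(m, r*SD), and the spectral mean (MNF, centroid) and median
(MDF, half-power) frequencies of a periodogram/Welch PSD estimate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocess import WindowSet

__all__ = [
    "FEATURE_NAMES",
    "FeatureSpec",
    "PSD",
    "FeatureMatrix",
    "rms",
    "variance",
    "zero_crossings",
    "waveform_length",
    "ar_coefficients",
    "sample_entropy",
    "estimate_psd",
    "mean_frequency",
    "median_frequency",
    "assemble_features",
]

FEATURE_NAMES: tuple[str, ...] = ("RMS", "VAR", "ZC", "WL", "AR", "SAEN", "MDF", "MNF")


@dataclass(frozen=True)
class FeatureSpec:
    """Which features to extract and their knobs.

    ``zc_eps`` is in squared z-units; ``saen_r`` is a multiple of the window
    SD; ``saen_cap`` replaces the +inf sentinel (no template matches) during
    assembly.
    """

    names: tuple[str, ...] = ("RMS", "WL")
    zc_eps: float = 0.0
    ar_order: int = 4
    saen_m: int = 2
    saen_r: float = 0.2
    saen_cap: float = 10.0
    psd_method: str = "periodogram"
    psd_detrend: str = "mean"

    def __post_init__(self) -> None:
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if not names or len(set(names)) != len(names):
            raise ValueError("feature names must be non-empty and unique")
        for n in names:
            if n not in FEATURE_NAMES:
                raise ValueError(f"unknown feature {n!r}; choose from {FEATURE_NAMES}")
        if self.zc_eps < 0:
            raise ValueError("zc_eps must be >= 0")
        if self.ar_order < 1 or self.saen_m < 1 or self.saen_r <= 0:
            raise ValueError("invalid AR/SampEn parameters")
        if self.psd_method not in ("periodogram", "welch"):
            raise ValueError("psd_method must be periodogram or welch")
        if self.psd_detrend not in ("none", "mean"):
            raise ValueError("psd_detrend must be none or mean")

    def n_columns(self, n_channels: int) -> int:
        per = {name: (self.ar_order if name == "AR" else 1) for name in self.names}
        return n_channels * sum(per.values())


@dataclass(frozen=True)
class PSD:
    """One-sided power spectral density estimate."""

    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        p = np.asarray(self.power, dtype=float)
        if f.shape != p.shape:
            raise ValueError("freqs and power must have equal length")
        if np.any(np.diff(f) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(p < 0):
            raise ValueError("power must be nonnegative")
        object.__setattr__(self, "freqs", f)
        object.__setattr__(self, "power", p)


@dataclass
class FeatureMatrix:
    """Window x feature-column matrix with column provenance.

    ``column_names`` are (channel, feature, component) triplets, channel
    1-based; ``groups`` carries (subject, session) per window.
    """

    values: np.ndarray
    column_names: list[tuple[int, str, int]]
    labels: np.ndarray
    groups: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != len(self.column_names):
            raise ValueError("column count mismatch")
        if self.values.shape[0] != len(self.labels):
            raise ValueError("one label per window required")
        if not np.all(np.isfinite(self.values)):
            w, c = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite feature value at window {w}, column {self.column_names[c]}"
            )

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def fuse(self, other: "FeatureMatrix") -> "FeatureMatrix":
        """Pairwise fusion = column-wise concatenation of two feature blocks."""
        if self.values.shape[0] != other.values.shape[0]:
            raise ValueError("window counts differ")
        if not np.array_equal(self.labels, other.labels):
            raise ValueError("labels differ between blocks")
        return FeatureMatrix(
            values=np.hstack([self.values, other.values]),
            column_names=self.column_names + other.column_names,
            labels=self.labels,
            groups=self.groups,
        )

    def drop_channel(self, channel: int) -> "FeatureMatrix":
        """Remove all feature columns of a 1-based channel."""
        keep = [i for i, (ch, _, _) in enumerate(self.column_names) if ch != channel]
        if len(keep) == self.n_columns:
            raise ValueError(f"channel {channel} has no columns in this matrix")
        return FeatureMatrix(
            values=self.values[:, keep],
            column_names=[self.column_names[i] for i in keep],
            labels=self.labels,
            groups=self.groups,
        )


# ---------------------------------------------------------------- scalar ops


def _check_window(x: np.ndarray, min_n: int, what: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < min_n:
        raise ValueError(f"{what} needs a 1-D window with at least {min_n} samples")
    return x


def rms(window: np.ndarray) -> float:
    """Root-mean-square amplitude, sqrt(mean(x_i^2))."""
    x = _check_window(window, 1, "rms")
    return float(np.sqrt(np.mean(x**2)))


def variance(window: np.ndarray) -> float:
    """Unbiased sample variance about the window mean (N-1 denominator)."""
    x = _check_window(window, 2, "variance")
    return float(np.var(x, ddof=1))


def zero_crossings(window: np.ndarray, eps: float = 0.0) -> int:
    """Count of adjacent pairs with -x_i * x_{i+1} strictly greater than eps."""
    x = _check_window(window, 2, "zero_crossings")
    if eps < 0:
        raise ValueError("eps must be >= 0")
    return int(np.count_nonzero(-x[:-1] * x[1:] > eps))


def waveform_length(window: np.ndarray) -> float:
    """Cumulative absolute sample-to-sample difference, sum |x_{i+1} - x_i|."""
    x = _check_window(window, 2, "waveform_length")
    return float(np.sum(np.abs(np.diff(x))))


def ar_coefficients(window: np.ndarray, order: int = 4) -> np.ndarray:
    """Yule-Walker AR coefficients of the order-p linear predictor
    x_t ~ sum_k a_k x_{t-k}.  A constant window yields all zeros."""
    x = _check_window(window, order + 2, "ar_coefficients")
    if np.std(x) == 0:
        return np.zeros(order)
    from statsmodels.regression.linear_model import yule_walker

    rho, _ = yule_walker(x, order=order, method="mle", demean=True)
    return np.asarray(rho, dtype=float)


def sample_entropy(window: np.ndarray, m: int = 2, r: float = 0.2) -> float:
    """SampEn(m, r*SD): -ln(A/B) with B (resp. A) the number of ordered pairs
    of m-length (resp. (m+1)-length) templates within Chebyshev tolerance,
    self-matches excluded.  Both counts use the first N-m template positions.
    Returns +inf when no matches exist (handled by assembly via ``saen_cap``).
    """
    x = _check_window(window, m + 2, "sample_entropy")
    n = x.size
    tol = r * float(np.std(x))
    n_templates = n - m  # positions 0..n-m-1 admit both m and m+1 templates
    tm = np.lib.stride_tricks.sliding_window_view(x, m)[:n_templates]
    tm1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)[:n_templates]

    def _pairs(templates: np.ndarray) -> int:
        d = np.max(np.abs(templates[:, None, :] - templates[None, :, :]), axis=-1)
        within = d <= tol
        np.fill_diagonal(within, False)
        return int(within.sum())

    b = _pairs(tm)
    a = _pairs(tm1)
    if b == 0 or a == 0:
        return math.inf
    return float(-math.log(a / b))


def estimate_psd(window: np.ndarray, fs: float, spec: FeatureSpec = FeatureSpec(names=("MNF",))) -> PSD:
    """One-sided PSD via periodogram (default) or Welch, mean removed first
    when ``psd_detrend == 'mean'``."""
    x = _check_window(window, 8, "estimate_psd")
    detrend = "constant" if spec.psd_detrend == "mean" else False
    if spec.psd_method == "welch":
        f, p = sps.welch(x, fs=fs, nperseg=min(256, x.size), detrend=detrend)
    else:
        f, p = sps.periodogram(x, fs=fs, detrend=detrend)
    return PSD(freqs=f, power=np.maximum(p, 0.0))


def mean_frequency(psd: PSD) -> float:
    """Spectral centroid: sum(f*P(f)) / sum(P(f))."""
    total = float(np.sum(psd.power))
    if total <= 0:
        raise ValueError("mean_frequency undefined for an all-zero spectrum")
    return float(np.sum(psd.freqs * psd.power) / total)


def median_frequency(psd: PSD) -> float:
    """Smallest grid frequency whose cumulative power reaches half the total
    (discrete convention, no interpolation)."""
    total = float(np.sum(psd.power))
    if total <= 0:
        raise ValueError("median_frequency undefined for an all-zero spectrum")
    cum = np.cumsum(psd.power)
    idx = int(np.searchsorted(cum, total / 2.0))
    return float(psd.freqs[idx])


# ---------------------------------------------------------------- assembly


def _batch_scalar(name: str, w: np.ndarray, spec: FeatureSpec) -> np.ndarray:
    """Vectorized W x C values for a scalar feature over windows w (W,C,L)."""
    if name == "RMS":
        return np.sqrt(np.mean(w**2, axis=-1))
    if name == "VAR":
        return np.var(w, ddof=1, axis=-1)
    if name == "ZC":
        return np.count_nonzero(-w[..., :-1] * w[..., 1:] > spec.zc_eps, axis=-1).astype(float)
    if name == "WL":
        return np.sum(np.abs(np.diff(w, axis=-1)), axis=-1)
    raise KeyError(name)


def _batch_spectral(name: str, w: np.ndarray, fs: float, spec: FeatureSpec) -> np.ndarray:
    detrend = "constant" if spec.psd_detrend == "mean" else False
    if spec.psd_method == "welch":
        f, p = sps.welch(w, fs=fs, nperseg=min(256, w.shape[-1]), detrend=detrend, axis=-1)
    else:
        f, p = sps.periodogram(w, fs=fs, detrend=detrend, axis=-1)
    p = np.maximum(p, 0.0)
    total = p.sum(axis=-1)
    if np.any(total <= 0):
        raise ValueError(f"{name} undefined for an all-zero spectrum (flat window?)")
    if name == "MNF":
        return (p * f).sum(axis=-1) / total
    cum = np.cumsum(p, axis=-1)
    idx = (cum >= (total / 2.0)[..., None]).argmax(axis=-1)
    return f[idx]


def assemble_features(windows: WindowSet, spec: FeatureSpec) -> FeatureMatrix:
    """Per-channel features concatenated feature-major: for each feature name
    in spec order, channels 1..C, then components (AR expands to ar_order
    columns).  Fusing two single-feature matrices column-wise therefore equals
    assembling the two names together.
    """
    if windows.n_windows == 0:
        raise ValueError("empty WindowSet")
    w = windows.windows
    n_win, n_ch, _ = w.shape
    blocks: list[np.ndarray] = []
    names: list[tuple[int, str, int]] = []

    for name in spec.names:
        if name in ("RMS", "VAR", "ZC", "WL"):
            vals = _batch_scalar(name, w, spec)  # (W, C)
            blocks.append(vals)
            names.extend((c + 1, name, 0) for c in range(n_ch))
        elif name in ("MNF", "MDF"):
            vals = _batch_spectral(name, w, windows.fs, spec)
            blocks.append(vals)
            names.extend((c + 1, name, 0) for c in range(n_ch))
        elif name == "AR":
            vals = np.empty((n_win, n_ch, spec.ar_order))
            for i in range(n_win):
                for c in range(n_ch):
                    vals[i, c] = ar_coefficients(w[i, c], spec.ar_order)
            blocks.append(vals.reshape(n_win, n_ch * spec.ar_order))
            names.extend(
                (c + 1, "AR", k) for c in range(n_ch) for k in range(spec.ar_order)
            )
        elif name == "SAEN":
            vals = np.empty((n_win, n_ch))
            capped = 0
            for i in range(n_win):
                for c in range(n_ch):
                    v = sample_entropy(w[i, c], spec.saen_m, spec.saen_r)
                    if math.isinf(v):
                        v = spec.saen_cap
                        capped += 1
                    vals[i, c] = v
            if capped:
                warnings.warn(
                    f"SAEN had no template matches for {capped} window-channel pairs; "
                    f"capped at {spec.saen_cap}"
                )
            blocks.append(vals)
            names.extend((c + 1, "SAEN", 0) for c in range(n_ch))
        else:  # pragma: no cover - spec validation excludes this
            raise KeyError(name)

    values = np.hstack(blocks)
    groups = windows.provenance[["subject", "session"]].reset_index(drop=True)
    return FeatureMatrix(
        values=values, column_names=names, labels=windows.labels.copy(), groups=groups
    )
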