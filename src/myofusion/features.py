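"""Denoising, windowing and sEMG feature extraction.

Implements the 15-480 Hz band-pass + 50 Hz notch front end (zero-phase),
250 ms / 50 ms sliding-window segmentation, ten time-domain and six
frequency-domain features, Spearman redundancy analysis with greedy
selection, and train-statistics standardization.

Note on SFA: the feature list names "Slow Feature Analysis" as a scalar
frequency-domain feature without defining it.  Here SFA is implemented as
the slowness statistic — the variance of the temporal first difference of
the unit-variance-normalized window — i.e. the quantity slow feature
analysis minimizes.  This is a reconstruction, not a published formula.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .synthetic import EmgRecording

__all__ = [
    "FilterConfig",
    "WindowingConfig",
    "Thresholds",
    "FeatureCatalog",
    "TD_FEATURES",
    "FD_FEATURES",
    "ALL_FEATURES",
    "HYBRID_FEATURES",
    "filter_recording",
    "segment_windows",
    "time_domain_features",
    "frequency_domain_features",
    "compute_feature_table",
    "estimate_thresholds",
    "spearman_redundancy",
    "Standardizer",
]

TD_FEATURES = ("RMS", "MAV", "WL", "ZC", "SSC", "VAR", "SSI", "MAX", "LogD", "WAMP")
FD_FEATURES = ("SFA", "MF", "F-DC", "F-M", "F-STD", "F-ENT")
ALL_FEATURES = TD_FEATURES + FD_FEATURES
HYBRID_FEATURES = ("WL", "WAMP", "F-ENT")


class ConfigError(ValueError):
    """Raised for invalid filter/windowing configuration."""


@dataclass(frozen=True)
class FilterConfig:
    band: tuple[float, float] = (15.0, 480.0)
    notch_freq: float = 50.0
    butter_order: int = 4
    notch_quality: float = 30.0

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not 0 < lo < hi:
            raise ConfigError("band must satisfy 0 < low < high")
        if self.butter_order < 1:
            raise ConfigError("butter_order must be >= 1")
        if self.notch_quality <= 0:
            raise ConfigError("notch_quality must be positive")


@dataclass(frozen=True)
class WindowingConfig:
    window_ms: float = 250.0
    step_ms: float = 50.0

    def __post_init__(self) -> None:
        if self.window_ms <= 0 or self.step_ms <= 0:
            raise ConfigError("window and step must be positive")
        if self.step_ms > self.window_ms:
            raise ConfigError("step must not exceed window length")

    def in_samples(self, fs: float) -> tuple[int, int]:
        w = self.window_ms * fs / 1000.0
        s = self.step_ms * fs / 1000.0
        if abs(w - round(w)) > 1e-9 or abs(s - round(s)) > 1e-9:
            raise ConfigError(
                f"window/step ({self.window_ms}/{self.step_ms} ms) must be whole "
                f"samples at fs={fs}"
            )
        return int(round(w)), int(round(s))


@dataclass(frozen=True)
class Thresholds:
    """Comparator thresholds for ZC/SSC/WAMP, in signal units."""

    wamp_thr: float = 0.0
    zc_thr: float = 0.0
    ssc_thr: float = 0.0

    def __post_init__(self) -> None:
        if min(self.wamp_thr, self.zc_thr, self.ssc_thr) < 0:
            raise ConfigError("thresholds must be >= 0")


@dataclass(frozen=True)
class FeatureCatalog:
    names: tuple[str, ...] = ALL_FEATURES
    thresholds: Thresholds = field(default_factory=Thresholds)


def filter_recording(rec: EmgRecording, cfg: FilterConfig = FilterConfig()) -> EmgRecording:
    """Band-pass + notch, applied forward-backward (zero phase) per channel."""
    lo, hi = cfg.band
    if hi >= rec.fs / 2:
        raise ConfigError(f"band edge {hi} Hz is outside Nyquist ({rec.fs / 2} Hz)")
    sos = signal.butter(cfg.butter_order, cfg.band, btype="bandpass", fs=rec.fs, output="sos")
    b_notch, a_notch = signal.iirnotch(cfg.notch_freq, cfg.notch_quality, fs=rec.fs)
    out = np.empty_like(rec.samples)
    for c in range(rec.n_channels):
        x = signal.sosfiltfilt(sos, rec.samples[c])
        out[c] = signal.filtfilt(b_notch, a_notch, x)
    return EmgRecording(samples=out, fs=rec.fs, reference=rec.reference)


@dataclass(frozen=True)
class Window:
    samples: np.ndarray  # (n_channels, window_samples)
    t: float  # window-center time, s
    label: float  # mean reference angle over the window, degrees
    interval_index: int  # target interval at the window center; -1 if absent


def n_windows(n_samples: int, window: int, step: int) -> int:
    if n_samples < window:
        return 0
    return 1 + (n_samples - window) // step


def segment_windows(rec: EmgRecording, cfg: WindowingConfig = WindowingConfig()) -> list[Window]:
    """Overlapping windows at offsets 0, step, 2*step, ..."""
    w, s = cfg.in_samples(rec.fs)
    count = n_windows(rec.n_samples, w, s)
    if count == 0:
        warnings.warn("recording shorter than one window; no windows produced")
        return []
    ref = rec.reference
    out = []
    for k in range(count):
        a, b = k * s, k * s + w
        center = a + w // 2
        idx = -1 if ref.interval_index is None else int(ref.interval_index[center])
        out.append(
            Window(
                samples=rec.samples[:, a:b],
                t=float(ref.times[center]),
                label=float(ref.angles[a:b].mean()),
                interval_index=idx,
            )
        )
    return out


def time_domain_features(x: np.ndarray, thresholds: Thresholds = Thresholds()) -> dict[str, float]:
    """Ten time-domain features of a single-channel window.

    RMS, MAV, WL, ZC (sign changes with amplitude gap >= zc_thr),
    SSC (slope-sign products exceeding ssc_thr), VAR (sample variance),
    SSI, MAX, LogD (geometric mean of |x| with an epsilon floor) and
    WAMP (first differences of magnitude >= wamp_thr).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("window must contain at least 2 samples")
    d = np.diff(x)
    eps = np.finfo(float).eps
    zc = int(np.count_nonzero((x[:-1] * x[1:] < 0) & (np.abs(d) >= thresholds.zc_thr)))
    prod = (x[1:-1] - x[:-2]) * (x[1:-1] - x[2:])
    return {
        "RMS": float(np.sqrt(np.mean(x**2))),
        "MAV": float(np.mean(np.abs(x))),
        "WL": float(np.sum(np.abs(d))),
        "ZC": float(zc),
        "SSC": float(np.count_nonzero(prod > thresholds.ssc_thr)),
        "VAR": float(np.var(x, ddof=1)),
        "SSI": float(np.sum(x**2)),
        "MAX": float(np.max(np.abs(x))),
        "LogD": float(np.exp(np.mean(np.log(np.maximum(np.abs(x), eps))))),
        "WAMP": float(np.count_nonzero(np.abs(d) >= thresholds.wamp_thr)),
    }


def power_spectrum(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Hann-tapered power spectrum |FFT(w*x)|^2 (unnormalized)."""
    x = np.asarray(x, dtype=float)
    w = signal.get_window("hann", x.size)
    p = np.abs(np.fft.rfft(w * x)) ** 2
    f = np.fft.rfftfreq(x.size, d=1.0 / fs)
    return f, p


def frequency_domain_features(x: np.ndarray, fs: float) -> dict[str, float]:
    """Six frequency-domain features of a single-channel window.

    For an all-zero window the spectral features follow the documented
    convention MF = 0, F-ENT = 0 (and F-M, F-STD, SFA = 0).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 8:
        raise ValueError("window must contain at least 8 samples")
    f, p = power_spectrum(x, fs)
    total = p.sum()
    std = x.std()
    if std > 0:
        z = (x - x.mean()) / std
        sfa = float(np.var(np.diff(z)))
    else:
        sfa = 0.0
    if total <= 0:
        return {"SFA": sfa, "MF": 0.0, "F-DC": 0.0, "F-M": 0.0, "F-STD": 0.0, "F-ENT": 0.0}
    q = p / total
    fm = float(np.sum(f * q))
    fstd = float(np.sqrt(np.sum((f - fm) ** 2 * q)))
    mf = float(f[np.argmax(np.cumsum(p) >= total / 2)])
    qa = q[q > 0]
    ent = float(-np.sum(qa * np.log(qa)))
    return {"SFA": sfa, "MF": mf, "F-DC": float(p[0]), "F-M": fm, "F-STD": fstd, "F-ENT": ent}


def window_features(
    win: Window, fs: float, catalog: FeatureCatalog = FeatureCatalog()
) -> dict[str, float]:
    """Flattened per-channel features ``ch{N}_{FEAT}`` for one window."""
    out: dict[str, float] = {}
    wanted_td = [n for n in catalog.names if n in TD_FEATURES]
    wanted_fd = [n for n in catalog.names if n in FD_FEATURES]
    for c in range(win.samples.shape[0]):
        x = win.samples[c]
        td = time_domain_features(x, catalog.thresholds) if wanted_td else {}
        fd = frequency_domain_features(x, fs) if wanted_fd else {}
        for name in catalog.names:
            out[f"ch{c + 1}_{name}"] = td[name] if name in TD_FEATURES else fd[name]
    return out


def feature_columns(n_channels: int, names: tuple[str, ...]) -> list[str]:
    return [f"ch{c + 1}_{n}" for c in range(n_channels) for n in names]


def compute_feature_table(
    rec: EmgRecording,
    windowing: WindowingConfig = WindowingConfig(),
    catalog: FeatureCatalog = FeatureCatalog(),
) -> pd.DataFrame:
    """Feature table with columns t, label, interval_idx, then chN_FEAT."""
    rows = []
    for win in segment_windows(rec, windowing):
        row = {"t": win.t, "label": win.label, "interval_idx": win.interval_index}
        row.update(window_features(win, rec.fs, catalog))
        rows.append(row)
    cols = ["t", "label", "interval_idx"] + feature_columns(rec.n_channels, catalog.names)
    return pd.DataFrame(rows, columns=cols)


def estimate_thresholds(
    rec: EmgRecording, rest_quantile: float = 0.1, scale: float = 2.0
) -> Thresholds:
    """Comparator thresholds from low-activation (near-rest) signal.

    Takes the samples whose |reference angle| falls in the lowest
    ``rest_quantile`` of the session, computes the per-channel standard
    deviation there, and sets every threshold to ``scale`` times the
    median across channels.
    """
    mag = np.abs(rec.reference.angles)
    mask = mag <= np.quantile(mag, rest_quantile)
    if mask.sum() < 10:
        mask = np.ones(rec.n_samples, dtype=bool)
    thr = scale * float(np.median(rec.samples[:, mask].std(axis=1)))
    return Thresholds(wamp_thr=thr, zc_thr=thr, ssc_thr=thr * thr)


def spearman_redundancy(
    features: pd.DataFrame | np.ndarray,
    names: list[str] | None = None,
    threshold: float = 0.8,
) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise |Spearman rho| across feature columns + greedy selection.

    Features are scanned in column order; one is kept if its |rho| with
    every already-kept feature is below ``threshold``.  Constant columns
    have undefined correlations: they are reported as NaN and excluded
    from the selection.
    """
    if isinstance(features, pd.DataFrame):
        mat = features.to_numpy(dtype=float)
        names = list(features.columns) if names is None else names
    else:
        mat = np.asarray(features, dtype=float)
        names = [f"f{i}" for i in range(mat.shape[1])] if names is None else names
    if mat.shape[0] < 10:
        raise ValueError("need at least 10 windows for redundancy analysis")
    constant = mat.std(axis=0) == 0
    p = mat.shape[1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if p == 1:
            rho = np.ones((1, 1))
        elif p == 2:  # spearmanr returns a scalar for two columns
            r = stats.spearmanr(mat[:, 0], mat[:, 1]).statistic
            rho = np.array([[1.0, r], [r, 1.0]])
        else:
            rho = np.asarray(stats.spearmanr(mat).statistic)
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    np.fill_diagonal(rho, 1.0)
    rho_df = pd.DataFrame(rho, index=names, columns=names)
    selected: list[str] = []
    for j, name in enumerate(names):
        if constant[j]:
            continue
        kept_idx = [names.index(s) for s in selected]
        if all(abs(rho[j, k]) < threshold for k in kept_idx):
            selected.append(name)
    return rho_df, selected


class Standardizer:
    """Per-dimension z-scoring with train-split statistics."""

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, X: np.ndarray | pd.DataFrame) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        scale = X.std(axis=0)
        if np.any(scale == 0):
            warnings.warn("zero-variance feature dimension; using unit divisor")
            scale = np.where(scale == 0, 1.0, scale)
        self.scale_ = scale
        return self

    def _check(self) -> None:
        if self.mean_ is None:
            raise RuntimeError("Standardizer is not fitted")

    def transform(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        self._check()
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        self._check()
        return np.asarray(Z, dtype=float) * self.scale_ + self.mean_

    def fit_transform(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        return self.fit(X).transform(X)

    def to_dict(self) -> dict:
        self._check()
        return {"mean": self.mean_.tolist(), "scale": self.scale_.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        obj = cls()
        obj.mean_ = np.asarray(d["mean"], dtype=float)
        obj.scale_ = np.asarray(d["scale"], dtype=float)
        return obj
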