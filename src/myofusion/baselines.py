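"""Comparison post-processing filters behind one stream interface.

Five classic smoothers — moving average (MA), exponential moving average
(EMA), median filter (MF), Savitzky–Golay (SG) and wavelet denoising
(WD) — each mapping a length-n prediction sequence to a length-n
smoothed sequence.  All default variants are causal (output at t uses
inputs at or before t) so latency comparisons against the fusion
post-processor are fair; MF/SG/WD also offer a centered offline mode for
open-loop analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import medfilt, savgol_filter

from ._dwt import DAUB4_LOWPASS, wavedec, waverec

__all__ = [
    "BaselineConfig",
    "BASELINE_METHODS",
    "moving_average",
    "ema",
    "median_filter_seq",
    "savitzky_golay_seq",
    "wavelet_denoise",
    "apply_baseline",
    "StreamFilter",
]

BASELINE_METHODS = ("MA", "EMA", "MF", "SG", "WD")


@dataclass(frozen=True)
class BaselineConfig:
    method: str = "EMA"
    m: int = 9  # window length for MA/MF/SG
    lam: float = 0.7  # EMA weight
    sg_order: int = 2
    wd_level: int = 3
    wd_block: int = 64  # trailing block length for streaming WD
    wd_threshold: float | None = None  # None = universal threshold
    centered: bool = False  # offline centered variants for MF/SG/WD

    def __post_init__(self) -> None:
        if self.method not in BASELINE_METHODS:
            raise ValueError(f"method must be one of {BASELINE_METHODS}")
        if not 0 <= self.lam < 1:
            raise ValueError("lambda must be in [0, 1)")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.method in ("MF", "SG") and self.m % 2 == 0:
            raise ValueError(f"{self.method} window length must be odd")
        if self.method == "SG" and self.sg_order >= self.m:
            raise ValueError("sg_order must be < m")


def moving_average(seq: np.ndarray, m: int) -> np.ndarray:
    """Causal mean of the last min(m, t+1) values."""
    seq = np.asarray(seq, dtype=float)
    if seq.size == 0:
        return seq.copy()
    c = np.concatenate([[0.0], np.cumsum(seq)])
    t = np.arange(seq.size)
    lo = np.maximum(0, t - m + 1)
    return (c[t + 1] - c[lo]) / (t + 1 - lo)


def ema(seq: np.ndarray, lam: float) -> np.ndarray:
    """Exact recursion ``out[t] = lam*out[t-1] + (1-lam)*seq[t]``."""
    seq = np.asarray(seq, dtype=float)
    out = np.empty_like(seq)
    if seq.size == 0:
        return out
    out[0] = seq[0]
    for t in range(1, seq.size):
        out[t] = lam * out[t - 1] + (1.0 - lam) * seq[t]
    return out


def median_filter_seq(seq: np.ndarray, m: int, centered: bool = False) -> np.ndarray:
    """Median over a trailing (or centered) window, truncated at edges."""
    if m % 2 == 0:
        raise ValueError("median filter window must be odd")
    seq = np.asarray(seq, dtype=float)
    if seq.size == 0:
        return seq.copy()
    if centered:
        return medfilt(seq, kernel_size=min(m, seq.size | 1))
    out = np.empty_like(seq)
    for t in range(seq.size):
        out[t] = np.median(seq[max(0, t - m + 1): t + 1])
    return out


def savitzky_golay_seq(
    seq: np.ndarray, m: int, order: int, centered: bool = False
) -> np.ndarray:
    """Least-squares polynomial fit per window.

    The causal variant fits the trailing window and evaluates the
    polynomial at the window's last point; truncated start windows reduce
    the fit order as needed.
    """
    if m % 2 == 0:
        raise ValueError("SG window length must be odd")
    if order >= m:
        raise ValueError("polynomial order must be < window length")
    seq = np.asarray(seq, dtype=float)
    if seq.size == 0:
        return seq.copy()
    if centered:
        if seq.size < m:
            return seq.copy()
        return savgol_filter(seq, window_length=m, polyorder=order)
    out = np.empty_like(seq)
    for t in range(seq.size):
        win = seq[max(0, t - m + 1): t + 1]
        deg = min(order, win.size - 1)
        # abscissa with the evaluation point at 0 for conditioning
        xs = np.arange(win.size, dtype=float) - (win.size - 1)
        out[t] = np.polyfit(xs, win, deg)[-1] if deg > 0 else win.mean()
    return out


def _denoise_block(block: np.ndarray, level: int, threshold: float | None) -> np.ndarray:
    """Universal-soft-threshold wavelet denoising of one block."""
    n = block.size
    # pad to a multiple of 2^level with edge values (periodized transform)
    mult = 2**level
    pad = (-n) % mult
    x = np.concatenate([block, np.full(pad, block[-1])]) if pad else block
    coeffs = wavedec(x, level, DAUB4_LOWPASS)
    if threshold is None:
        finest = coeffs[-1]
        sigma = np.median(np.abs(finest)) / 0.6745 if finest.size else 0.0
        threshold = sigma * np.sqrt(2.0 * np.log(max(x.size, 2)))
    den = [coeffs[0]] + [
        np.sign(d) * np.maximum(np.abs(d) - threshold, 0.0) for d in coeffs[1:]
    ]
    return waverec(den, DAUB4_LOWPASS)[:n]


def wavelet_denoise(
    seq: np.ndarray,
    level: int = 3,
    threshold: float | None = None,
    block: int = 64,
    centered: bool = False,
) -> np.ndarray:
    """Wavelet denoising of a prediction sequence.

    Offline (``centered=True``): one transform over the whole sequence.
    Streaming (default): for each t the trailing ``block`` samples are
    denoised and the last output sample is emitted, keeping the filter
    causal.  Inputs shorter than one transform step pass through with a
    warning.
    """
    seq = np.asarray(seq, dtype=float)
    if seq.size < 2**level:
        if seq.size:
            warnings.warn("sequence too short for wavelet denoising; passthrough")
        return seq.copy()
    if centered:
        return _denoise_block(seq, level, threshold)
    out = np.empty_like(seq)
    for t in range(seq.size):
        win = seq[max(0, t - block + 1): t + 1]
        if win.size < 2**level:
            out[t] = seq[t]
        else:
            out[t] = _denoise_block(win, level, threshold)[-1]
    return out


def apply_baseline(seq: np.ndarray, cfg: BaselineConfig) -> np.ndarray:
    """Dispatch a sequence through the configured post-processor."""
    if cfg.method == "MA":
        return moving_average(seq, cfg.m)
    if cfg.method == "EMA":
        return ema(seq, cfg.lam)
    if cfg.method == "MF":
        return median_filter_seq(seq, cfg.m, centered=cfg.centered)
    if cfg.method == "SG":
        return savitzky_golay_seq(seq, cfg.m, cfg.sg_order, centered=cfg.centered)
    return wavelet_denoise(
        seq, level=cfg.wd_level, threshold=cfg.wd_threshold,
        block=cfg.wd_block, centered=cfg.centered,
    )


class StreamFilter:
    """Streaming wrapper: feed predictions one at a time.

    Maintains the input history and re-applies the causal batch filter to
    the trailing suffix, so streaming and batch outputs agree exactly.
    """

    def __init__(self, cfg: BaselineConfig):
        if cfg.centered:
            raise ValueError("streaming use requires a causal (non-centered) config")
        self.cfg = cfg
        self._hist: list[float] = []
        self._ema_state: float | None = None

    def update(self, value: float) -> float:
        value = float(value)
        if self.cfg.method == "EMA":  # O(1) exact recursion
            if self._ema_state is None:
                self._ema_state = value
            else:
                self._ema_state = self.cfg.lam * self._ema_state + (1 - self.cfg.lam) * value
            return self._ema_state
        self._hist.append(value)
        span = {"MA": self.cfg.m, "MF": self.cfg.m, "SG": self.cfg.m, "WD": self.cfg.wd_block}
        tail = np.asarray(self._hist[-span[self.cfg.method]:])
        return float(apply_baseline(tail, self.cfg)[-1])
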