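"""Open-loop and closed-loop performance metrics.

Open loop: hit rate (fraction of predictions inside the cued target
interval) and wrist smoothness (mean absolute first difference of the
predicted angle sequence).  Closed loop: task completion time, robot
trajectory smoothness (mean absolute difference of discrete Menger
curvature between adjacent steps) and tracking error (mean shortest
distance from each path point to the reference polyline).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import interval_edges

__all__ = [
    "IntervalTargets",
    "hit_rate",
    "wrist_smoothness",
    "menger_curvature",
    "trajectory_smoothness",
    "tracking_error",
    "compare_methods",
    "plot_comparison",
]


@dataclass
class IntervalTargets:
    """Per-step target interval [lo, hi) in degrees.

    Intervals are half-open with the topmost closed at ``+phi_RM``
    (membership of that endpoint is handled in :func:`hit_rate`).
    """

    lo: np.ndarray
    hi: np.ndarray
    top: float  # closed upper endpoint of the topmost interval

    @classmethod
    def from_indices(
        cls, indices: np.ndarray, phi_LM: float = 60.0, phi_RM: float = 60.0
    ) -> "IntervalTargets":
        e = interval_edges(phi_LM, phi_RM)
        idx = np.asarray(indices, dtype=int)
        if idx.min() < 0 or idx.max() > 6:
            raise ValueError("interval indices must be in 0..6")
        return cls(lo=e[idx], hi=e[idx + 1], top=float(e[-1]))

    def __len__(self) -> int:
        return self.lo.size

    def contains(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        inside = (theta >= self.lo) & (theta < self.hi)
        # topmost interval is closed at +phi_RM
        return inside | ((self.hi == self.top) & (theta == self.top))


def hit_rate(predictions: np.ndarray, targets: IntervalTargets) -> float:
    """Fraction of predictions falling inside their target interval."""
    predictions = np.asarray(predictions, dtype=float)
    if predictions.size == 0:
        raise ValueError("empty prediction sequence")
    if predictions.size != len(targets):
        raise ValueError("predictions and targets length mismatch")
    return float(np.mean(targets.contains(predictions)))


def wrist_smoothness(seq: np.ndarray) -> float:
    """Mean absolute first difference; smaller is smoother."""
    seq = np.asarray(seq, dtype=float)
    if seq.size < 2:
        raise ValueError("need at least 2 samples")
    return float(np.mean(np.abs(np.diff(seq))))


def menger_curvature(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Curvature of the circumscribed circle through three points.

    ``kappa = 4 * area / (|p1p2| |p2p3| |p3p1|)``; collinear points give 0.
    """
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    a = np.linalg.norm(p2 - p1)
    b = np.linalg.norm(p3 - p2)
    c = np.linalg.norm(p3 - p1)
    if min(a, b, c) == 0:
        raise ValueError("coincident points")
    cross = (p2[0] - p1[0]) * (p3[1] - p1[1]) - (p2[1] - p1[1]) * (p3[0] - p1[0])
    return float(2.0 * abs(cross) / (a * b * c))


def trajectory_smoothness(path: np.ndarray) -> float:
    """Mean |kappa_{i+1} - kappa_i| of discrete curvature along a path.

    Coincident consecutive points are dropped with a warning before the
    curvature is evaluated on consecutive point triples.
    """
    path = np.atleast_2d(np.asarray(path, dtype=float))
    keep = np.ones(len(path), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(path, axis=0), axis=1) > 0
    if not keep.all():
        warnings.warn("coincident consecutive points skipped")
        path = path[keep]
    if len(path) < 4:
        raise ValueError("need at least 4 distinct points")
    kappa = np.array(
        [menger_curvature(path[i - 1], path[i], path[i + 1]) for i in range(1, len(path) - 1)]
    )
    return float(np.mean(np.abs(np.diff(kappa))))


def _point_segment_distances(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


def tracking_error(path: np.ndarray, reference: np.ndarray) -> float:
    """Mean exact point-to-polyline distance from path to reference."""
    path = np.atleast_2d(np.asarray(path, dtype=float))
    reference = np.atleast_2d(np.asarray(reference, dtype=float))
    if path.size == 0:
        raise ValueError("empty path")
    if len(reference) < 2:
        raise ValueError("reference needs at least 2 vertices")
    dists = np.full(len(path), np.inf)
    for i in range(len(reference) - 1):
        d = _point_segment_distances(path, reference[i], reference[i + 1])
        dists = np.minimum(dists, d)
    return float(np.mean(dists))


def compare_methods(
    traces: dict[str, np.ndarray], targets: IntervalTargets
) -> pd.DataFrame:
    """Open-loop metric table: one row per post-processing method."""
    rows = []
    for method, seq in traces.items():
        seq = np.asarray(seq, dtype=float)
        if seq.size != len(targets):
            raise ValueError(f"trace for {method!r} misaligned with targets")
        rows.append(
            {
                "method": method,
                "R_hit": hit_rate(seq, targets),
                "S_wrist": wrist_smoothness(seq),
                "n": seq.size,
            }
        )
    return pd.DataFrame(rows, columns=["method", "R_hit", "S_wrist", "n"])


def plot_comparison(table: pd.DataFrame, out_path) -> None:
    """Bar chart of hit rate and smoothness per method."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    axes[0].bar(table["method"], table["R_hit"], color="tab:blue")
    axes[0].set_ylabel("hit rate")
    axes[0].set_ylim(0, 1)
    axes[1].bar(table["method"], table["S_wrist"], color="tab:orange")
    axes[1].set_ylabel("wrist smoothness (deg/step)")
    for ax in axes:
        ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
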