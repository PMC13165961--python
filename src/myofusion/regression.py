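"""Plug-in instantaneous wrist-angle regressors.

The default backbone is a random forest (100 trees, depth 15) trained on
the hybrid WL/WAMP/F-ENT feature set, but any object exposing
``predict(X) -> angles`` can be substituted: the downstream fusion stage
only consumes the instantaneous prediction stream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .features import Standardizer

__all__ = [
    "RegressorConfig",
    "RegressorHandle",
    "split_train_test",
    "train_regressor",
    "predict_stream",
    "save_handle",
    "load_handle",
]


@dataclass(frozen=True)
class RegressorConfig:
    kind: str = "random_forest"
    n_trees: int = 100
    max_depth: int = 15
    train_fraction: float = 0.8
    seed: int = 0
    shuffle: bool = False  # default chronological split (overlapping windows leak)

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


def split_train_test(
    frames: pd.DataFrame, cfg: RegressorConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """80/20 split; chronologically contiguous by default.

    Train size is ``floor(n * train_fraction)``.  A seeded shuffled split
    is available via ``cfg.shuffle`` but leaks samples across overlapping
    windows, so it is off by default.
    """
    n = len(frames)
    if n < 10:
        raise ValueError(f"need at least 10 frames to split, got {n}")
    n_train = int(np.floor(n * cfg.train_fraction))
    if cfg.shuffle:
        order = np.random.default_rng(cfg.seed).permutation(n)
        idx_train, idx_test = np.sort(order[:n_train]), np.sort(order[n_train:])
        return frames.iloc[idx_train], frames.iloc[idx_test]
    return frames.iloc[:n_train], frames.iloc[n_train:]


@dataclass
class RegressorHandle:
    """A fitted predictor plus the metadata needed to reuse it.

    ``model.predict`` must be deterministic once fitted.  Features fed to
    ``predict`` are expected to be standardized with ``standardizer``.
    """

    model: object
    feature_columns: list[str]
    standardizer: Standardizer
    config: RegressorConfig

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.feature_columns):
            raise ValueError(
                f"feature dimension {X.shape[1]} != trained dimension "
                f"{len(self.feature_columns)}"
            )
        return np.asarray(self.model.predict(X), dtype=float)


def train_regressor(
    train_frames: pd.DataFrame,
    cfg: RegressorConfig,
    feature_columns: list[str],
    standardizer: Standardizer | None = None,
) -> RegressorHandle:
    """Fit the default random forest on (standardized) features.

    If no standardizer is given, one is fitted on the training frames.
    """
    X = train_frames[feature_columns].to_numpy(dtype=float)
    y = train_frames["label"].to_numpy(dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite features or labels")
    if standardizer is None:
        standardizer = Standardizer().fit(X)
    Xs = standardizer.transform(X)
    if cfg.kind != "random_forest":
        raise ValueError(f"unknown regressor kind {cfg.kind!r}")
    model = RandomForestRegressor(
        n_estimators=cfg.n_trees,
        max_depth=cfg.max_depth,
        random_state=cfg.seed,
        n_jobs=1,
    )
    model.fit(Xs, y)
    return RegressorHandle(
        model=model,
        feature_columns=list(feature_columns),
        standardizer=standardizer,
        config=cfg,
    )


def predict_stream(handle: RegressorHandle, frames: pd.DataFrame) -> np.ndarray:
    """One instantaneous prediction per frame, order preserved."""
    if len(frames) == 0:
        return np.empty(0)
    X = handle.standardizer.transform(frames[handle.feature_columns].to_numpy(dtype=float))
    return handle.predict(X)


def save_handle(handle: RegressorHandle, path: str | Path) -> None:
    path = Path(path)
    joblib.dump(handle.model, path)
    meta = {
        "feature_columns": handle.feature_columns,
        "standardizer": handle.standardizer.to_dict(),
        "config": asdict(handle.config),
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2))


def load_handle(path: str | Path) -> RegressorHandle:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
    return RegressorHandle(
        model=joblib.load(path),
        feature_columns=meta["feature_columns"],
        standardizer=Standardizer.from_dict(meta["standardizer"]),
        config=RegressorConfig(**meta["config"]),
    )
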