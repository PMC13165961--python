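"""End-to-end experiment orchestration.

Chains synthetic session generation, filtering, feature extraction,
regressor training, every configured post-processor, and open-loop
metric evaluation into a deterministic artifact tree.  All randomness is
derived from one global seed through stage-name-hashed substreams, so
stages can be rerun independently yet reproducibly.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .baselines import BASELINE_METHODS, BaselineConfig, apply_baseline
from .config import ExperimentConfig, config_to_dict, derive_seed, save_config
from .evaluation import IntervalTargets, compare_methods, plot_comparison
from .features import (
    ALL_FEATURES,
    HYBRID_FEATURES,
    FeatureCatalog,
    Standardizer,
    Thresholds,
    compute_feature_table,
    estimate_thresholds,
    feature_columns,
    filter_recording,
)
from .fusion import KernelConfig, records_to_frame, run_fusion_stream
from .regression import RegressorHandle, predict_stream, split_train_test, train_regressor
from .synthetic import (
    EmgRecording,
    apply_motion_lag,
    generate_emg,
    generate_reference_trajectory,
    write_recording,
)

__all__ = ["Session", "build_session", "run_methods", "evaluate_open_loop",
           "rf_test_errors", "run_experiment", "benchmark_seeds"]


def _feature_names(cfg: ExperimentConfig) -> tuple[str, ...]:
    return HYBRID_FEATURES if cfg.features.set == "hybrid" else ALL_FEATURES


@dataclass
class Session:
    """Everything produced by one synthetic train+validation session."""

    cfg: ExperimentConfig
    seed: int
    rec_train: EmgRecording
    rec_valid: EmgRecording
    thresholds: Thresholds
    table_train: pd.DataFrame
    train_frames: pd.DataFrame
    test_frames: pd.DataFrame
    table_valid: pd.DataFrame
    handle: RegressorHandle
    theta_hat: np.ndarray  # raw predictions on the validation session
    X_valid: np.ndarray  # standardized validation features
    targets: IntervalTargets
    kernel: KernelConfig  # possibly length-scale-calibrated


def _make_recording(cfg: ExperimentConfig, spec, stage: str, seed: int) -> EmgRecording:
    traj = generate_reference_trajectory(replace(spec, seed=derive_seed(seed, f"{stage}_protocol")))
    performed = apply_motion_lag(traj, cfg.lag_tau)
    channels = cfg.channels
    if stage == "train" and cfg.clean_training:
        # supervised collection is controlled; transient electrode artifacts
        # are a deployment-time disturbance the regressor has not seen
        channels = replace(channels, artifact_rate=0.0)
    rec = generate_emg(
        performed, channels, seed=derive_seed(seed, f"{stage}_emg"),
        phi_LM=spec.phi_LM, phi_RM=spec.phi_RM,
    )
    return filter_recording(rec, cfg.filtering)


def build_session(cfg: ExperimentConfig, seed: int | None = None) -> Session:
    """Generate, featurize and fit one full synthetic session."""
    seed = cfg.seed if seed is None else seed
    rec_train = _make_recording(cfg, cfg.protocol_train, "train", seed)
    thresholds = estimate_thresholds(rec_train)
    catalog = FeatureCatalog(names=_feature_names(cfg), thresholds=thresholds)

    table_train = compute_feature_table(rec_train, cfg.windowing, catalog)
    reg_cfg = replace(cfg.regressor, seed=derive_seed(seed, "regressor"))
    train_frames, test_frames = split_train_test(table_train, reg_cfg)
    feat_cols = feature_columns(cfg.channels.n_channels, catalog.names)
    standardizer = Standardizer().fit(train_frames[feat_cols])
    handle = train_regressor(train_frames, reg_cfg, feat_cols, standardizer)

    kernel = cfg.kernel
    if cfg.calibrate_kernel:
        Xtr = standardizer.transform(train_frames[feat_cols])
        step = np.median(np.linalg.norm(np.diff(Xtr, axis=0), axis=1))
        if step > 0:
            kernel = replace(kernel, length_scale=cfg.calib_factor * float(step))

    rec_valid = _make_recording(cfg, cfg.protocol_valid, "valid", seed)
    table_valid = compute_feature_table(rec_valid, cfg.windowing, catalog)
    X_valid = standardizer.transform(table_valid[feat_cols])
    theta_hat = handle.predict(X_valid)
    targets = IntervalTargets.from_indices(
        table_valid["interval_idx"].to_numpy(),
        phi_LM=cfg.protocol_valid.phi_LM, phi_RM=cfg.protocol_valid.phi_RM,
    )
    return Session(
        cfg=cfg, seed=seed, rec_train=rec_train, rec_valid=rec_valid,
        thresholds=thresholds, table_train=table_train, train_frames=train_frames,
        test_frames=test_frames, table_valid=table_valid, handle=handle,
        theta_hat=theta_hat, X_valid=X_valid, targets=targets, kernel=kernel,
    )


def _baseline_cfg(cfg: ExperimentConfig, method: str) -> BaselineConfig:
    b = cfg.baselines
    return BaselineConfig(
        method=method, m=b.m, lam=b.lam, sg_order=b.sg_order,
        wd_level=b.wd_level, wd_block=b.wd_block,
    )


def run_methods(
    session: Session,
) -> tuple[dict[str, np.ndarray], pd.DataFrame | None]:
    """Apply every configured post-processor to the raw prediction stream.

    Returns the per-method smoothed sequences and, when LGPR is among the
    methods, its full fusion trace.
    """
    cfg = session.cfg
    traces: dict[str, np.ndarray] = {}
    fusion_trace = None
    for method in cfg.methods:
        if method == "none":
            traces[method] = session.theta_hat.copy()
        elif method in BASELINE_METHODS:
            traces[method] = apply_baseline(session.theta_hat, _baseline_cfg(cfg, method))
        elif method == "LGPR":
            records = run_fusion_stream(
                session.X_valid, session.theta_hat, session.kernel, cfg.fusion
            )
            fusion_trace = records_to_frame(records)
            traces[method] = fusion_trace["theta_tilde"].to_numpy()
    return traces, fusion_trace


def evaluate_open_loop(session: Session, traces: dict[str, np.ndarray]) -> pd.DataFrame:
    return compare_methods(traces, session.targets)


def rf_test_errors(session: Session) -> np.ndarray:
    """|prediction - label| on the held-out chronological test split."""
    preds = predict_stream(session.handle, session.test_frames)
    return np.abs(preds - session.test_frames["label"].to_numpy())


def run_experiment(cfg: ExperimentConfig, out_dir: str | Path | None = None) -> Path:
    """Run the full pipeline and write a deterministic artifact tree."""
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    for sub in ("data", "features", "traces", "report"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    session = build_session(cfg)
    write_recording(session.rec_train, out / "data" / "train.csv",
                    meta={"protocol": "training_sweep", "seed": session.seed})
    write_recording(session.rec_valid, out / "data" / "valid.csv",
                    meta={"protocol": "validation_steps", "seed": session.seed})
    session.table_train.to_csv(out / "features" / "train.csv", index=False)
    session.table_valid.to_csv(out / "features" / "valid.csv", index=False)

    traces, fusion_trace = run_methods(session)
    for method, seq in traces.items():
        df = pd.DataFrame(
            {
                "t": session.table_valid["t"],
                "theta_hat": session.theta_hat,
                "theta_tilde": seq,
                "label": session.table_valid["label"],
                "interval_idx": session.table_valid["interval_idx"],
            }
        )
        df.to_csv(out / "traces" / f"{method}.csv", index=False)
    if fusion_trace is not None:
        fusion_trace.to_csv(out / "traces" / "LGPR_full.csv", index=False)

    table = evaluate_open_loop(session, traces)
    table.to_csv(out / "report" / "metrics.csv", index=False)
    plot_comparison(table, out / "report" / "comparison.png")

    save_config(cfg, out / "effective_config.yaml")
    manifest = {
        "myofusion_version": __version__,
        "python": platform.python_version(),
        "seed": session.seed,
        "methods": list(cfg.methods),
        "n_train_frames": len(session.train_frames),
        "n_test_frames": len(session.test_frames),
        "n_valid_frames": len(session.table_valid),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def benchmark_seeds(cfg: ExperimentConfig, seeds: list[int]) -> pd.DataFrame:
    """Open-loop metrics per seed for every configured method."""
    rows = []
    for seed in seeds:
        session = build_session(cfg, seed=seed)
        traces, _ = run_methods(session)
        table = evaluate_open_loop(session, traces)
        table.insert(0, "seed", seed)
        rows.append(table)
    return pd.concat(rows, ignore_index=True)
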