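"""Synthetic sEMG session generation.

Builds reference wrist-angle trajectories for the two cueing protocols
(a constant-rate training sweep and a stepped validation sequence over
seven angle intervals) and synthesizes angle-driven multi-channel sEMG
as amplitude-modulated band-limited Gaussian noise with optional 50 Hz
mains interference.  Flexion is positive, extension negative.

No physiological motor-unit modelling is attempted: the carrier is
band-limited noise whose envelope follows a normalized muscle-activation
level derived from the wrist angle, which is sufficient to exercise the
full decoding pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "SpecError",
    "ProtocolSpec",
    "AngleTrajectory",
    "EmgChannelModel",
    "EmgRecording",
    "interval_edges",
    "interval_centers",
    "interval_index_of",
    "generate_reference_trajectory",
    "apply_motion_lag",
    "generate_emg",
    "write_recording",
    "read_recording",
]

N_INTERVALS = 7

MODES = ("training_sweep", "validation_steps")


class SpecError(ValueError):
    """Raised for an invalid protocol or channel-model specification."""


@dataclass(frozen=True)
class ProtocolSpec:
    """Parameters of one cueing protocol.

    ``training_sweep`` is a triangle wave between ``-phi_LM`` and
    ``+phi_RM`` at constant ``sweep_rate``; ``validation_steps`` is a
    piecewise-constant sequence of interval-center targets, each held
    ``hold_duration`` seconds, with ``n_transitions`` target changes
    within ``total_duration`` seconds.
    """

    mode: str
    phi_LM: float = 60.0
    phi_RM: float = 60.0
    sweep_rate: float = 10.0
    hold_duration: float = 5.0
    n_transitions: int = 12
    total_duration: float = 60.0
    fs: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise SpecError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.phi_LM <= 0 or self.phi_RM <= 0:
            raise SpecError("phi_LM and phi_RM must be positive")
        if self.sweep_rate <= 0:
            raise SpecError("sweep_rate must be positive")
        if self.hold_duration <= 0:
            raise SpecError("hold_duration must be positive")
        if self.total_duration <= 0:
            raise SpecError("total_duration must be positive")
        if self.fs <= 0:
            raise SpecError("fs must be positive")
        if self.n_transitions < 1:
            raise SpecError("n_transitions must be >= 1")


@dataclass
class AngleTrajectory:
    """Uniformly sampled wrist-angle trajectory.

    ``interval_index`` holds the 0..6 target interval per sample for
    validation-mode trajectories and is ``None`` for training sweeps.
    """

    times: np.ndarray
    angles: np.ndarray
    fs: float
    interval_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.times.shape != self.angles.shape:
            raise ValueError("times and angles must have equal shape")
        if self.interval_index is not None:
            self.interval_index = np.asarray(self.interval_index, dtype=int)
            if self.interval_index.shape != self.times.shape:
                raise ValueError("interval_index shape mismatch")

    def __len__(self) -> int:
        return self.times.size

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


def interval_edges(phi_LM: float, phi_RM: float) -> np.ndarray:
    """Edges of the seven target intervals.

    Boundaries sit at ``-phi_LM, -(5/7)phi_LM, -(3/7)phi_LM, -(1/7)phi_LM,
    (1/7)phi_RM, (3/7)phi_RM, (5/7)phi_RM, phi_RM``; the central interval
    spans the deadzone.
    """
    left = -phi_LM * np.array([7, 5, 3, 1]) / 7.0
    right = phi_RM * np.array([1, 3, 5, 7]) / 7.0
    return np.concatenate([left, right])


def interval_centers(phi_LM: float, phi_RM: float) -> np.ndarray:
    e = interval_edges(phi_LM, phi_RM)
    return 0.5 * (e[:-1] + e[1:])


def interval_index_of(angles: np.ndarray, phi_LM: float, phi_RM: float) -> np.ndarray:
    """Map angles to their interval index (0..6).

    Intervals are half-open ``[lo, hi)`` except the topmost, which is
    closed at ``+phi_RM``.  Out-of-range angles clip to the end intervals.
    """
    e = interval_edges(phi_LM, phi_RM)
    idx = np.searchsorted(e, np.asarray(angles, dtype=float), side="right") - 1
    return np.clip(idx, 0, N_INTERVALS - 1)


def _time_grid(spec: ProtocolSpec) -> np.ndarray:
    # Endpoint-inclusive grid so a transition scheduled exactly at
    # total_duration is observed (12 transitions of 5 s holds fit in 60 s).
    n = int(round(spec.total_duration * spec.fs)) + 1
    return np.arange(n) / spec.fs


def _training_sweep(spec: ProtocolSpec) -> AngleTrajectory:
    times = _time_grid(spec)
    t_pts = [0.0]
    a_pts = [0.0]
    direction = 1.0
    while t_pts[-1] <= spec.total_duration:
        target = spec.phi_RM if direction > 0 else -spec.phi_LM
        leg = abs(target - a_pts[-1]) / spec.sweep_rate
        t_pts.append(t_pts[-1] + leg)
        a_pts.append(target)
        direction = -direction
    angles = np.interp(times, t_pts, a_pts)
    return AngleTrajectory(times=times, angles=angles, fs=spec.fs)


def _validation_steps(spec: ProtocolSpec) -> AngleTrajectory:
    times = _time_grid(spec)
    rng = np.random.default_rng(spec.seed)
    n_levels = spec.n_transitions + 1
    levels = [int(rng.integers(N_INTERVALS))]
    while len(levels) < n_levels:
        # uniform among the other six intervals: no immediate repetition
        step = int(rng.integers(1, N_INTERVALS))
        levels.append((levels[-1] + step) % N_INTERVALS)
    levels = np.asarray(levels)
    seg = np.minimum((times / spec.hold_duration).astype(int), n_levels - 1)
    idx = levels[seg]
    centers = interval_centers(spec.phi_LM, spec.phi_RM)
    return AngleTrajectory(
        times=times, angles=centers[idx], fs=spec.fs, interval_index=idx
    )


def generate_reference_trajectory(spec: ProtocolSpec) -> AngleTrajectory:
    """Generate the cued target trajectory for a protocol."""
    if spec.mode == "training_sweep":
        return _training_sweep(spec)
    return _validation_steps(spec)


def apply_motion_lag(traj: AngleTrajectory, tau: float = 0.2) -> AngleTrajectory:
    """First-order lag modelling the performed (vs. cued) wrist angle.

    Target transitions are instantaneous; the wrist is not.  The lag uses
    the exact zero-order-hold discretization of ``tau * dy/dt = x - y``
    with ``y(0) = x(0)``.  The target interval index is carried through
    unchanged (it labels the cue, not the motion).
    """
    if tau <= 0:
        return replace(traj, angles=traj.angles.copy())
    dt = 1.0 / traj.fs
    alpha = 1.0 - np.exp(-dt / tau)
    b, a = [alpha], [1.0, -(1.0 - alpha)]
    zi = signal.lfiltic(b, a, y=[traj.angles[0]], x=[traj.angles[0]])
    lagged, _ = signal.lfilter(b, a, traj.angles, zi=zi)
    return replace(traj, angles=lagged)


@dataclass(frozen=True)
class EmgChannelModel:
    """Ring of electrodes around the forearm.

    Channels in ``flexor_channels`` respond to flexion, channels in
    ``extensor_channels`` to extension; intermediate channels blend the
    two by ring distance to the nearest member of each set.
    """

    n_channels: int = 8
    flexor_channels: tuple[int, ...] = (0, 1, 2)
    extensor_channels: tuple[int, ...] = (4, 5, 6)
    baseline_amplitude: float = 0.05
    gain: float = 1.0
    mains_amplitude: float = 0.1
    band: tuple[float, float] = (20.0, 450.0)
    # movement-onset co-contraction burst: all channels receive an extra
    # activation min(|d2theta/dt2| / burst_accel_ref, 1) * burst_gain, so
    # abrupt target transitions (not the constant-rate sweep) produce
    # out-of-distribution feature patterns — the transition-spike phenomenon
    burst_gain: float = 1.0
    burst_accel_ref: float = 500.0  # deg/s^2 at which the burst saturates
    # transient electrode/motion artifacts on single channels: a mixture of
    # a broadband amplitude burst (mimics activation, corrupting amplitude
    # features) and a low-frequency 20-30 Hz component (spectrally unlike
    # muscle activity); the dominant source of spiky decoding errors
    artifact_rate: float = 0.15  # events per second per channel
    artifact_duration: float = 0.12  # s
    artifact_gain: float = 3.0  # artifact amplitude
    artifact_band: tuple[float, float] = (20.0, 30.0)
    artifact_lowfreq_frac: float = 0.5  # narrowband share of the artifact

    def __post_init__(self) -> None:
        flex, ext = set(self.flexor_channels), set(self.extensor_channels)
        if not flex or not ext:
            raise SpecError("flexor and extensor channel sets must be non-empty")
        if flex & ext:
            raise SpecError("flexor and extensor channel sets must be disjoint")
        chans = flex | ext
        if min(chans) < 0 or max(chans) >= self.n_channels:
            raise SpecError("channel index out of range")
        if min(self.baseline_amplitude, self.gain, self.mains_amplitude,
               self.burst_gain) < 0:
            raise SpecError("amplitudes must be >= 0")
        if self.burst_accel_ref <= 0:
            raise SpecError("burst_accel_ref must be positive")
        if self.artifact_rate < 0 or self.artifact_gain < 0:
            raise SpecError("artifact parameters must be >= 0")
        if self.artifact_duration <= 0:
            raise SpecError("artifact_duration must be positive")
        lo, hi = self.band
        if not 0 < lo < hi:
            raise SpecError("band must satisfy 0 < low < high")


def _ring_distance(a: int, b: int, n: int) -> int:
    d = abs(a - b) % n
    return min(d, n - d)


def _flexion_weights(model: EmgChannelModel) -> np.ndarray:
    """Per-channel flexion weight in [0, 1], interpolated around the ring."""
    w = np.empty(model.n_channels)
    for c in range(model.n_channels):
        df = min(_ring_distance(c, f, model.n_channels) for f in model.flexor_channels)
        de = min(_ring_distance(c, e, model.n_channels) for e in model.extensor_channels)
        w[c] = de / (df + de) if (df + de) > 0 else 0.5
    return w


@dataclass
class EmgRecording:
    """Multi-channel sEMG with an aligned reference trajectory."""

    samples: np.ndarray  # (n_channels, n_samples)
    fs: float
    reference: AngleTrajectory

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.shape[1] != len(self.reference):
            raise ValueError("samples and reference trajectory length mismatch")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


def activation_profile(
    angles: np.ndarray, model: EmgChannelModel, phi_LM: float, phi_RM: float
) -> np.ndarray:
    """Normalized activation per channel, shape (n_channels, n_samples)."""
    flex = np.maximum(0.0, np.asarray(angles, dtype=float) / phi_RM)
    ext = np.maximum(0.0, -np.asarray(angles, dtype=float) / phi_LM)
    w = _flexion_weights(model)
    return w[:, None] * flex[None, :] + (1.0 - w)[:, None] * ext[None, :]


def generate_emg(
    trajectory: AngleTrajectory,
    model: EmgChannelModel,
    seed: int = 0,
    phi_LM: float | None = None,
    phi_RM: float | None = None,
) -> EmgRecording:
    """Synthesize sEMG driven by a wrist-angle trajectory.

    Each channel is unit-variance Gaussian noise band-limited to
    ``model.band``, amplitude-modulated by ``baseline + gain * activation``,
    plus a 50 Hz mains sinusoid with a random per-channel phase.
    Bit-identical for a fixed seed.
    """
    fs = trajectory.fs
    lo, hi = model.band
    if fs <= 2 * hi:
        raise SpecError(f"fs={fs} must exceed twice the upper band edge {hi}")
    if phi_LM is None:
        phi_LM = float(np.abs(np.min(trajectory.angles)) or 60.0)
    if phi_RM is None:
        phi_RM = float(np.max(trajectory.angles) or 60.0)
    rng = np.random.default_rng(seed)
    n = len(trajectory)
    act = activation_profile(trajectory.angles, model, phi_LM, phi_RM)
    rate = np.gradient(trajectory.angles) * fs
    accel = np.abs(np.gradient(rate) * fs)
    burst = model.burst_gain * np.minimum(accel / model.burst_accel_ref, 1.0)
    sos = signal.butter(4, model.band, btype="bandpass", fs=fs, output="sos")
    phases = rng.uniform(0.0, 2 * np.pi, size=model.n_channels)
    samples = np.empty((model.n_channels, n))
    for c in range(model.n_channels):
        white = rng.standard_normal(n)
        carrier = signal.sosfiltfilt(sos, white)
        carrier /= carrier.std()
        envelope = model.baseline_amplitude + model.gain * act[c] + burst
        mains = model.mains_amplitude * np.sin(
            2 * np.pi * 50.0 * trajectory.times + phases[c]
        )
        samples[c] = envelope * carrier + mains
        n_events = rng.poisson(model.artifact_rate * n / fs)
        if n_events > 0:
            sos_art = signal.butter(2, model.artifact_band, btype="bandpass",
                                    fs=fs, output="sos")
            narrow = signal.sosfiltfilt(sos_art, rng.standard_normal(n))
            narrow /= narrow.std()
            dur = int(round(model.artifact_duration * fs))
            w = model.artifact_lowfreq_frac
            for start in rng.integers(0, max(n - dur, 1), size=n_events):
                sl = slice(start, start + dur)
                samples[c, sl] += model.artifact_gain * (
                    (1.0 - w) * carrier[sl] + w * narrow[sl]
                )
    return EmgRecording(samples=samples, fs=fs, reference=trajectory)


def write_recording(rec: EmgRecording, csv_path: str | Path, meta: dict | None = None) -> None:
    """Write a recording as CSV plus a JSON sidecar with fs and metadata."""
    csv_path = Path(csv_path)
    cols = {"time": rec.reference.times}
    for c in range(rec.n_channels):
        cols[f"ch{c + 1}"] = rec.samples[c]
    cols["ref_angle"] = rec.reference.angles
    idx = rec.reference.interval_index
    cols["interval_idx"] = idx if idx is not None else np.full(rec.n_samples, -1)
    pd.DataFrame(cols).to_csv(csv_path, index=False)
    sidecar = {"fs": rec.fs, "n_channels": rec.n_channels}
    if meta:
        sidecar.update(meta)
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_recording(csv_path: str | Path) -> EmgRecording:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    sidecar = csv_path.with_suffix(".json")
    fs = json.loads(sidecar.read_text())["fs"] if sidecar.exists() else 1.0 / np.diff(df["time"][:2])[0]
    chan_cols = [c for c in df.columns if c.startswith("ch")]
    idx = df["interval_idx"].to_numpy()
    traj = AngleTrajectory(
        times=df["time"].to_numpy(),
        angles=df["ref_angle"].to_numpy(),
        fs=float(fs),
        interval_index=None if (idx < 0).all() else idx,
    )
    return EmgRecording(samples=df[chan_cols].to_numpy().T, fs=float(fs), reference=traj)
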