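"""Unicycle robot simulator and wrist-angle -> velocity mapping.

The wrist flexion-extension angle steers a planar unicycle robot: a
neutral-band deadzone maps to straight motion, flexion turns right
(positive angular velocity), extension turns left, and linear velocity
trades off linearly against |omega|.  A scripted pure-pursuit operator
closes the loop at 10 Hz for in-silico trials; the operator and decoder
models are simulation plumbing, not part of the decoding method itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import features as _feat
from .baselines import BaselineConfig, StreamFilter
from .fusion import FusionConfig, FusionEngine, KernelConfig
from .synthetic import AngleTrajectory, EmgChannelModel, generate_emg

__all__ = [
    "MappingConfig",
    "RobotState",
    "ControlInput",
    "map_angle_to_velocity",
    "inverse_mapping",
    "kinematic_step",
    "wrap_angle",
    "PurePursuitOperator",
    "PassthroughDecoder",
    "NoisyDecoder",
    "EmgDecoder",
    "make_postprocessor",
    "TrialRecord",
    "simulate_closed_loop",
]


@dataclass(frozen=True)
class MappingConfig:
    """Wrist-angle to robot-velocity mapping parameters.

    ``theta_LD``/``theta_RD`` (deadzone edges) default to one seventh of
    the corresponding range limit.
    """

    theta_LM: float = 60.0
    theta_RM: float = 60.0
    theta_LD: float | None = None
    theta_RD: float | None = None
    omega_max: float = 1.0
    v_max: float = 0.3
    dt: float = 0.1

    def __post_init__(self) -> None:
        if self.theta_LD is None:
            object.__setattr__(self, "theta_LD", self.theta_LM / 7.0)
        if self.theta_RD is None:
            object.__setattr__(self, "theta_RD", self.theta_RM / 7.0)
        if not 0 < self.theta_LD < self.theta_LM:
            raise ValueError("need 0 < theta_LD < theta_LM")
        if not 0 < self.theta_RD < self.theta_RM:
            raise ValueError("need 0 < theta_RD < theta_RM")
        if min(self.omega_max, self.v_max, self.dt) <= 0:
            raise ValueError("omega_max, v_max and dt must be positive")


@dataclass
class RobotState:
    x: float = 0.0
    y: float = 0.0
    heading: float = 0.0  # rad, wrapped to (-pi, pi]
    t: float = 0.0

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass(frozen=True)
class ControlInput:
    v: float
    omega: float


def wrap_angle(a: float) -> float:
    """Wrap to (-pi, pi]."""
    a = (a + np.pi) % (2 * np.pi) - np.pi
    return np.pi if a == -np.pi else float(a)


def map_angle_to_velocity(theta: float, cfg: MappingConfig = MappingConfig()) -> ControlInput:
    """Piecewise-linear mapping with a closed deadzone, then v from omega.

    The deadzone boundary belongs to the deadzone so omega is continuous;
    angles beyond the range limits clamp to +/- omega_max.
    """
    theta = float(theta)
    if -cfg.theta_LD <= theta <= cfg.theta_RD:
        omega = 0.0
    elif theta > cfg.theta_RD:  # flexion -> right turn, positive omega
        omega = min((theta - cfg.theta_RD) / (cfg.theta_RM - cfg.theta_RD), 1.0) * cfg.omega_max
    else:  # extension -> left turn, negative omega
        omega = max((theta + cfg.theta_LD) / (cfg.theta_LM - cfg.theta_LD), -1.0) * cfg.omega_max
    v = cfg.v_max * (1.0 - abs(omega) / cfg.omega_max)
    return ControlInput(v=v, omega=omega)


def inverse_mapping(omega: float, cfg: MappingConfig = MappingConfig()) -> float:
    """Wrist angle whose mapping yields the requested angular velocity."""
    omega = float(np.clip(omega, -cfg.omega_max, cfg.omega_max))
    if omega == 0.0:
        return 0.0
    if omega > 0:
        return cfg.theta_RD + omega / cfg.omega_max * (cfg.theta_RM - cfg.theta_RD)
    return -cfg.theta_LD + omega / cfg.omega_max * (cfg.theta_LM - cfg.theta_LD)


def kinematic_step(s: RobotState, u: ControlInput, dt: float) -> RobotState:
    """Forward-Euler unicycle update."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    return RobotState(
        x=s.x + u.v * np.cos(s.heading) * dt,
        y=s.y + u.v * np.sin(s.heading) * dt,
        heading=wrap_angle(s.heading + u.omega * dt),
        t=s.t + dt,
    )


class PurePursuitOperator:
    """Scripted operator: steer toward a lookahead point on the reference.

    Maps (robot state, reference polyline) to an intended wrist angle by
    inverting the velocity mapping, with optional seeded intent noise.
    """

    def __init__(
        self,
        mapping: MappingConfig,
        lookahead: float = 0.3,
        gain: float = 2.0,
        noise_std: float = 0.0,
        seed: int = 0,
    ):
        self.mapping = mapping
        self.lookahead = lookahead
        self.gain = gain
        self.noise_std = noise_std
        self._rng = np.random.default_rng(seed)

    def _lookahead_point(self, pos: np.ndarray, ref: np.ndarray) -> np.ndarray:
        # closest vertex, then march ahead along the polyline
        d = np.linalg.norm(ref - pos[None, :], axis=1)
        i = int(np.argmin(d))
        acc = 0.0
        while i < len(ref) - 1 and acc < self.lookahead:
            acc += float(np.linalg.norm(ref[i + 1] - ref[i]))
            i += 1
        return ref[i]

    def __call__(self, state: RobotState, reference: np.ndarray) -> float:
        target = self._lookahead_point(state.position, np.asarray(reference, dtype=float))
        desired = np.arctan2(target[1] - state.y, target[0] - state.x)
        err = wrap_angle(desired - state.heading)
        # kinematics integrate heading CCW-positive, so steer with the error
        omega = float(np.clip(self.gain * err, -self.mapping.omega_max, self.mapping.omega_max))
        theta = inverse_mapping(omega, self.mapping)
        if self.noise_std > 0:
            theta += self._rng.normal(0.0, self.noise_std)
        return theta


class PassthroughDecoder:
    """Ideal decoder: predicted angle equals the intended angle."""

    def __call__(self, theta_intent: float) -> tuple[float, np.ndarray]:
        return float(theta_intent), np.array([theta_intent / 30.0])


class NoisyDecoder:
    """Additive-noise pseudo-decoder with occasional spike errors.

    The pseudo-feature vector is the noisy intent on a roughly unit
    scale, which gives the fusion stage a meaningful feature-space
    distance without simulating EMG at every control step.
    """

    def __init__(self, noise_std: float = 5.0, spike_prob: float = 0.05,
                 spike_scale: float = 30.0, seed: int = 0):
        self.noise_std = noise_std
        self.spike_prob = spike_prob
        self.spike_scale = spike_scale
        self._rng = np.random.default_rng(seed)

    def __call__(self, theta_intent: float) -> tuple[float, np.ndarray]:
        theta = theta_intent + self._rng.normal(0.0, self.noise_std)
        if self._rng.random() < self.spike_prob:
            # magnitude varies trial to trial, as real decoding spikes do
            theta += self._rng.choice([-1.0, 1.0]) * self.spike_scale \
                * self._rng.uniform(0.5, 1.5)
        return float(theta), np.array([theta / 30.0])


class EmgDecoder:
    """Full-chain decoder: intent -> one EMG window -> features -> regressor."""

    def __init__(
        self,
        handle,
        channel_model: EmgChannelModel,
        thresholds: _feat.Thresholds,
        filter_cfg: _feat.FilterConfig = _feat.FilterConfig(),
        window_ms: float = 250.0,
        fs: float = 1000.0,
        phi_LM: float = 60.0,
        phi_RM: float = 60.0,
        feature_names: tuple[str, ...] = _feat.HYBRID_FEATURES,
        seed: int = 0,
    ):
        self.handle = handle
        self.channel_model = channel_model
        self.thresholds = thresholds
        self.filter_cfg = filter_cfg
        self.window_samples = int(round(window_ms * fs / 1000.0))
        self.fs = fs
        self.phi_LM = phi_LM
        self.phi_RM = phi_RM
        self.feature_names = feature_names
        self._rng = np.random.default_rng(seed)

    def __call__(self, theta_intent: float) -> tuple[float, np.ndarray]:
        n = self.window_samples
        traj = AngleTrajectory(
            times=np.arange(n) / self.fs,
            angles=np.full(n, float(theta_intent)),
            fs=self.fs,
        )
        rec = generate_emg(
            traj, self.channel_model, seed=int(self._rng.integers(2**31)),
            phi_LM=self.phi_LM, phi_RM=self.phi_RM,
        )
        rec = _feat.filter_recording(rec, self.filter_cfg)
        catalog = _feat.FeatureCatalog(names=self.feature_names, thresholds=self.thresholds)
        win = _feat.segment_windows(rec, _feat.WindowingConfig(
            window_ms=n * 1000.0 / self.fs, step_ms=n * 1000.0 / self.fs))[0]
        feats = _feat.window_features(win, self.fs, catalog)
        x = np.array([feats[c] for c in self.handle.feature_columns])
        xs = self.handle.standardizer.transform(x[None, :])[0]
        return float(self.handle.predict(xs[None, :])[0]), xs


class _NoPostproc:
    def update(self, x: np.ndarray, theta_hat: float) -> float:
        return float(theta_hat)


class _BaselinePostproc:
    def __init__(self, cfg: BaselineConfig):
        self._filt = StreamFilter(cfg)

    def update(self, x: np.ndarray, theta_hat: float) -> float:
        return self._filt.update(theta_hat)


class _FusionPostproc:
    def __init__(self, kcfg: KernelConfig, fcfg: FusionConfig):
        self._engine = FusionEngine(kcfg, fcfg)

    def update(self, x: np.ndarray, theta_hat: float) -> float:
        return self._engine.step(x, theta_hat).theta_tilde


def make_postprocessor(
    method: str,
    baseline_cfg: BaselineConfig | None = None,
    kcfg: KernelConfig = KernelConfig(),
    fcfg: FusionConfig = FusionConfig(),
):
    """Streaming post-processor for a method name (none/MA/EMA/MF/SG/WD/LGPR)."""
    method = method.upper() if method.lower() != "none" else "none"
    if method == "none":
        return _NoPostproc()
    if method == "LGPR":
        return _FusionPostproc(kcfg, fcfg)
    cfg = baseline_cfg if baseline_cfg is not None else BaselineConfig(method=method)
    if cfg.method != method:
        cfg = BaselineConfig(
            method=method, m=cfg.m, lam=cfg.lam, sg_order=cfg.sg_order,
            wd_level=cfg.wd_level, wd_block=cfg.wd_block,
        )
    return _BaselinePostproc(cfg)


@dataclass
class TrialRecord:
    """One closed-loop trial: path, control trace, and task time."""

    states: np.ndarray  # (n, 2) positions
    headings: np.ndarray
    inputs: np.ndarray  # (n, 2) [v, omega]
    theta_intent: np.ndarray
    theta_hat: np.ndarray
    theta_tilde: np.ndarray
    t_task: float
    completed: bool


def simulate_closed_loop(
    reference: np.ndarray,
    operator,
    decoder,
    postproc,
    cfg: MappingConfig = MappingConfig(),
    start: RobotState | None = None,
    goal_radius: float = 0.1,
    timeout: float = 120.0,
) -> TrialRecord:
    """Closed loop at 1/cfg.dt Hz until the goal or timeout.

    Each step: operator intent -> decoder (raw prediction + features) ->
    post-processor -> velocity mapping -> kinematic step.
    """
    reference = np.atleast_2d(np.asarray(reference, dtype=float))
    if len(reference) < 2:
        raise ValueError("reference needs at least 2 vertices")
    state = start if start is not None else RobotState()
    goal = reference[-1]
    positions, headings, inputs = [], [], []
    intents, hats, tildes = [], [], []
    n_steps = int(np.ceil(timeout / cfg.dt))
    completed = False
    for _ in range(n_steps):
        positions.append([state.x, state.y])
        headings.append(state.heading)
        if np.linalg.norm(state.position - goal) < goal_radius:
            completed = True
            break
        intent = operator(state, reference)
        theta_hat, x = decoder(intent)
        theta_tilde = postproc.update(x, theta_hat)
        u = map_angle_to_velocity(theta_tilde, cfg)
        inputs.append([u.v, u.omega])
        intents.append(intent)
        hats.append(theta_hat)
        tildes.append(theta_tilde)
        state = kinematic_step(state, u, cfg.dt)
    return TrialRecord(
        states=np.asarray(positions),
        headings=np.asarray(headings),
        inputs=np.asarray(inputs) if inputs else np.empty((0, 2)),
        theta_intent=np.asarray(intents),
        theta_hat=np.asarray(hats),
        theta_tilde=np.asarray(tildes),
        t_task=state.t,
        completed=completed,
    )
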