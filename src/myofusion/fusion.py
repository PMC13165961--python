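"""Uncertainty-aware probabilistic fusion post-processing.

The streaming estimator keeps a FIFO window of the last N (feature,
fused-output) pairs, fits a local Gaussian process (Matérn kernel) on it,
and fuses the instantaneous regressor prediction with the GP prediction
via a closed-form adaptive gain::

    G_t = sigma_p^2 / (Sigma_t + sigma_p^2)
    fused = G_t * theta_hat + (1 - G_t) * theta_gp

where ``Sigma_t`` is the GP predictive variance at the current feature
vector.  The gain decreases strictly with uncertainty and the fused
output is always a convex combination of the two inputs, so a bounded
prediction stream yields a bounded fused stream.

By default the GP prior mean is the mean of the stored window outputs so
that far-from-data queries revert to recent behaviour rather than to 0
degrees; a literal zero-mean prior is available via
``FusionConfig(prior_mean="zero")``.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize

__all__ = [
    "KernelConfig",
    "FusionConfig",
    "SlidingDataset",
    "EstimateRecord",
    "NumericalError",
    "matern_kernel",
    "kernel_matrix",
    "lgpr_predict",
    "adaptive_gain",
    "fuse",
    "FusionEngine",
    "run_fusion_stream",
    "records_to_frame",
]

_SUPPORTED_NU = (0.5, 1.5, 2.5)
_MAX_JITTER = 1e-4


class NumericalError(RuntimeError):
    """SPD factorization failed even after jitter escalation."""


@dataclass(frozen=True)
class KernelConfig:
    """Matérn kernel hyperparameters.

    ``signal_var`` is in squared output units (deg^2) so that the GP
    predictive variance lives on the wrist-angle scale.
    """

    nu: float = 2.5
    length_scale: float = 1.0
    signal_var: float = 25.0
    noise_var: float = 1e-2
    jitter: float = 1e-8

    def __post_init__(self) -> None:
        if self.nu not in _SUPPORTED_NU:
            raise ValueError(f"nu must be one of {_SUPPORTED_NU}")
        if min(self.length_scale, self.signal_var, self.noise_var, self.jitter) <= 0:
            raise ValueError("all kernel parameters must be positive")


@dataclass(frozen=True)
class FusionConfig:
    window: int = 30  # sliding-dataset capacity N
    sigma_p2: float = 0.01  # temporal-regularization (prior) variance, deg^2
    sigma_min: float = 1e-10  # floor applied to Sigma_t before the gain
    refit_every: int = 0  # 0 = never refit kernel hyperparameters
    prior_mean: str = "window"  # "window" | "zero"

    def __post_init__(self) -> None:
        if self.window < 2:
            raise ValueError("window capacity N must be >= 2")
        if self.sigma_p2 <= 0:
            raise ValueError("sigma_p2 must be positive")
        if self.sigma_min <= 0:
            raise ValueError("sigma_min must be positive")
        if self.prior_mean not in ("window", "zero"):
            raise ValueError("prior_mean must be 'window' or 'zero'")


class SlidingDataset:
    """FIFO buffer of (feature vector, fused output) pairs, capacity N."""

    def __init__(self, capacity: int):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = capacity
        self._pairs: deque[tuple[np.ndarray, float]] = deque(maxlen=capacity)

    def append(self, x: np.ndarray, y: float) -> None:
        self._pairs.append((np.asarray(x, dtype=float).ravel(), float(y)))

    def __len__(self) -> int:
        return len(self._pairs)

    @property
    def full(self) -> bool:
        return len(self._pairs) == self.capacity

    @property
    def X(self) -> np.ndarray:
        return np.stack([p[0] for p in self._pairs])

    @property
    def y(self) -> np.ndarray:
        return np.array([p[1] for p in self._pairs])


def _matern_of_distance(r: np.ndarray, cfg: KernelConfig) -> np.ndarray:
    s = np.asarray(r, dtype=float) / cfg.length_scale
    if cfg.nu == 0.5:
        k = np.exp(-s)
    elif cfg.nu == 1.5:
        a = np.sqrt(3.0) * s
        k = (1.0 + a) * np.exp(-a)
    else:  # nu == 2.5
        a = np.sqrt(5.0) * s
        k = (1.0 + a + a * a / 3.0) * np.exp(-a)
    return cfg.signal_var * k


def matern_kernel(x1: np.ndarray, x2: np.ndarray, cfg: KernelConfig = KernelConfig()) -> float:
    """Stationary Matérn-nu covariance between two feature vectors."""
    x1 = np.asarray(x1, dtype=float).ravel()
    x2 = np.asarray(x2, dtype=float).ravel()
    if x1.shape != x2.shape:
        raise ValueError(f"dimension mismatch: {x1.shape} vs {x2.shape}")
    return float(_matern_of_distance(np.linalg.norm(x1 - x2), cfg))


def kernel_matrix(X: np.ndarray, cfg: KernelConfig) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    diff = X[:, None, :] - X[None, :, :]
    return _matern_of_distance(np.sqrt((diff**2).sum(-1)), cfg)


def kernel_vector(X: np.ndarray, x: np.ndarray, cfg: KernelConfig) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    x = np.asarray(x, dtype=float).ravel()
    return _matern_of_distance(np.linalg.norm(X - x[None, :], axis=1), cfg)


def _spd_solve(A: np.ndarray, B: np.ndarray, base_jitter: float) -> np.ndarray:
    """Cholesky solve with x10 jitter escalation up to 1e-4."""
    try:
        cf = linalg.cho_factor(A, lower=True)
        return linalg.cho_solve(cf, B)
    except linalg.LinAlgError:
        pass
    jitter = base_jitter
    while jitter <= _MAX_JITTER:
        try:
            cf = linalg.cho_factor(A + jitter * np.eye(A.shape[0]), lower=True)
            return linalg.cho_solve(cf, B)
        except linalg.LinAlgError:
            jitter *= 10.0
    raise NumericalError(
        f"SPD factorization failed (n={A.shape[0]}, cond~{np.linalg.cond(A):.2e}, "
        f"max jitter {_MAX_JITTER})"
    )


def lgpr_predict(
    dataset: SlidingDataset,
    x: np.ndarray,
    kcfg: KernelConfig = KernelConfig(),
    sigma_min: float = 0.0,
    prior_mean: str = "window",
) -> tuple[float, float]:
    """Local-GP predictive mean and variance at feature vector ``x``.

    mean = m + k(x)^T (K + sigma_n^2 I)^{-1} (y - m)
    var  = k(x, x) - k(x)^T (K + sigma_n^2 I)^{-1} k(x)

    with ``m`` the window mean of the stored outputs (or 0 in zero-mean
    mode).  The variance is floored at ``sigma_min``.
    """
    if len(dataset) == 0:
        raise ValueError("sliding dataset is empty")
    X, y = dataset.X, dataset.y
    m = float(y.mean()) if prior_mean == "window" else 0.0
    K = kernel_matrix(X, kcfg) + kcfg.noise_var * np.eye(len(dataset))
    k = kernel_vector(X, x, kcfg)
    sol = _spd_solve(K, np.column_stack([y - m, k]), kcfg.jitter)
    mean = m + float(k @ sol[:, 0])
    var = float(matern_kernel(x, x, kcfg) - k @ sol[:, 1])
    return mean, max(var, sigma_min)


def adaptive_gain(sigma_t: float, sigma_p2: float) -> float:
    """Closed-form gain ``sigma_p^2 / (Sigma_t + sigma_p^2)``.

    Strictly decreasing in ``Sigma_t``, with limits 1 (as Sigma_t -> 0)
    and 0 (as Sigma_t -> inf).
    """
    if sigma_t <= 0:
        raise ValueError("Sigma_t must be positive (floor it first)")
    if sigma_p2 <= 0:
        raise ValueError("sigma_p2 must be positive")
    return sigma_p2 / (sigma_t + sigma_p2)


def fuse(theta_hat: float, theta_gp: float, sigma_t: float, sigma_p2: float) -> float:
    """Precision-weighted fusion of the instantaneous and GP predictions.

    Equivalent to ``G*theta_hat + (1-G)*theta_gp`` with the adaptive gain;
    always a convex combination of the two inputs.
    """
    if not (np.isfinite(theta_hat) and np.isfinite(theta_gp)):
        raise ValueError("non-finite fusion inputs")
    g = adaptive_gain(sigma_t, sigma_p2)
    return g * theta_hat + (1.0 - g) * theta_gp


@dataclass(frozen=True)
class EstimateRecord:
    """Per-step trace of the fusion loop.

    During warm-up (window not yet full) the fused output equals the raw
    prediction and ``sigma``/``gain``/``theta_gp`` are NaN sentinels.
    """

    t: int
    theta_hat: float
    theta_gp: float
    sigma: float
    gain: float
    theta_tilde: float
    warmup: bool


def _negative_log_marginal_likelihood(
    log_params: np.ndarray, X: np.ndarray, y: np.ndarray, kcfg: KernelConfig
) -> float:
    ls, sv = np.exp(log_params)
    cfg = KernelConfig(
        nu=kcfg.nu, length_scale=ls, signal_var=sv,
        noise_var=kcfg.noise_var, jitter=kcfg.jitter,
    )
    K = kernel_matrix(X, cfg) + cfg.noise_var * np.eye(len(y))
    try:
        cf = linalg.cho_factor(K + kcfg.jitter * np.eye(len(y)), lower=True)
    except linalg.LinAlgError:
        return 1e12
    alpha = linalg.cho_solve(cf, y)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    return float(0.5 * (y @ alpha + logdet + len(y) * np.log(2 * np.pi)))


def refit_kernel(X: np.ndarray, y: np.ndarray, kcfg: KernelConfig) -> KernelConfig:
    """Marginal-likelihood refit of length scale and signal variance."""
    yc = y - y.mean()
    res = optimize.minimize(
        _negative_log_marginal_likelihood,
        x0=np.log([kcfg.length_scale, kcfg.signal_var]),
        args=(X, yc, kcfg),
        method="Nelder-Mead",
        options={"maxiter": 60, "xatol": 1e-2, "fatol": 1e-3},
    )
    ls, sv = np.exp(res.x)
    return KernelConfig(
        nu=kcfg.nu, length_scale=float(ls), signal_var=float(sv),
        noise_var=kcfg.noise_var, jitter=kcfg.jitter,
    )


class FusionEngine:
    """Streaming state for the fusion post-processor."""

    def __init__(self, kcfg: KernelConfig = KernelConfig(), fcfg: FusionConfig = FusionConfig()):
        self.kcfg = kcfg
        self.fcfg = fcfg
        self.dataset = SlidingDataset(fcfg.window)
        self._t = 0

    def step(self, x: np.ndarray, theta_hat: float) -> EstimateRecord:
        """One iteration of the streaming loop.

        Warm-up passes the raw prediction through; afterwards the local GP
        supplies (mean, variance), the adaptive gain is computed, and the
        fused output is fed back into the sliding dataset.
        """
        x = np.asarray(x, dtype=float).ravel()
        theta_hat = float(theta_hat)
        if not self.dataset.full:
            rec = EstimateRecord(
                t=self._t, theta_hat=theta_hat, theta_gp=np.nan, sigma=np.nan,
                gain=np.nan, theta_tilde=theta_hat, warmup=True,
            )
        else:
            if self.fcfg.refit_every > 0 and self._t % self.fcfg.refit_every == 0:
                self.kcfg = refit_kernel(self.dataset.X, self.dataset.y, self.kcfg)
            mean, var = lgpr_predict(
                self.dataset, x, self.kcfg,
                sigma_min=self.fcfg.sigma_min, prior_mean=self.fcfg.prior_mean,
            )
            gain = adaptive_gain(var, self.fcfg.sigma_p2)
            tilde = gain * theta_hat + (1.0 - gain) * mean
            rec = EstimateRecord(
                t=self._t, theta_hat=theta_hat, theta_gp=mean, sigma=var,
                gain=gain, theta_tilde=tilde, warmup=False,
            )
        self.dataset.append(x, rec.theta_tilde)
        self._t += 1
        return rec


def run_fusion_stream(
    X: np.ndarray,
    theta_hat: np.ndarray,
    kcfg: KernelConfig = KernelConfig(),
    fcfg: FusionConfig = FusionConfig(),
) -> list[EstimateRecord]:
    """Run the full streaming loop over a prediction stream.

    ``X`` holds one standardized feature vector per row, aligned with
    ``theta_hat``.  Returns the per-step trace.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    theta_hat = np.asarray(theta_hat, dtype=float)
    if X.shape[0] != theta_hat.size:
        raise ValueError("feature rows and prediction stream length mismatch")
    engine = FusionEngine(kcfg, fcfg)
    return [engine.step(X[i], theta_hat[i]) for i in range(theta_hat.size)]


def records_to_frame(records: list[EstimateRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "t": r.t, "theta_hat": r.theta_hat, "theta_gp": r.theta_gp,
                "sigma": r.sigma, "gain": r.gain, "theta_tilde": r.theta_tilde,
                "warmup": r.warmup,
            }
            for r in records
        ],
        columns=["t", "theta_hat", "theta_gp", "sigma", "gain", "theta_tilde", "warmup"],
    )
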