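"""Time-varying GGMs over trajectory windows (kernel-smoothed covariances).

The trajectory is cut into contiguous non-overlapping windows of ``width``
frames; each window gets its own sparse GGM, but the covariance fed to the
solver is a kernel-weighted blend of neighbouring windows' covariances, so
the sequence of models evolves smoothly while still tracking sub-state
changes.  The module also computes the segmentation diagnostics used to
locate sub-state boundaries: per-window entropy, the likelihood of each
window's frames under the previous window's model, a frame-by-model
log-likelihood matrix, and the symmetric KL divergence between sequential
models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimate import CovariateMatrix, EstimationSettings, bcd_solve
from .model import (
    GaussianGraphicalModel,
    differential_entropy,
    log_density,
    symmetric_kl,
)

__all__ = [
    "WindowSpec",
    "KernelSpec",
    "TimeVaryingModel",
    "partition_windows",
    "weighted_covariance",
    "sawtooth_kernel",
    "learn_time_varying",
    "entropy_series",
    "next_window_loglik",
    "loglik_matrix",
    "sequential_kl",
    "diagnostics_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowSpec:
    """Non-overlapping contiguous windows: window k covers frames
    [k*width, (k+1)*width); a trailing partial window is dropped."""

    width: int
    count: int

    def frames(self, tau: int) -> slice:
        if not 0 <= tau < self.count:
            raise ValueError(f"window index {tau} out of range [0, {self.count})")
        return slice(tau * self.width, (tau + 1) * self.width)


@dataclass(frozen=True)
class KernelSpec:
    """Smoothing kernel over window offsets.

    ``offsets[i]`` is a (signed) window offset relative to the current
    window and ``weights[i]`` its nonnegative weight.  Offsets falling off
    the trajectory are dropped and the remaining weights renormalized.
    """

    offsets: tuple[int, ...]
    weights: tuple[float, ...]

    def __post_init__(self):
        if len(self.offsets) != len(self.weights):
            raise ValueError("offsets and weights must align")
        w = np.asarray(self.weights, float)
        if not np.all(np.isfinite(w)) or np.any(w < 0):
            raise ValueError("kernel weights must be finite and nonnegative")
        if not np.any(w > 0):
            raise ValueError("kernel needs at least one positive weight")


@dataclass
class TimeVaryingModel:
    """Ordered sequence of per-window GGMs plus the specs that produced it."""

    models: list[GaussianGraphicalModel]
    window_spec: WindowSpec
    kernel_spec: KernelSpec
    lambda_: float

    @property
    def T(self) -> int:
        return len(self.models)


def partition_windows(data: CovariateMatrix, width: int) -> WindowSpec:
    """Split t frames into T = floor(t / width) full windows."""
    if width < 2:
        raise ValueError("window width must be >= 2 frames")
    if width > data.t:
        raise ValueError(f"window width {width} exceeds trajectory length {data.t}")
    count = data.t // width
    dropped = data.t - count * width
    if dropped:
        logger.info("dropping %d trailing frame(s) not filling a window", dropped)
    return WindowSpec(width=width, count=count)


def sawtooth_kernel(depth: int) -> KernelSpec:
    """Trailing one-sided kernel: the current window, then each previous
    window at half the weight of the one after it, normalized to sum 1.

    depth=2 gives (2/3, 1/3) over offsets (0, -1); depth=3 gives
    (4/7, 2/7, 1/7), i.e. 0.57 / 0.29 / 0.14 at two decimals.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    raw = np.array([2.0 ** (-k) for k in range(depth)])
    w = raw / raw.sum()
    return KernelSpec(offsets=tuple(-k for k in range(depth)), weights=tuple(w))


def _window_moments(data: CovariateMatrix, spec: WindowSpec, k: int) -> tuple[np.ndarray, np.ndarray]:
    vals = data.values[spec.frames(k)]
    mu = vals.mean(axis=0)
    dev = vals - mu
    return mu, dev.T @ dev / vals.shape[0]


def _effective_kernel(kernel: KernelSpec, tau: int, count: int) -> tuple[np.ndarray, np.ndarray]:
    ks, ws = [], []
    for off, w in zip(kernel.offsets, kernel.weights):
        k = tau + off
        if 0 <= k < count and w > 0:
            ks.append(k)
            ws.append(w)
    if not ws:
        raise ValueError(f"no kernel weight falls inside the trajectory at window {tau}")
    ws = np.asarray(ws, float)
    return np.asarray(ks, int), ws / ws.sum()


def weighted_covariance(
    data: CovariateMatrix, window_spec: WindowSpec, kernel_spec: KernelSpec, tau: int
) -> np.ndarray:
    """Kernel-weighted covariance S(tau): convex combination of the centered
    per-window second-moment matrices of the windows the kernel touches.
    Offsets clipped at the trajectory edge are excluded from the normalizer.
    """
    ks, ws = _effective_kernel(kernel_spec, tau, window_spec.count)
    n = data.n
    S = np.zeros((n, n))
    for k, w in zip(ks, ws):
        _, cov_k = _window_moments(data, window_spec, k)
        S += w * cov_k
    return 0.5 * (S + S.T)


def _weighted_mean(
    data: CovariateMatrix, window_spec: WindowSpec, kernel_spec: KernelSpec, tau: int
) -> np.ndarray:
    ks, ws = _effective_kernel(kernel_spec, tau, window_spec.count)
    mu = np.zeros(data.n)
    for k, w in zip(ks, ws):
        mu_k, _ = _window_moments(data, window_spec, k)
        mu += w * mu_k
    return mu


def learn_time_varying(
    data: CovariateMatrix,
    width: int,
    kernel_spec: KernelSpec,
    settings: EstimationSettings,
) -> TimeVaryingModel:
    """Fit one sparse GGM per window from the kernel-weighted covariance.

    The per-window mean uses the same kernel weights as S(tau).  A single
    lambda is shared across all windows.  Consecutive solves are
    warm-started from the previous window's W; the dual optimum is unique,
    so warm starting changes only the path, not the answer.
    """
    spec = partition_windows(data, width)
    models: list[GaussianGraphicalModel] = []
    W_prev: np.ndarray | None = None
    for tau in range(spec.count):
        S_tau = weighted_covariance(data, spec, kernel_spec, tau)
        result = bcd_solve(S_tau, settings, W0=W_prev)
        W_prev = result.W
        mu_tau = _weighted_mean(data, spec, kernel_spec, tau)
        models.append(
            GaussianGraphicalModel(mean=mu_tau, precision=result.precision,
                                   labels=data.labels)
        )
    return TimeVaryingModel(models=models, window_spec=spec,
                            kernel_spec=kernel_spec, lambda_=settings.lambda_)


def entropy_series(tvm: TimeVaryingModel) -> np.ndarray:
    """Differential entropy of each window model, in window order (nats)."""
    return np.array([differential_entropy(m) for m in tvm.models])


def next_window_loglik(tvm: TimeVaryingModel, data: CovariateMatrix) -> np.ndarray:
    """Entry i: mean log-density of window i+1's frames under model i.

    Sharp drops mark moments where the next window no longer looks like the
    state the current model captured — i.e. sub-state transitions.
    """
    if tvm.T < 2:
        raise ValueError("need at least two windows")
    out = np.empty(tvm.T - 1)
    for i in range(tvm.T - 1):
        frames = data.values[tvm.window_spec.frames(i + 1)]
        out[i] = float(np.mean(log_density(tvm.models[i], frames)))
    return out


def loglik_matrix(tvm: TimeVaryingModel, data: CovariateMatrix) -> np.ndarray:
    """(t, T) matrix of per-frame log-densities under every window model.

    Block structure along the diagonal exposes the sub-states the
    trajectory visits.
    """
    used = tvm.window_spec.count * tvm.window_spec.width
    frames = data.values[:used]
    cols = [log_density(m, frames) for m in tvm.models]
    return np.stack(cols, axis=1)


def sequential_kl(tvm: TimeVaryingModel) -> np.ndarray:
    """Symmetric KL between model tau and model tau+1, for each tau."""
    if tvm.T < 2:
        raise ValueError("need at least two windows")
    return np.array(
        [symmetric_kl(tvm.models[i], tvm.models[i + 1]) for i in range(tvm.T - 1)]
    )


def diagnostics_frame(tvm: TimeVaryingModel, data: CovariateMatrix) -> pd.DataFrame:
    """Segmentation diagnostics as a tidy table (window, entropy,
    next_window_loglik, sequential_symkl); the last two are NaN-padded so
    every column has length T."""
    ent = entropy_series(tvm)
    nwl = np.append(next_window_loglik(tvm, data), np.nan) if tvm.T > 1 else np.array([np.nan])
    skl = np.append(sequential_kl(tvm), np.nan) if tvm.T > 1 else np.array([np.nan])
    return pd.DataFrame(
        {
            "window": np.arange(tvm.T),
            "entropy": ent,
            "next_window_loglik": nwl,
            "sequential_symkl": skl,
        }
    )
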