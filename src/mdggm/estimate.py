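"""Sparse precision-matrix estimation by block coordinate descent.

The estimator maximizes the L1-penalized Gaussian log-likelihood

    log |P| - trace(S P) - lambda * ||P||_1        (P = precision, S = sample cov)

where the L1 norm sums the absolute values of *all* entries, diagonal
included.  Rather than attacking this non-smooth primal directly, the solver
works on the smooth convex dual

    maximize  log |W|   subject to  ||W - S||_inf <= lambda,

whose optimizer W is the regularized covariance; the penalized precision is
W^-1.  One block-coordinate step updates a single row/column of W by solving
a box-constrained quadratic subproblem, itself handled through its lasso
dual by cyclic coordinate minimization.  The duality gap

    trace(W^-1 S) - n + lambda * ||W^-1||_1

is the convergence criterion: it is zero at the optimum and non-negative
everywhere, so it is a certificate, not a heuristic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .model import GaussianGraphicalModel, edge_list

__all__ = [
    "CovariateMatrix",
    "EstimationSettings",
    "SolveResult",
    "sample_mean",
    "sample_covariance",
    "bcd_solve",
    "learn_ggm",
    "penalized_objective",
    "threshold_baseline",
    "default_lambda",
]

logger = logging.getLogger(__name__)


@dataclass
class CovariateMatrix:
    """A t-frame by n-covariate time series, the universal model input.

    ``values[k]`` is the covariate vector of frame ``k`` (e.g. per-residue
    C-alpha fluctuation magnitudes in Angstrom); frames are in strict
    temporal order.
    """

    values: np.ndarray
    labels: tuple[str, ...] = ()
    frame_index: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] < 2:
            raise ValueError("a covariate matrix needs at least 2 frames")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("covariate matrix contains non-finite entries")
        if not self.labels:
            self.labels = tuple(f"x{i}" for i in range(self.values.shape[1]))
        self.labels = tuple(self.labels)
        if len(self.labels) != self.values.shape[1]:
            raise ValueError("label count must match covariate count")
        if self.frame_index is None:
            self.frame_index = np.arange(self.values.shape[0])
        else:
            self.frame_index = np.asarray(self.frame_index)
            if self.frame_index.shape[0] != self.values.shape[0]:
                raise ValueError("frame index length must match frame count")
            if np.any(np.diff(self.frame_index.astype(float)) <= 0):
                raise ValueError("frame index must be strictly increasing")

    @property
    def t(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]


@dataclass
class EstimationSettings:
    """Knobs of the sparse estimator.

    lambda_ is the sparsity/likelihood trade-off (larger => sparser graph);
    epsilon the duality-gap tolerance (default scales with dimension as
    1e-6 * n, applied inside the solver when left as None); max_sweeps caps
    the number of full passes over the columns.
    """

    lambda_: float = 0.1
    epsilon: float | None = None
    max_sweeps: int = 200

    def __post_init__(self):
        if self.lambda_ < 0:
            raise ValueError("lambda must be >= 0")
        if self.epsilon is not None and self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.max_sweeps < 1:
            raise ValueError("max_sweeps must be >= 1")


@dataclass
class SolveResult:
    """Outcome of the dual solve: W (regularized covariance), its inverse,
    and per-sweep trace data for auditing monotonicity and feasibility."""

    W: np.ndarray
    precision: np.ndarray
    sweeps_used: int
    converged: bool
    final_gap: float
    logdet_history: list[float] = field(default_factory=list)
    feasible_history: list[bool] = field(default_factory=list)


def sample_mean(data: CovariateMatrix) -> np.ndarray:
    """Column means mu = (1/t) sum_k d_k."""
    return data.values.mean(axis=0)


def sample_covariance(data: CovariateMatrix) -> np.ndarray:
    """Centered second-moment matrix with 1/t scaling (symmetric PSD).

    The 1/t scaling makes trace(S P) the per-frame average of the quadratic
    likelihood term, so lambda keeps a comparable meaning across trajectory
    lengths.
    """
    if data.t < 2:
        raise ValueError("need at least 2 frames for a covariance")
    dev = data.values - data.values.mean(axis=0)
    s = dev.T @ dev / data.t
    return 0.5 * (s + s.T)


def _lasso_cd(B: np.ndarray, s: np.ndarray, lam: float, z0: np.ndarray,
              tol: float = 1e-10, max_iter: int = 2000) -> np.ndarray:
    """Cyclic coordinate minimization of  z'Bz - 2 s'z + 2 lam ||z||_1.

    This is the dual of the box-constrained column subproblem; the primal
    column is recovered as y = B z.  B is SPD (a principal submatrix of a
    PD iterate).
    """
    m = s.shape[0]
    z = z0.copy()
    Bz = B @ z
    diag = np.diag(B)
    for _ in range(max_iter):
        zmax = 0.0
        dmax = 0.0
        for j in range(m):
            zj_old = z[j]
            # residual excluding coordinate j
            r = s[j] - (Bz[j] - diag[j] * zj_old)
            zj_new = np.sign(r) * max(abs(r) - lam, 0.0) / diag[j]
            if zj_new != zj_old:
                delta = zj_new - zj_old
                Bz += delta * B[:, j]
                z[j] = zj_new
                dmax = max(dmax, abs(delta))
            zmax = max(zmax, abs(z[j]))
        if dmax <= tol * max(zmax, 1.0):
            break
    return z


def _duality_gap(W: np.ndarray, S: np.ndarray, lam: float) -> tuple[float, np.ndarray]:
    prec = np.linalg.inv(W)
    prec = 0.5 * (prec + prec.T)
    gap = float(np.sum(prec * S)) - W.shape[0] + lam * float(np.abs(prec).sum())
    return gap, prec


def bcd_solve(S: np.ndarray, settings: EstimationSettings,
              W0: np.ndarray | None = None) -> SolveResult:
    """Maximize log|W| over the box ||W - S||_inf <= lambda.

    Starts from W = S + lambda*I (or a warm start clipped into the box) and
    cycles over columns; each column update solves the inner box-constrained
    quadratic through its lasso dual.  The diagonal stays at S_ii + lambda,
    where the per-column log-det gain is maximal.  All iterates are strictly
    positive-definite, so the precision W^-1 always exists.

    With lambda = 0 the feasible set is the single point W = S, which must
    then be strictly positive-definite.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("S must be square")
    if not np.allclose(S, S.T, atol=1e-8 * (1.0 + np.abs(S).max())):
        raise ValueError("S must be symmetric")
    n = S.shape[0]
    lam = settings.lambda_
    eps = settings.epsilon if settings.epsilon is not None else 1e-6 * n

    if lam == 0.0:
        # feasible set degenerates to {S}
        try:
            np.linalg.cholesky(S)
        except np.linalg.LinAlgError as exc:
            raise ValueError("lambda=0 requires a strictly PD sample covariance") from exc
        gap, prec = _duality_gap(S, S, 0.0)
        return SolveResult(W=S.copy(), precision=prec, sweeps_used=0,
                           converged=True, final_gap=gap,
                           logdet_history=[float(np.linalg.slogdet(S)[1])],
                           feasible_history=[True])

    if W0 is not None:
        W = 0.5 * (W0 + W0.T)
        # project any warm start into the feasible box, keep diagonal pinned
        W = np.clip(W, S - lam, S + lam)
        np.fill_diagonal(W, np.diag(S) + lam)
        try:
            np.linalg.cholesky(W)
        except np.linalg.LinAlgError:
            W = S + lam * np.eye(n)
    else:
        W = S + lam * np.eye(n)

    idx = np.arange(n)
    z_cache = np.zeros((n, n - 1))
    logdet_history: list[float] = [float(np.linalg.slogdet(W)[1])]
    feasible_history: list[bool] = [bool(np.max(np.abs(W - S)) <= lam + 1e-8)]

    converged = False
    gap = np.inf
    sweeps = 0
    for sweeps in range(1, settings.max_sweeps + 1):
        for j in range(n):
            rest = idx[idx != j]
            B = W[np.ix_(rest, rest)]
            s_j = S[rest, j]
            z = _lasso_cd(B, s_j, lam, z_cache[j])
            z_cache[j] = z
            y = B @ z
            # numerical safety: y must sit inside the box around S_j
            y = np.clip(y, s_j - lam, s_j + lam)
            W[rest, j] = y
            W[j, rest] = y
        logdet_history.append(float(np.linalg.slogdet(W)[1]))
        feasible_history.append(bool(np.max(np.abs(W - S)) <= lam + 1e-8))
        gap, prec = _duality_gap(W, S, lam)
        if gap <= eps:
            converged = True
            break
    else:
        gap, prec = _duality_gap(W, S, lam)

    # Assemble the precision from the converged lasso coefficients: with
    # y = B z the block inverse gives P_jj = 1/(W_jj - y.z), P_j = -z P_jj,
    # so coordinates soft-thresholded to zero become exact zeros in the
    # precision instead of inversion noise at the duality-gap level.
    prec = np.empty_like(W)
    for j in range(n):
        rest = idx[idx != j]
        B = W[np.ix_(rest, rest)]
        z = _lasso_cd(B, S[rest, j], lam, z_cache[j])
        y = W[rest, j]
        p_jj = 1.0 / (W[j, j] - float(y @ z))
        prec[j, j] = p_jj
        prec[rest, j] = -z * p_jj
    prec = 0.5 * (prec + prec.T)
    gap = float(np.sum(prec * S)) - n + lam * float(np.abs(prec).sum())

    if not converged:
        logger.warning(
            "BCD did not reach gap <= %.3g in %d sweeps (final gap %.3g)",
            eps, settings.max_sweeps, gap,
        )
    return SolveResult(W=W, precision=prec, sweeps_used=sweeps,
                       converged=converged, final_gap=gap,
                       logdet_history=logdet_history,
                       feasible_history=feasible_history)


def learn_ggm(data: CovariateMatrix, settings: EstimationSettings) -> GaussianGraphicalModel:
    """Fit a sparse GGM: sample mean + regularized covariance from the dual solve."""
    S = sample_covariance(data)
    result = bcd_solve(S, settings)
    return GaussianGraphicalModel(
        mean=sample_mean(data), precision=result.precision, labels=data.labels
    )


def penalized_objective(precision: np.ndarray, S: np.ndarray, lam: float) -> float:
    """L1-penalized log-likelihood  log|P| - trace(S P) - lam * ||P||_1.

    The L1 norm sums absolute values of *all* entries (diagonal included).
    """
    precision = np.asarray(precision, dtype=float)
    sign, logdet = np.linalg.slogdet(precision)
    if sign <= 0:
        raise ValueError("precision must be positive-definite")
    return float(logdet - np.sum(S * precision) - lam * np.abs(precision).sum())


def threshold_baseline(data: CovariateMatrix, edge_count: int) -> list[tuple[int, int, float]]:
    """Sub-optimal comparator: invert the sample covariance, keep the
    ``edge_count`` largest-magnitude off-diagonal couplings.

    Ties in magnitude are broken by lexicographic (i, j).  Raises if the
    sample covariance is singular (use the regularized estimator then).
    """
    S = sample_covariance(data)
    try:
        prec = np.linalg.inv(S)
    except np.linalg.LinAlgError as exc:
        raise RuntimeError(
            "sample covariance is singular; use the regularized estimator"
        ) from exc
    n = S.shape[0]
    entries = [
        (i, j, float(prec[i, j]))
        for i in range(n)
        for j in range(i + 1, n)
        if prec[i, j] != 0.0
    ]
    entries.sort(key=lambda e: (-abs(e[2]), e[0], e[1]))
    return entries[:edge_count]


def default_lambda(t: int, n: int, alpha: float = 0.05,
                   scales: np.ndarray | None = None) -> float:
    """Analytic regularization level controlling false edge discovery.

    Uses the Student-t tail construction: with ``q`` the upper
    ``alpha / (2 n^2)`` quantile of a t distribution on ``t - 2`` degrees of
    freedom,

        lambda = (max_{i<j} sigma_i sigma_j) * q / sqrt(t - 2 + q^2).

    At this level the probability of the estimator connecting any pair of
    variables that are truly non-adjacent is bounded by ``alpha``.  With no
    ``scales`` supplied the variables are treated as unit-variance, which
    matches covariates standardized beforehand.  Monotone non-increasing in
    ``t`` and decreasing toward 0 as the sample grows.
    """
    if t <= 2:
        raise ValueError("need t > 2 frames")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    q = float(stats.t.ppf(1.0 - alpha / (2.0 * n * n), df=t - 2))
    scale = 1.0
    if scales is not None:
        scales = np.asarray(scales, float)
        if scales.shape[0] != n:
            raise ValueError("scales must have length n")
        prod = np.outer(scales, scales)
        scale = float(np.max(prod[~np.eye(n, dtype=bool)])) if n > 1 else float(scales[0] ** 2)
    return scale * q / np.sqrt(t - 2 + q * q)
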