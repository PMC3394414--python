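"""Analytic machinery for Gaussian graphical models (GGMs).

A GGM is a multivariate normal whose precision matrix (inverse covariance)
doubles as the adjacency structure of a Markov random field: a nonzero
off-diagonal entry ``precision[i, j]`` means variables ``i`` and ``j`` are
directly coupled; a zero means any correlation between them is mediated by
other variables.  Everything downstream — density evaluation, entropy,
KL divergence, conditioning on a clamped subset of variables, and sampling —
is available in closed form, which is what makes these models attractive
summaries of molecular-dynamics covariates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla

__all__ = [
    "GaussianGraphicalModel",
    "VariablePartition",
    "log_density",
    "free_energy",
    "differential_entropy",
    "kl_divergence",
    "symmetric_kl",
    "condition",
    "sample",
    "data_log_likelihood",
    "edge_list",
    "save_model",
    "load_model",
    "write_edges_csv",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


def _as_spd(mat: np.ndarray, name: str) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{name} must be a square matrix, got shape {mat.shape}")
    if not np.allclose(mat, mat.T, atol=1e-8 * (1.0 + np.abs(mat).max())):
        raise ValueError(f"{name} must be symmetric")
    return 0.5 * (mat + mat.T)


@dataclass(frozen=True)
class GaussianGraphicalModel:
    """A Gaussian Markov random field with parameters (mean, precision).

    Parameters
    ----------
    mean : (n,) array
        Mean vector, in covariate units (Angstrom for positional
        fluctuations).
    precision : (n, n) array
        Symmetric positive-definite precision matrix; its off-diagonal
        support is the edge set of the model's graph.
    labels : sequence of str, optional
        One name per covariate (e.g. residue identifiers).  Defaults to
        ``x0 … x{n-1}``.

    The covariance and the natural parameter ``h = precision @ mean`` are
    derived lazily and cached; the precision is the stored representation.
    """

    mean: np.ndarray
    precision: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self):
        mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        prec = _as_spd(self.precision, "precision")
        n = mean.shape[0]
        if prec.shape != (n, n):
            raise ValueError(
                f"precision shape {prec.shape} incompatible with mean of length {n}"
            )
        try:
            chol_prec = np.linalg.cholesky(prec)
        except np.linalg.LinAlgError as exc:
            raise ValueError("precision must be positive-definite") from exc
        labels = tuple(self.labels) if self.labels else tuple(f"x{i}" for i in range(n))
        if len(labels) != n:
            raise ValueError(f"expected {n} labels, got {len(labels)}")
        # covariance via Cholesky of the precision: Sigma = L^-T L^-1
        inv_l = sla.solve_triangular(chol_prec, np.eye(n), lower=True)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "precision", prec)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "_chol_prec", chol_prec)
        object.__setattr__(self, "_cov", inv_l.T @ inv_l)

    @property
    def n(self) -> int:
        return self.mean.shape[0]

    @property
    def covariance(self) -> np.ndarray:
        """Inverse of the precision matrix (dense, cached)."""
        return self._cov

    @property
    def natural_param(self) -> np.ndarray:
        """The natural parameter h = precision @ mean."""
        return self.precision @ self.mean

    @property
    def log_det_cov(self) -> float:
        # |Sigma| = 1/|precision|; |precision| = prod diag(chol)^2
        return -2.0 * float(np.sum(np.log(np.diag(self._chol_prec))))

    @classmethod
    def from_covariance(
        cls, mean: np.ndarray, covariance: np.ndarray, labels: Sequence[str] = ()
    ) -> "GaussianGraphicalModel":
        cov = _as_spd(covariance, "covariance")
        prec = np.linalg.inv(cov)
        return cls(mean=np.asarray(mean, float), precision=0.5 * (prec + prec.T),
                   labels=tuple(labels))


@dataclass(frozen=True)
class VariablePartition:
    """A split of the variables into a clamped set V and a free set W.

    ``conditioned`` holds the indices being fixed, ``values`` the vector they
    are fixed to.  The free set is the complement; both sets must be
    non-empty (a fully clamped model is a point mass, not a GGM).
    """

    conditioned: tuple[int, ...]
    values: np.ndarray

    def free_indices(self, n: int) -> np.ndarray:
        v = set(self.conditioned)
        return np.array([i for i in range(n) if i not in v], dtype=int)

    def validate(self, n: int) -> None:
        idx = np.asarray(self.conditioned, dtype=int)
        vals = np.atleast_1d(np.asarray(self.values, dtype=float))
        if idx.size == 0:
            raise ValueError("conditioned set V must be non-empty")
        if len(set(idx.tolist())) != idx.size:
            raise ValueError("conditioned indices must be distinct")
        if idx.min() < 0 or idx.max() >= n:
            raise ValueError(f"conditioned indices out of range for n={n}")
        if idx.size >= n:
            raise ValueError("free set W must be non-empty (cannot clamp all variables)")
        if vals.shape[0] != idx.size:
            raise ValueError("values length must match the conditioned index set")


def _check_vector(model: GaussianGraphicalModel, x: np.ndarray) -> np.ndarray:
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if x.shape[-1] != model.n:
        raise ValueError(f"expected length-{model.n} vector(s), got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("input vector contains non-finite values")
    return x


def log_density(model: GaussianGraphicalModel, x: np.ndarray) -> float | np.ndarray:
    """Log of the Gaussian density at ``x``.

    Accepts a single length-n vector or a (t, n) stack of vectors; returns a
    scalar or a length-t array respectively.
    """
    x = _check_vector(model, x)
    dev = x - model.mean
    # quadratic form via the precision Cholesky: dev' P dev = ||L' dev||^2
    q = np.square(dev @ model._chol_prec).sum(axis=-1)
    out = -0.5 * (model.n * _LOG_2PI + model.log_det_cov + q)
    return float(out) if np.ndim(out) == 0 else out


def free_energy(model: GaussianGraphicalModel) -> float:
    """-ln Z with Z = sqrt((2 pi)^n |Sigma|); equals the log density at the mean."""
    return -0.5 * (model.n * _LOG_2PI + model.log_det_cov)


def differential_entropy(model: GaussianGraphicalModel) -> float:
    """Differential entropy (1/2) ln((2 pi e)^n |Sigma|), in nats."""
    return 0.5 * (model.n * (_LOG_2PI + 1.0) + model.log_det_cov)


def kl_divergence(m0: GaussianGraphicalModel, m1: GaussianGraphicalModel) -> float:
    """KL(m0 || m1) between two Gaussians of the same dimension.

    Closed form:
    ``1/2 (tr(S1^-1 S0) + (mu1-mu0)' S1^-1 (mu1-mu0) - ln(|S0|/|S1|) - n)``.
    """
    if m0.n != m1.n:
        raise ValueError(f"dimension mismatch: {m0.n} vs {m1.n}")
    dmu = m1.mean - m0.mean
    trace_term = float(np.sum(m1.precision * m0.covariance))
    quad = float(dmu @ m1.precision @ dmu)
    log_ratio = m0.log_det_cov - m1.log_det_cov
    return 0.5 * (trace_term + quad - log_ratio - m0.n)


def symmetric_kl(m0: GaussianGraphicalModel, m1: GaussianGraphicalModel) -> float:
    """Symmetrized divergence KL(m0||m1) + KL(m1||m0)."""
    return kl_divergence(m0, m1) + kl_divergence(m1, m0)


def condition(
    model: GaussianGraphicalModel, partition: VariablePartition
) -> GaussianGraphicalModel:
    """Condition the model on clamped values for a subset V of variables.

    Returns the Gaussian over the free set W with

    - mean ``mu_W + Sigma_WV Sigma_VV^-1 (v - mu_V)``
    - covariance ``Sigma_WW - Sigma_WV Sigma_VV^-1 Sigma_VW``

    (the Schur complement), which is again positive-definite.
    """
    partition.validate(model.n)
    v_idx = np.asarray(partition.conditioned, dtype=int)
    w_idx = partition.free_indices(model.n)
    vals = np.atleast_1d(np.asarray(partition.values, dtype=float))

    cov = model.covariance
    s_vv = cov[np.ix_(v_idx, v_idx)]
    s_wv = cov[np.ix_(w_idx, v_idx)]
    s_ww = cov[np.ix_(w_idx, w_idx)]

    gain = s_wv @ np.linalg.inv(s_vv)
    cond_mean = model.mean[w_idx] + gain @ (vals - model.mean[v_idx])
    cond_cov = s_ww - gain @ s_wv.T
    cond_cov = 0.5 * (cond_cov + cond_cov.T)
    labels = tuple(model.labels[i] for i in w_idx)
    return GaussianGraphicalModel.from_covariance(cond_mean, cond_cov, labels)


def sample(
    model: GaussianGraphicalModel, count: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``count`` i.i.d. vectors from the model; deterministic given seed.

    Uses the lower-triangular Cholesky factor of the covariance, so the map
    from standard-normal draws to samples is fixed by the model alone.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    chol = np.linalg.cholesky(model.covariance)
    z = rng.standard_normal((count, model.n))
    return model.mean + z @ chol.T


def data_log_likelihood(
    model: GaussianGraphicalModel,
    data: np.ndarray,
    normalization: str = "total",
) -> float:
    """Log-likelihood of a (t, n) covariate matrix under the model.

    ``normalization`` divides the summed per-frame log densities by nothing
    (``"total"``), by the frame count (``"per_frame"``), or by frames times
    dimension (``"per_frame_per_dim"``).
    """
    values = np.atleast_2d(np.asarray(getattr(data, "values", data), dtype=float))
    if values.shape[1] != model.n:
        raise ValueError(
            f"data has {values.shape[1]} columns but model has {model.n} variables"
        )
    total = float(np.sum(log_density(model, values)))
    t = values.shape[0]
    if normalization == "total":
        return total
    if normalization == "per_frame":
        return total / t
    if normalization == "per_frame_per_dim":
        return total / (t * model.n)
    raise ValueError(f"unknown normalization {normalization!r}")


def edge_list(
    model: GaussianGraphicalModel, threshold: float = 1e-8
) -> list[tuple[int, int, float]]:
    """Off-diagonal precision entries with |value| strictly above threshold.

    Returns tuples ``(i, j, weight)`` with ``i < j``; the weight is the
    precision entry itself (a direct-coupling strength, not a correlation).
    """
    prec = model.precision
    n = model.n
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            w = prec[i, j]
            if abs(w) > threshold:
                out.append((i, j, float(w)))
    return out


def save_model(model: GaussianGraphicalModel, path: str | Path, lam: float | None = None,
               meta: dict | None = None) -> None:
    """Serialize to a single JSON document; covariance is recomputed on load."""
    doc = {
        "labels": list(model.labels),
        "mean": model.mean.tolist(),
        "precision": model.precision.tolist(),
        "lambda": lam,
        "meta": meta or {},
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def load_model(path: str | Path) -> GaussianGraphicalModel:
    doc = json.loads(Path(path).read_text())
    return GaussianGraphicalModel(
        mean=np.asarray(doc["mean"], float),
        precision=np.asarray(doc["precision"], float),
        labels=tuple(doc["labels"]),
    )


def write_edges_csv(
    model: GaussianGraphicalModel, path: str | Path, threshold: float = 1e-8
) -> pd.DataFrame:
    """Export the edge list as CSV with columns i_label, j_label, weight."""
    rows = [
        {"i_label": model.labels[i], "j_label": model.labels[j], "weight": w}
        for i, j, w in edge_list(model, threshold)
    ]
    df = pd.DataFrame(rows, columns=["i_label", "j_label", "weight"])
    df.to_csv(path, index=False)
    return df
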