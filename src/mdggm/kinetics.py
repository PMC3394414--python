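"""Markov chains over clustered window models (conformational kinetics).

The window models from the time-varying fit are compared pairwise with the
symmetric KL divergence, grouped by complete-linkage agglomerative
clustering, and the clusters treated as states of a Markov chain whose
transition probabilities come from counting which cluster follows which in
trajectory order.  Each state carries a representative GGM (the KL-medoid
of its cluster by default), so the chain is fully generative: sample a
state path, then sample conformations from each visited state's model.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .estimate import CovariateMatrix
from .model import GaussianGraphicalModel, sample as sample_model, symmetric_kl
from .timevarying import TimeVaryingModel

__all__ = [
    "ClusterAssignment",
    "MarkovChainModel",
    "pairwise_symkl",
    "complete_linkage",
    "suggest_k",
    "estimate_chain",
    "sample_chain_trajectory",
    "stationary_distribution",
    "save_chain",
    "load_chain",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClusterAssignment:
    """Cluster labels (0-based) for the T window models, in temporal order.

    Ids are assigned by order of first appearance along the trajectory, so
    label 0 is always the cluster of the first window.
    """

    labels: np.ndarray
    k: int

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=int)
        if set(np.unique(labels).tolist()) != set(range(self.k)):
            raise ValueError("every cluster id in 0..k-1 must be used")
        object.__setattr__(self, "labels", labels)


@dataclass
class MarkovChainModel:
    """k states with prior, row-stochastic transition matrix, and one
    representative GGM per state; frames_per_state is the window width the
    chain was estimated at (one chain step emits that many frames)."""

    prior: np.ndarray
    transition: np.ndarray
    state_models: list[GaussianGraphicalModel]
    frames_per_state: int

    def __post_init__(self):
        self.prior = np.asarray(self.prior, float)
        self.transition = np.asarray(self.transition, float)
        k = self.prior.shape[0]
        if self.transition.shape != (k, k):
            raise ValueError("transition matrix shape must match prior length")
        if np.any(self.prior < 0) or np.any(self.transition < 0):
            raise ValueError("probabilities must be nonnegative")
        if not math.isclose(self.prior.sum(), 1.0, abs_tol=1e-8):
            raise ValueError("prior must sum to 1")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("transition rows must sum to 1")
        if len(self.state_models) != k:
            raise ValueError("need one representative model per state")

    @property
    def k(self) -> int:
        return self.prior.shape[0]


def pairwise_symkl(tvm: TimeVaryingModel) -> np.ndarray:
    """T x T matrix of symmetric KL divergences between window models.

    In the symmetrized divergence the log-determinant terms cancel, leaving

        KLsym(a, b) = 1/2 ( tr(P_b S_a) + tr(P_a S_b)
                            + dmu' (P_a + P_b) dmu - 2n ),

    evaluated for all pairs at once from the stacked means, covariances and
    precisions (identical to summing the two one-directional closed forms).
    """
    T = tvm.T
    if T < 2:
        raise ValueError("need at least two models")
    n = tvm.models[0].n
    means = np.stack([m.mean for m in tvm.models])
    covs = np.stack([m.covariance for m in tvm.models])
    precs = np.stack([m.precision for m in tvm.models])
    # cross_tr[a, b] = tr(S_a P_b); symmetric matrices so elementwise works
    cross_tr = np.einsum("aij,bij->ab", covs, precs)
    dmu = means[:, None, :] - means[None, :, :]
    quad = np.einsum("abi,bij,abj->ab", dmu, precs, dmu)
    d = 0.5 * (cross_tr + cross_tr.T + quad + quad.T - 2 * n)
    np.fill_diagonal(d, 0.0)
    return np.maximum(d, 0.0)


def _relabel_by_first_appearance(raw: np.ndarray) -> np.ndarray:
    mapping: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def complete_linkage(d: np.ndarray, k: int) -> ClusterAssignment:
    """Agglomerative clustering under the maximum-linkage criterion, cut at
    k clusters.  Complete linkage merges the pair of clusters whose largest
    inter-element distance is smallest, so it depends only on the ordering
    of the distances (invariant to monotone transformations)."""
    d = np.asarray(d, float)
    T = d.shape[0]
    if d.shape != (T, T):
        raise ValueError("distance matrix must be square")
    if not (1 <= k <= T):
        raise ValueError(f"k must be in [1, {T}]")
    if k == T:
        raw = np.arange(T)
    else:
        condensed = squareform(0.5 * (d + d.T), checks=False)
        Z = hierarchy.linkage(condensed, method="complete")
        raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    labels = _relabel_by_first_appearance(np.asarray(raw, int))
    k_used = int(labels.max()) + 1
    if k_used != k:
        # maxclust can return fewer clusters on exactly tied merges
        logger.warning("requested %d clusters, obtained %d", k, k_used)
    return ClusterAssignment(labels=labels, k=k_used)


def suggest_k(T: int) -> int:
    """Heuristic cluster count: ceil(ln T).

    Sub-states are separated by energy barriers crossed with exponentially
    small probability, so the number of states visited by T sequential
    models grows only logarithmically in T.  T=500 gives 7.  Overridable.
    """
    if T < 2:
        raise ValueError("need T >= 2")
    return max(1, math.ceil(math.log(T)))


def _medoid(members: list[int], d: np.ndarray) -> int:
    sub = d[np.ix_(members, members)]
    return members[int(np.argmin(sub.sum(axis=1)))]


def estimate_chain(
    assignment: ClusterAssignment,
    tvm: TimeVaryingModel,
    d: np.ndarray | None = None,
    prior_mode: str = "cluster_size",
) -> MarkovChainModel:
    """Estimate the Markov chain over cluster-states by transition counting.

    ``transition[i, j]`` is the number of times a window in cluster i is
    immediately followed by one in cluster j, normalized per row; the prior
    is the relative cluster size.  A state with no outgoing transitions
    (it appears only at the trajectory end) becomes a self-loop — counting
    gives no information there and a self-loop is the most conservative
    completion.  Representative state models are the symmetric-KL medoids
    of each cluster (``d`` is recomputed if not supplied).
    """
    if prior_mode != "cluster_size":
        raise ValueError(f"unknown prior mode {prior_mode!r}")
    labels = assignment.labels
    if labels.shape[0] != tvm.T:
        raise ValueError("assignment length must equal the number of models")
    k = assignment.k
    counts = np.zeros((k, k))
    for a, b in zip(labels[:-1], labels[1:]):
        counts[a, b] += 1
    transition = np.zeros_like(counts)
    for i in range(k):
        row_sum = counts[i].sum()
        if row_sum == 0:
            logger.warning("state %d has no outgoing transitions; using a self-loop", i)
            transition[i, i] = 1.0
        else:
            transition[i] = counts[i] / row_sum
    prior = np.bincount(labels, minlength=k).astype(float) / labels.shape[0]

    if d is None:
        d = pairwise_symkl(tvm)
    state_models = []
    for i in range(k):
        members = np.flatnonzero(labels == i).tolist()
        state_models.append(tvm.models[_medoid(members, d)])
    return MarkovChainModel(
        prior=prior,
        transition=transition,
        state_models=state_models,
        frames_per_state=tvm.window_spec.width,
    )


def sample_chain_trajectory(
    chain: MarkovChainModel, n_windows: int, seed: int | np.random.Generator
) -> tuple[CovariateMatrix, np.ndarray]:
    """Generate a synthetic trajectory from the chain.

    Draws the initial state from the prior, subsequent states from the
    transition matrix, and ``frames_per_state`` conformations per visited
    state from that state's GGM.  Returns the covariate matrix and the
    state label per window.
    """
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    states = np.empty(n_windows, dtype=int)
    states[0] = rng.choice(chain.k, p=chain.prior)
    for i in range(1, n_windows):
        states[i] = rng.choice(chain.k, p=chain.transition[states[i - 1]])
    blocks = [
        sample_model(chain.state_models[s], chain.frames_per_state, rng)
        for s in states
    ]
    values = np.vstack(blocks)
    labels = chain.state_models[0].labels
    return CovariateMatrix(values=values, labels=labels), states


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Stationary vector of a row-stochastic matrix (left eigenvector of
    eigenvalue 1, normalized to sum 1)."""
    transition = np.asarray(transition, float)
    vals, vecs = np.linalg.eig(transition.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def save_chain(chain: MarkovChainModel, path: str | Path,
               model_paths: list[str] | None = None) -> None:
    """Serialize the chain as JSON; state models inline unless paths given."""
    doc = {
        "prior": chain.prior.tolist(),
        "transition": chain.transition.tolist(),
        "frames_per_state": chain.frames_per_state,
        "labels": list(chain.state_models[0].labels),
        "state_models": model_paths
        if model_paths is not None
        else [
            {"mean": m.mean.tolist(), "precision": m.precision.tolist()}
            for m in chain.state_models
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def load_chain(path: str | Path) -> MarkovChainModel:
    doc = json.loads(Path(path).read_text())
    labels = tuple(doc["labels"])
    models = [
        GaussianGraphicalModel(
            mean=np.asarray(m["mean"], float),
            precision=np.asarray(m["precision"], float),
            labels=labels,
        )
        for m in doc["state_models"]
    ]
    return MarkovChainModel(
        prior=np.asarray(doc["prior"], float),
        transition=np.asarray(doc["transition"], float),
        state_models=models,
        frames_per_state=int(doc["frames_per_state"]),
    )
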