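"""Synthetic data with known ground truth for estimator validation.

Generates covariate matrices from known sparse GGMs and piecewise-stationary
switching trajectories from known Markov chains, plus the recovery metrics
(edge precision/recall/F1, best-permutation transition error) that quantify
how well the estimators get the truth back.  Frames are drawn independently
within windows — the clean regime for validating the estimators; real MD
frames are autocorrelated, which these fixtures deliberately do not model.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .estimate import CovariateMatrix
from .model import GaussianGraphicalModel, edge_list, sample as sample_model

__all__ = [
    "GroundTruth",
    "RecoveryReport",
    "random_sparse_precision",
    "random_ggm",
    "ggm_dataset",
    "switching_trajectory",
    "recovery_report",
]


@dataclass
class GroundTruth:
    """What generated a fixture: the model(s), and for switching fixtures
    the true chain, hidden state sequence and window length.  The recorded
    seed reproduces the fixture bit-for-bit."""

    models: list[GaussianGraphicalModel]
    seed: int
    transition: np.ndarray | None = None
    state_sequence: np.ndarray | None = None
    frames_per_window: int | None = None
    params: dict = field(default_factory=dict)

    def sidecar(self, path: str | Path) -> None:
        """Write provenance (parameters + seed, not the data) as JSON."""
        doc = {
            "seed": self.seed,
            "params": self.params,
            "n_models": len(self.models),
            "transition": None if self.transition is None else self.transition.tolist(),
            "state_sequence": None
            if self.state_sequence is None
            else self.state_sequence.tolist(),
            "frames_per_window": self.frames_per_window,
        }
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


@dataclass
class RecoveryReport:
    """Edge-recovery and (optionally) chain-recovery metrics."""

    edge_precision: float | None = None
    edge_recall: float | None = None
    edge_f1: float | None = None
    state_permutation: tuple[int, ...] | None = None
    transition_max_abs_error: float | None = None


def random_sparse_precision(
    n: int, density: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Random symmetric PD precision with the requested off-diagonal density.

    Support is chosen uniformly among pairs; nonzero couplings are drawn
    uniform in magnitude [0.5, 1.0] with random sign, and the diagonal is
    inflated to strict diagonal dominance, which guarantees positive
    definiteness regardless of the sign pattern.
    """
    if not 0.0 < density <= 1.0:
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pairs = list(itertools.combinations(range(n), 2))
    n_edges = int(round(density * len(pairs)))
    prec = np.zeros((n, n))
    if pairs and n_edges:
        chosen = rng.choice(len(pairs), size=n_edges, replace=False)
        for idx in chosen:
            i, j = pairs[idx]
            w = rng.uniform(0.5, 1.0) * rng.choice([-1.0, 1.0])
            prec[i, j] = prec[j, i] = w
    row_abs = np.abs(prec).sum(axis=1)
    np.fill_diagonal(prec, row_abs + rng.uniform(0.5, 1.0, size=n))
    return prec


def random_ggm(
    n: int, density: float, seed: int | np.random.Generator,
    mean_scale: float = 1.0,
) -> GaussianGraphicalModel:
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    prec = random_sparse_precision(n, density, rng)
    mean = rng.normal(scale=mean_scale, size=n)
    return GaussianGraphicalModel(mean=mean, precision=prec)


def ggm_dataset(
    model: GaussianGraphicalModel, t: int, seed: int
) -> tuple[CovariateMatrix, GroundTruth]:
    """t independent draws from one GGM, with provenance attached."""
    if t < 2:
        raise ValueError("need t >= 2 frames")
    values = sample_model(model, t, seed)
    data = CovariateMatrix(values=values, labels=model.labels)
    truth = GroundTruth(models=[model], seed=seed, params={"t": t, "n": model.n})
    return data, truth


def switching_trajectory(
    models: list[GaussianGraphicalModel],
    transition: np.ndarray,
    windows: int,
    frames_per_window: int,
    seed: int,
    prior: np.ndarray | None = None,
) -> tuple[CovariateMatrix, GroundTruth]:
    """Piecewise-stationary trajectory from a hidden Markov state sequence.

    The hidden sequence is drawn from the chain (uniform initial state
    unless ``prior`` is given); every window's frames are then sampled from
    its state's GGM.  Emulates a molecule hopping between conformational
    sub-states with distinct fluctuation structure.
    """
    transition = np.asarray(transition, float)
    k = len(models)
    if transition.shape != (k, k):
        raise ValueError("transition shape must match number of models")
    if not np.allclose(transition.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("transition must be row-stochastic")
    rng = np.random.default_rng(seed)
    p0 = np.full(k, 1.0 / k) if prior is None else np.asarray(prior, float)
    states = np.empty(windows, dtype=int)
    states[0] = rng.choice(k, p=p0)
    for i in range(1, windows):
        states[i] = rng.choice(k, p=transition[states[i - 1]])
    blocks = [sample_model(models[s], frames_per_window, rng) for s in states]
    data = CovariateMatrix(values=np.vstack(blocks), labels=models[0].labels)
    truth = GroundTruth(
        models=models,
        seed=seed,
        transition=transition,
        state_sequence=states,
        frames_per_window=frames_per_window,
        params={"windows": windows, "frames_per_window": frames_per_window, "k": k},
    )
    return data, truth


def _edge_set(model: GaussianGraphicalModel, threshold: float) -> set[tuple[int, int]]:
    return {(i, j) for i, j, _ in edge_list(model, threshold)}


def recovery_report(
    truth: GroundTruth,
    fitted,
    threshold: float = 1e-8,
) -> RecoveryReport:
    """Score a fitted object against the ground truth.

    For a single GGM: edge precision / recall / F1 of the fitted
    off-diagonal support against the generating support.  For a Markov
    chain: states are matched by the permutation minimizing the transition
    max-abs error (feasible for the small k used here), and that error is
    reported.
    """
    report = RecoveryReport()
    if isinstance(fitted, GaussianGraphicalModel):
        if len(truth.models) != 1:
            raise ValueError("single-model report needs a single-model truth")
        true_model = truth.models[0]
        if fitted.n != true_model.n:
            raise ValueError("dimension mismatch between truth and fit")
        true_edges = _edge_set(true_model, threshold)
        fit_edges = _edge_set(fitted, threshold)
        tp = len(true_edges & fit_edges)
        precision = tp / len(fit_edges) if fit_edges else (1.0 if not true_edges else 0.0)
        recall = tp / len(true_edges) if true_edges else 1.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision + recall > 0
            else 0.0
        )
        report.edge_precision = precision
        report.edge_recall = recall
        report.edge_f1 = f1
        return report

    # Markov chain: best-permutation matching on the transition matrix
    fitted_transition = np.asarray(fitted.transition, float)
    if truth.transition is None:
        raise ValueError("truth carries no transition matrix")
    true_transition = truth.transition
    k = true_transition.shape[0]
    if fitted_transition.shape != (k, k):
        raise ValueError("state-count mismatch between truth and fit")
    best_err = np.inf
    best_perm: tuple[int, ...] = tuple(range(k))
    for perm in itertools.permutations(range(k)):
        p = list(perm)
        err = float(np.max(np.abs(fitted_transition[np.ix_(p, p)] - true_transition)))
        if err < best_err:
            best_err = err
            best_perm = perm
    report.state_permutation = best_perm
    report.transition_max_abs_error = best_err
    return report
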