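"""Independent oracles used to check the closed-form and solver code paths.

Each oracle reaches the quantity under test by a different route than the
implementation: direct-formula evaluation with generic linear algebra,
numerical integration on a grid, Monte-Carlo estimation, or a generic
bound-constrained optimizer applied to the dual problem.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def direct_log_density(mean, cov, x):
    """Gaussian log density via explicit determinant and linear solve."""
    mean = np.asarray(mean, float)
    cov = np.asarray(cov, float)
    x = np.asarray(x, float)
    n = mean.shape[0]
    dev = x - mean
    sign, logdet = np.linalg.slogdet(cov)
    assert sign > 0
    return -0.5 * (n * np.log(2 * np.pi) + logdet + dev @ np.linalg.solve(cov, dev))


def box_logdet_oracle(S, lam, tol=1e-12):
    """Generic convex solve of: maximize log|W| s.t. ||W - S||_inf <= lam.

    Parametrizes the upper triangle of the symmetric W and hands the box
    constraints to L-BFGS-B as variable bounds; non-PD iterates are repelled
    with a smallest-eigenvalue penalty.  Entirely independent of the block
    coordinate descent path.
    """
    S = np.asarray(S, float)
    n = S.shape[0]
    iu = np.triu_indices(n)

    def unpack(x):
        W = np.zeros((n, n))
        W[iu] = x
        return W + W.T - np.diag(np.diag(W))

    def fg(x):
        W = unpack(x)
        vals, vecs = np.linalg.eigh(W)
        if vals.min() <= 1e-10:
            v = vecs[:, 0]
            g = -np.outer(v, v)
            G = np.where(np.eye(n, dtype=bool), g, 2 * g)
            return 1e8 - 1e6 * vals.min(), -1e6 * G[iu]
        P = np.linalg.inv(W)
        G = np.where(np.eye(n, dtype=bool), -P, -2 * P)
        return -float(np.sum(np.log(vals))), G[iu]

    x0 = (S + lam * np.eye(n))[iu]
    bounds = list(zip((S - lam)[iu], (S + lam)[iu]))
    res = minimize(fg, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 5000, "ftol": tol, "gtol": 1e-12})
    return unpack(res.x)


def grid_condition_oracle(mean, cov, v_index, v_value, half_width=8.0, points=401):
    """Conditional mean/covariance of a 3-variable Gaussian by numerical
    normalization of the joint density on a 2-D grid over the free pair."""
    mean = np.asarray(mean, float)
    cov = np.asarray(cov, float)
    assert mean.shape[0] == 3
    free = [i for i in range(3) if i != v_index]
    sd = np.sqrt(np.diag(cov))
    axes = [np.linspace(mean[i] - half_width * sd[i], mean[i] + half_width * sd[i], points)
            for i in free]
    g0, g1 = np.meshgrid(axes[0], axes[1], indexing="ij")
    x = np.empty(g0.shape + (3,))
    x[..., free[0]] = g0
    x[..., free[1]] = g1
    x[..., v_index] = v_value
    dev = x - mean
    prec = np.linalg.inv(cov)
    q = np.einsum("...i,ij,...j->...", dev, prec, dev)
    w = np.exp(-0.5 * (q - q.min()))
    w /= w.sum()
    mu0 = float((w * g0).sum())
    mu1 = float((w * g1).sum())
    c00 = float((w * (g0 - mu0) ** 2).sum())
    c11 = float((w * (g1 - mu1) ** 2).sum())
    c01 = float((w * (g0 - mu0) * (g1 - mu1)).sum())
    return np.array([mu0, mu1]), np.array([[c00, c01], [c01, c11]])


def mc_kl(sampler0, logp0, logp1, count, seed):
    """Monte-Carlo KL(m0 || m1) with its standard error."""
    x = sampler0(count, seed)
    diff = logp0(x) - logp1(x)
    return float(np.mean(diff)), float(np.std(diff, ddof=1) / np.sqrt(count))
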