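"""Sampling machinery shared by the item-level and screen-level fitters.

No probabilistic-programming backend is assumed: the fitters run an
adaptive random-walk Metropolis-within-Gibbs scheme written directly in
numpy.  The discrete attentiveness indicator is marginalized analytically
inside the likelihood (the two-component mixture), so only continuous
parameters are sampled.  This module provides

* per-parameter proposal-scale adaptation (Robbins--Monro during warmup),
* transforms for constrained parameters: the probability simplex
  (multinomial-logit with its Jacobian) and correlation matrices
  (canonical partial correlations with the LKJ density),
* the half-Cauchy log-prior used for scale parameters,
* the split potential-scale-reduction factor (split R-hat).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "AdaptiveScale",
    "half_cauchy_logpdf",
    "simplex_from_z",
    "simplex_logjac",
    "corr_chol_from_y",
    "lkj_cpc_logprior",
    "psrf",
    "split_rhat_all",
]


class AdaptiveScale:
    """Robbins--Monro adaptation of log proposal scales during warmup.

    One instance manages a (possibly vector-valued) family of proposal
    scales; per-element acceptance indicators drive each element's scale
    toward the target acceptance rate.  Adaptation is frozen after warmup,
    keeping the post-warmup chain Markovian.
    """

    def __init__(self, shape=(), init_scale: float = 0.3,
                 target: float = 0.44, warmup: int = 500) -> None:
        self.log_scale = np.full(shape, np.log(init_scale))
        self.target = target
        self.warmup = warmup
        self.t = np.zeros(shape, dtype=int)

    @property
    def scale(self):
        return np.exp(self.log_scale)

    def update(self, accepted) -> None:
        """Adapt every element with its own acceptance indicator."""
        self.t = self.t + 1
        active = self.t <= self.warmup
        step = 1.0 / (self.t + 10.0) ** 0.6
        delta = step * (np.asarray(accepted, dtype=float) - self.target)
        self.log_scale = self.log_scale + np.where(active, delta, 0.0)
        self.log_scale = np.clip(self.log_scale, -10.0, 4.0)

    def update_at(self, k: int, accepted: bool) -> None:
        """Adapt a single element of a vector-valued scale family."""
        self.t[k] += 1
        if self.t[k] > self.warmup:
            return
        step = 1.0 / (self.t[k] + 10.0) ** 0.6
        self.log_scale[k] = np.clip(
            self.log_scale[k] + step * (float(accepted) - self.target), -10.0, 4.0
        )


def half_cauchy_logpdf(x, scale: float = 5.0):
    """Log-density of the half-Cauchy(0, scale) distribution for x > 0."""
    x = np.asarray(x, dtype=float)
    out = np.where(
        x > 0,
        np.log(2.0 / (np.pi * scale)) - np.log1p((x / scale) ** 2),
        -np.inf,
    )
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Simplex transform (kappa)
# ---------------------------------------------------------------------------


def simplex_from_z(z: np.ndarray) -> np.ndarray:
    """Map unconstrained z (length K) to a K+1 simplex via softmax([0, z])."""
    full = np.concatenate([[0.0], np.asarray(z, dtype=float)])
    full -= full.max()
    e = np.exp(full)
    return e / e.sum()


def simplex_logjac(kappa: np.ndarray) -> float:
    """Log |Jacobian| of the multinomial-logit transform at ``kappa``.

    Combined with a Dirichlet(1) prior (constant on the simplex) this is the
    whole log-prior contribution of the unconstrained coordinates.
    """
    return float(np.sum(np.log(kappa)))


# ---------------------------------------------------------------------------
# Correlation-matrix transform (Omega) via canonical partial correlations
# ---------------------------------------------------------------------------


def corr_chol_from_y(y: np.ndarray, d: int) -> np.ndarray:
    """Cholesky factor of a correlation matrix from unconstrained y.

    ``y`` has length d(d-1)/2; canonical partial correlations are
    ``tanh(y)`` filled row-wise into the lower triangle, and the Cholesky
    factor is built with the standard recursive construction, guaranteeing
    a valid (unit-diagonal, positive-definite) correlation matrix for any
    real ``y``.
    """
    z = np.tanh(y)
    L = np.zeros((d, d))
    L[0, 0] = 1.0
    idx = 0
    for i in range(1, d):
        rem = 1.0
        for j in range(i):
            L[i, j] = z[idx] * np.sqrt(rem)
            rem -= L[i, j] ** 2
            idx += 1
        L[i, i] = np.sqrt(max(rem, 1e-300))
    return L


def lkj_cpc_logprior(y: np.ndarray, d: int, eta: float = 1.0) -> float:
    """Log-density of unconstrained y such that Omega ~ LKJ(eta).

    Under the canonical-partial-correlation construction the cpcs are
    independent with density proportional to ``(1 - z^2)^(beta_i - 1)`` where
    ``beta_i = eta + (d - 1 - i) / 2`` for the cpc in row ``i`` (1-based
    second index), and the tanh transform contributes ``log(1 - z^2)`` per
    coordinate.
    """
    z = np.tanh(y)
    log1mz2 = np.log1p(-z * z)
    lp = 0.0
    idx = 0
    for i in range(1, d):
        beta = eta + (d - 1 - i) / 2.0
        for _ in range(i):
            lp += beta * log1mz2[idx]  # (beta-1)*log(1-z^2) + jacobian log(1-z^2)
            idx += 1
    return float(lp)


# ---------------------------------------------------------------------------
# Convergence diagnostics
# ---------------------------------------------------------------------------


def psrf(chains_of_draws) -> float:
    """Split potential scale reduction factor (split R-hat).

    Parameters
    ----------
    chains_of_draws
        Array-like of shape (m, n): m >= 2 chains of equal length n.  Each
        chain is split in half, and the classical Gelman--Rubin statistic is
        computed on the 2m half-chains.
    """
    draws = np.asarray(chains_of_draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2:
        raise ValueError("psrf requires >= 2 chains of equal length")
    if np.all(draws == draws[0]):
        return 1.0  # duplicated chains carry no between-chain information
    m, n = draws.shape
    half = n // 2
    if half < 2:
        raise ValueError("chains too short to split")
    split = np.concatenate([draws[:, :half], draws[:, half: 2 * half]], axis=0)
    m2, n2 = split.shape
    chain_means = split.mean(axis=1)
    chain_vars = split.var(axis=1, ddof=1)
    W = chain_vars.mean()
    B = n2 * chain_means.var(ddof=1)
    if W == 0:
        return 1.0  # identical constant chains
    var_plus = (n2 - 1) / n2 * W + B / n2
    return float(np.sqrt(var_plus / W))


def split_rhat_all(draws: dict) -> dict:
    """Split R-hat for every scalar component of a dict of draw arrays.

    Each value has shape (chains, n, ...); the statistic is computed along
    the first two axes for every trailing index, returned as flat arrays.
    """
    out = {}
    for name, arr in draws.items():
        arr = np.asarray(arr, dtype=float)
        flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
        vals = np.array([psrf(flat[:, :, k]) for k in range(flat.shape[2])])
        out[name] = vals
    return out
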