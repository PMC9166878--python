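"""Bayesian estimation of the item-level careless-responding mixture model.

The sampler is an adaptive random-walk Metropolis-within-Gibbs scheme over
the continuous parameters, with the discrete per-(person, screen)
attentiveness indicator marginalized analytically: every person-screen
contributes ``log[p1 * A + (1 - p1) * C]`` where ``A`` and ``C`` are the
attentive (GPCM response x distance--difficulty lognormal RT) and careless
(``kappa`` x shared lognormal RT) factors and ``p1 = logistic(psi - iota)``.
Posterior attentiveness probabilities are recovered per retained draw from
the mixture responsibilities.

Identification follows the standard constraints: person-parameter means are
zero and trait variances are one; the covariance is parameterized as
``diag(sigma_psi, sigma_tau, 1, .., 1) * Omega * diag(...)`` with an LKJ(1)
prior on the correlation matrix ``Omega``.  Scale parameters and item
discriminations carry half-Cauchy(0, 5) priors; step difficulties, the
non-negative time-intensity offsets ``beta*``, ``gamma``, ``beta_C`` and the
screen attentiveness difficulties ``iota`` carry diffuse normal(0, 10)
priors; ``kappa`` is Dirichlet(1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import log_expit
from scipy.stats import norm

from ._mcmc import (
    AdaptiveScale,
    corr_chol_from_y,
    half_cauchy_logpdf,
    lkj_cpc_logprior,
    psrf,
    simplex_from_z,
    simplex_logjac,
    split_rhat_all,
)
from .simulator import ResponseDataset

__all__ = [
    "PriorConfig",
    "McmcConfig",
    "PosteriorResult",
    "fit_item_model",
    "classify_attentiveness",
    "cier_rate",
    "psrf",
]


@dataclass
class PriorConfig:
    """Prior settings; defaults are the diffuse choices used throughout."""

    lkj_shape: float = 1.0
    half_cauchy_scale: float = 5.0
    normal_sd: float = 10.0
    dirichlet_kappa: float = 1.0  # symmetric concentration

    def __post_init__(self) -> None:
        if min(self.half_cauchy_scale, self.normal_sd, self.dirichlet_kappa) <= 0:
            raise ValueError("prior scales must be positive")


@dataclass
class McmcConfig:
    """Chain settings.  ``warmup`` defaults to half the iterations."""

    chains: int = 4
    iterations: int = 4000
    warmup: int | None = None
    seed: int = 0
    psrf_threshold: float = 1.10
    init_jitter: float = 0.5
    progress: bool = False

    def __post_init__(self) -> None:
        if self.warmup is None:
            self.warmup = self.iterations // 2
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for PSRF")
        if not 0 < self.warmup < self.iterations:
            raise ValueError("warmup must lie strictly between 0 and iterations")


@dataclass
class PosteriorResult:
    """Posterior draws, summaries, diagnostics and attentiveness classification."""

    draws: dict  # name -> array (chains, n_retained, ...)
    summaries: pd.DataFrame  # index: parameter, columns: median, q2.5, q97.5
    psrf: pd.Series  # per scalar parameter component
    p_cier: np.ndarray  # posterior P(delta = 0); (N, S) item model, (N,) screen model
    rates: dict  # overall / per-screen careless rates
    converged: bool
    max_psrf: float
    person_ids: list
    screen_ids: list
    meta: dict = field(default_factory=dict)

    def flag_nonconverged(self) -> pd.Series:
        return self.psrf[self.psrf >= self.meta.get("psrf_threshold", 1.10)]


# ---------------------------------------------------------------------------
# Data preparation
# ---------------------------------------------------------------------------


class _ItemData:
    """Dense arrays for the sampler, built from a long-format dataset."""

    def __init__(self, dataset: ResponseDataset):
        df = dataset.df
        self.person_ids = list(pd.unique(df["person_id"]))
        self.item_ids = [it.item_id for it in dataset.items]
        self.screen_ids = [sc.screen_id for sc in dataset.screens]
        Ks = {it.K for it in dataset.items}
        if len(Ks) != 1:
            raise ValueError(f"items disagree on the number of categories: {Ks}")
        self.K = Ks.pop()
        self.N = len(self.person_ids)
        self.J = len(self.item_ids)
        self.S = len(self.screen_ids)
        item_pos = {iid: k for k, iid in enumerate(self.item_ids)}
        screen_pos = {sid: k for k, sid in enumerate(self.screen_ids)}
        self.screen_of_item = np.array(
            [screen_pos[it.screen_id] for it in dataset.items]
        )
        self.items_of_screen = [
            np.flatnonzero(self.screen_of_item == s) for s in range(self.S)
        ]
        self.trait_of_screen = np.array([sc.trait_index for sc in dataset.screens])

        person_pos = {pid: k for k, pid in enumerate(self.person_ids)}
        self.X = np.full((self.N, self.J), -1, dtype=int)
        self.T = np.full((self.N, self.J), np.nan)
        rows = df["person_id"].map(person_pos).to_numpy()
        cols = df["item_id"].map(item_pos).to_numpy()
        x = df["x"].to_numpy(dtype=float)
        t = df["t"].to_numpy(dtype=float)
        obs_x = ~np.isnan(x)
        if obs_x.any():
            bad = (x[obs_x] < 0) | (x[obs_x] > self.K) | (x[obs_x] % 1 != 0)
            if bad.any():
                raise ValueError("responses outside 0..K present")
        obs_t = ~np.isnan(t)
        if obs_t.any() and np.any(t[obs_t] <= 0):
            raise ValueError("non-positive response times present")
        self.X[rows[obs_x], cols[obs_x]] = x[obs_x].astype(int)
        self.T[rows[obs_t], cols[obs_t]] = t[obs_t]
        self.MX = self.X >= 0  # observed-response mask
        self.MT = ~np.isnan(self.T)  # observed-RT mask
        self.logT = np.where(self.MT, np.log(np.where(self.MT, self.T, 1.0)), 0.0)
        self.Xc = np.where(self.MX, self.X, 0)  # clipped for safe indexing


def _middle_of_b(b: np.ndarray) -> np.ndarray:
    """Middle step difficulty per item for a (J, K) step matrix."""
    K = b.shape[1]
    if K % 2 == 1:
        return b[:, K // 2]
    return 0.5 * (b[:, K // 2 - 1] + b[:, K // 2])


def _gpcm_logp_obs(eta: np.ndarray, v: np.ndarray, b: np.ndarray,
                   Xc: np.ndarray, MX: np.ndarray) -> np.ndarray:
    """Log GPCM probability of the observed responses.

    eta: (N, J) trait value per cell; v: (J,); b: (J, K); returns (N, J)
    with zeros at missing cells.
    """
    steps = v[None, :, None] * eta[..., None] - b[None, :, :]  # (N, J, K)
    cum = np.concatenate(
        [np.zeros(steps.shape[:-1] + (1,)), np.cumsum(steps, axis=-1)], axis=-1
    )
    m = cum.max(axis=-1, keepdims=True)
    logZ = m[..., 0] + np.log(np.exp(cum - m).sum(axis=-1))
    logp = np.take_along_axis(cum, Xc[..., None], axis=-1)[..., 0] - logZ
    return np.where(MX, logp, 0.0)


_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def _lognorm_logpdf_obs(logT: np.ndarray, MT: np.ndarray, mu: np.ndarray,
                        sigma: float) -> np.ndarray:
    """Lognormal log-density at observed RTs (zeros at missing cells)."""
    z = (logT - mu) / sigma
    out = -0.5 * z * z - np.log(sigma) - _LOG_SQRT_2PI - logT
    return np.where(MT, out, 0.0)


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------


class _ItemSampler:
    """One chain of the item-level model."""

    def __init__(self, data: _ItemData, priors: PriorConfig, mcmc: McmcConfig,
                 rng: np.random.Generator):
        self.d = data
        self.pr = priors
        self.rng = rng
        self.D = 2 + data.S  # psi, tau, eta_1..eta_S
        self.warmup = mcmc.warmup
        self._init_state(mcmc.init_jitter)
        self._init_adapt()
        self.refresh_all()

    # -- initialization ----------------------------------------------------

    def _init_state(self, jitter: float) -> None:
        d, rng = self.d, self.rng
        # data-driven centers + chain-specific jitter for honest R-hat
        logt_person = np.where(d.MT, d.logT, np.nan)
        person_mean = np.nanmean(logt_person, axis=1)
        person_mean = np.where(np.isfinite(person_mean), person_mean,
                               np.nanmean(logt_person))
        tau0 = np.nanmean(person_mean) - person_mean
        self.P = np.zeros((d.N, self.D))
        self.P[:, 0] = rng.normal(0, max(jitter, 0.1), d.N)  # psi
        self.P[:, 1] = tau0 + rng.normal(0, 0.3 * jitter + 0.05, d.N)
        for s in range(d.S):
            idx = d.items_of_screen[s]
            score = np.where(d.MX[:, idx], d.X[:, idx], np.nan).mean(axis=1)
            score = np.where(np.isfinite(score), score, np.nanmean(score))
            sd = np.nanstd(score)
            eta0 = (score - np.nanmean(score)) / (sd if sd > 0 else 1.0)
            self.P[:, 2 + s] = eta0 + rng.normal(0, 0.3 * jitter + 0.05, d.N)
        self.logv = rng.normal(0.0, 0.2 * jitter, d.J)
        base_b = np.linspace(-0.8, 0.8, d.K)
        self.b = base_b[None, :] + rng.normal(0, 0.3 * jitter, (d.J, d.K))
        self.bstar = np.abs(rng.normal(0.3, 0.15 * jitter + 0.02, d.J))
        self.iota = rng.normal(-2.5, 0.5 * jitter, d.S)
        self.gamma = rng.normal(0.02, 0.05 * jitter)
        all_logt = d.logT[d.MT]
        self.beta_C = float(np.quantile(all_logt, 0.1)) + rng.normal(0, 0.3 * jitter)
        self.lsA = np.log(0.6) + rng.normal(0, 0.2 * jitter)
        self.lsC = np.log(0.9) + rng.normal(0, 0.2 * jitter)
        self.zk = rng.normal(0, 0.3 * jitter, d.K)
        self.y = rng.normal(0, 0.2 * jitter, self.D * (self.D - 1) // 2)
        self.lspsi = np.log(1.2) + rng.normal(0, 0.3 * jitter)
        self.lstau = np.log(0.4) + rng.normal(0, 0.3 * jitter)

    def _init_adapt(self) -> None:
        d, w = self.d, self.warmup
        self.ad_P = [AdaptiveScale((d.N,), 0.5, 0.44, w) for _ in range(self.D)]
        self.ad_logv = AdaptiveScale((d.J,), 0.1, 0.44, w)
        self.ad_b = AdaptiveScale((d.J,), 0.1, 0.28, w)
        self.ad_bstar = AdaptiveScale((d.J,), 0.1, 0.44, w)
        self.ad_iota = AdaptiveScale((d.S,), 0.3, 0.44, w)
        self.ad_scalars = {
            name: AdaptiveScale((), 0.05, 0.44, w)
            for name in ("gamma", "beta_C", "lsA", "lsC", "lspsi", "lstau")
        }
        self.ad_zk = AdaptiveScale((), 0.1, 0.28, w)
        self.ad_zk_coord = AdaptiveScale((d.K,), 0.2, 0.44, w)
        self.ad_y = AdaptiveScale((self.D * (self.D - 1) // 2,), 0.2, 0.44, w)
        self.ad_coupled = {
            name: AdaptiveScale((), 0.1, 0.44, w)
            for name in ("lspsi", "lstau", "betaC_tau", "betaC_bstar")
        }
        self.ad_psi_scale = AdaptiveScale((), 0.6, 0.44, w)
        self.ad_psi_corr = AdaptiveScale((), 0.3, 0.28, w)
        self._psi_block_turn = 0

    # -- state-dependent quantities ----------------------------------------

    @property
    def sigma_A(self) -> float:
        return float(np.exp(self.lsA))

    @property
    def sigma_C(self) -> float:
        return float(np.exp(self.lsC))

    @property
    def kappa(self) -> np.ndarray:
        return simplex_from_z(self.zk)

    def _omega_from_y(self, y) -> np.ndarray:
        """Correlation matrix in (psi, tau, eta..) order from cpcs.

        The cpcs parameterize the *permuted* order (tau, eta_1.., eta_S,
        psi): with psi last, the cpcs that involve psi (the final D-1
        entries of y) leave the (tau, eta) block untouched, which lets the
        psi-hierarchy moves travel without disturbing the data-rich
        correlations.
        """
        L = corr_chol_from_y(y, self.D)
        Om_perm = L @ L.T
        perm = np.r_[np.arange(1, self.D), 0]  # original index at each perm slot
        inv = np.argsort(perm)
        return Om_perm[np.ix_(inv, inv)]

    def sigma_chol(self, y=None, lspsi=None, lstau=None) -> np.ndarray:
        """Cholesky factor of the person covariance diag(s) Omega diag(s)."""
        y = self.y if y is None else y
        lspsi = self.lspsi if lspsi is None else lspsi
        lstau = self.lstau if lstau is None else lstau
        Om = self._omega_from_y(y)
        sd = np.ones(self.D)
        sd[0] = np.exp(lspsi)
        sd[1] = np.exp(lstau)
        return np.linalg.cholesky(sd[:, None] * Om * sd[None, :])

    def person_logprior(self, P=None, L=None) -> np.ndarray:
        """Per-person MVN(0, Sigma) log-density (N,)."""
        P = self.P if P is None else P
        L = self.sigma_chol() if L is None else L
        from scipy.linalg import solve_triangular

        z = solve_triangular(L, P.T, lower=True)
        logdet = np.sum(np.log(np.diag(L)))
        return -0.5 * np.sum(z * z, axis=0) - logdet - self.D * _LOG_SQRT_2PI

    # -- cache construction --------------------------------------------------

    def eta_cells(self, P=None) -> np.ndarray:
        """Trait value per (person, item) cell: (N, J)."""
        P = self.P if P is None else P
        trait_cols = 2 + self.d.trait_of_screen[self.d.screen_of_item]
        return P[:, trait_cols]

    def att_t_logp(self, P=None, logv=None, b=None, bstar=None, gamma=None,
                   beta_C=None, sigma_A=None, cols=None) -> np.ndarray:
        """Attentive lognormal RT log-density per cell (optionally a column subset)."""
        d = self.d
        P = self.P if P is None else P
        v = np.exp(self.logv if logv is None else logv)
        b = self.b if b is None else b
        bstar = self.bstar if bstar is None else bstar
        gamma = self.gamma if gamma is None else gamma
        beta_C = self.beta_C if beta_C is None else beta_C
        sigma_A = self.sigma_A if sigma_A is None else sigma_A
        o = _middle_of_b(b)
        eta = self.eta_cells(P)
        if cols is not None:
            v, b, bstar, o = v[cols], b[cols], bstar[cols], o[cols]
            eta = eta[:, cols]
            logT, MT = d.logT[:, cols], d.MT[:, cols]
        else:
            logT, MT = d.logT, d.MT
        dist = np.abs(v[None, :] * eta - o[None, :])
        mu = (beta_C + bstar)[None, :] - P[:, 1][:, None] - gamma * dist
        return _lognorm_logpdf_obs(logT, MT, mu, sigma_A)

    def att_x_logp(self, P=None, logv=None, b=None, cols=None) -> np.ndarray:
        d = self.d
        P = self.P if P is None else P
        v = np.exp(self.logv if logv is None else logv)
        b = self.b if b is None else b
        eta = self.eta_cells(P)
        if cols is not None:
            v, b = v[cols], b[cols]
            eta = eta[:, cols]
            Xc, MX = d.Xc[:, cols], d.MX[:, cols]
        else:
            Xc, MX = d.Xc, d.MX
        return _gpcm_logp_obs(eta, v, b, Xc, MX)

    def cier_t_logp(self, beta_C=None, sigma_C=None) -> np.ndarray:
        d = self.d
        beta_C = self.beta_C if beta_C is None else beta_C
        sigma_C = self.sigma_C if sigma_C is None else sigma_C
        return _lognorm_logpdf_obs(d.logT, d.MT, beta_C, sigma_C)

    def cier_x_logp(self, kappa=None) -> np.ndarray:
        d = self.d
        kappa = self.kappa if kappa is None else kappa
        return np.where(d.MX, np.log(kappa)[d.Xc], 0.0)

    def screen_sums(self, cell: np.ndarray) -> np.ndarray:
        """(N, J) cell values summed into (N, S) screen blocks."""
        out = np.empty((self.d.N, self.d.S))
        for s, idx in enumerate(self.d.items_of_screen):
            out[:, s] = cell[:, idx].sum(axis=1)
        return out

    def mix_from(self, lp1, lp0, A, C) -> np.ndarray:
        return np.logaddexp(lp1 + A, lp0 + C)

    def refresh_all(self) -> None:
        self.ax = self.att_x_logp()
        self.at = self.att_t_logp()
        self.cx = self.cier_x_logp()
        self.ct = self.cier_t_logp()
        self.A = self.screen_sums(self.ax + self.at)
        self.C = self.screen_sums(self.cx + self.ct)
        dlin = self.P[:, [0]] - self.iota[None, :]
        self.lp1 = log_expit(dlin)
        self.lp0 = log_expit(-dlin)
        self.mix = self.mix_from(self.lp1, self.lp0, self.A, self.C)

    # -- updates -------------------------------------------------------------

    def update_persons(self) -> None:
        d, rng = self.d, self.rng
        L = self.sigma_chol()
        for c in range(self.D):
            ad = self.ad_P[c]
            prop = self.P[:, c] + ad.scale * rng.standard_normal(d.N)
            Pc = self.P.copy()
            Pc[:, c] = prop
            if c == 0:
                dlin = prop[:, None] - self.iota[None, :]
                lp1n, lp0n = log_expit(dlin), log_expit(-dlin)
                mixn = self.mix_from(lp1n, lp0n, self.A, self.C)
                axn = atn = An = None
            elif c == 1:
                atn = self.att_t_logp(P=Pc)
                An = self.screen_sums(self.ax + atn)
                mixn = self.mix_from(self.lp1, self.lp0, An, self.C)
                axn, lp1n, lp0n = None, None, None
            else:
                s = int(np.flatnonzero(self.d.trait_of_screen == c - 2)[0])
                idx = d.items_of_screen[s]
                axn_c = self.att_x_logp(P=Pc, cols=idx)
                atn_c = self.att_t_logp(P=Pc, cols=idx)
                An = self.A.copy()
                An[:, s] = (axn_c + atn_c).sum(axis=1)
                mixn = self.mix.copy()
                mixn[:, s] = np.logaddexp(self.lp1[:, s] + An[:, s],
                                          self.lp0[:, s] + self.C[:, s])
            dll = (mixn - self.mix).sum(axis=1)
            dpr = self.person_logprior(Pc, L) - self.person_logprior(self.P, L)
            acc = np.log(rng.random(d.N)) < dll + dpr
            ad.update(acc)
            if not acc.any():
                continue
            self.P[acc, c] = prop[acc]
            self.mix[acc] = mixn[acc]
            if c == 0:
                self.lp1[acc] = lp1n[acc]
                self.lp0[acc] = lp0n[acc]
            elif c == 1:
                self.at[acc] = atn[acc]
                self.A[acc] = An[acc]
            else:
                rows = np.flatnonzero(acc)
                self.ax[np.ix_(rows, idx)] = axn_c[acc]
                self.at[np.ix_(rows, idx)] = atn_c[acc]
                self.A[acc, s] = An[acc, s]

    def _item_col_delta(self, j: int, axn_j, atn_j):
        """Candidate screen/mix columns when item j's cell columns change."""
        s = self.d.screen_of_item[j]
        A_s = self.A[:, s] + (axn_j + atn_j) - (self.ax[:, j] + self.at[:, j])
        mix_s = np.logaddexp(self.lp1[:, s] + A_s, self.lp0[:, s] + self.C[:, s])
        dll = float((mix_s - self.mix[:, s]).sum())
        return s, A_s, mix_s, dll

    def _accept_item(self, j, s, A_s, mix_s, axn_j, atn_j) -> None:
        self.A[:, s] = A_s
        self.mix[:, s] = mix_s
        self.ax[:, j] = axn_j
        self.at[:, j] = atn_j

    def update_items(self) -> None:
        """One sweep over all item parameters.

        Candidate likelihood columns are precomputed in a handful of
        vectorized full-matrix calls (columns are independent given the
        person parameters); the accept/reject loop itself then only touches
        cheap per-column sums, updating the shared screen caches
        sequentially so within-screen coupling through the mixture is
        respected.
        """
        d, rng, sd = self.d, self.rng, self.pr.normal_sd
        hc = self.pr.half_cauchy_scale
        # --- discriminations -------------------------------------------------
        prop = self.logv + self.ad_logv.scale * rng.standard_normal(d.J)
        ax_all = self.att_x_logp(logv=prop)
        at_all = self.att_t_logp(logv=prop)
        dpr_all = (half_cauchy_logpdf(np.exp(prop), hc) + prop
                   - half_cauchy_logpdf(np.exp(self.logv), hc) - self.logv)
        for j in range(d.J):
            s, A_s, mix_s, dll = self._item_col_delta(j, ax_all[:, j], at_all[:, j])
            acc = np.log(rng.random()) < dll + float(dpr_all[j])
            self.ad_logv.update_at(j, acc)
            if acc:
                self.logv[j] = prop[j]
                self._accept_item(j, s, A_s, mix_s, ax_all[:, j], at_all[:, j])
        # --- step difficulties (joint K-vector per item) ----------------------
        bprop = self.b + self.ad_b.scale[:, None] * rng.standard_normal((d.J, d.K))
        ax_all = self.att_x_logp(b=bprop)
        at_all = self.att_t_logp(b=bprop)
        dpr_all = (norm.logpdf(bprop, 0, sd).sum(axis=1)
                   - norm.logpdf(self.b, 0, sd).sum(axis=1))
        for j in range(d.J):
            s, A_s, mix_s, dll = self._item_col_delta(j, ax_all[:, j], at_all[:, j])
            acc = np.log(rng.random()) < dll + float(dpr_all[j])
            self.ad_b.update_at(j, acc)
            if acc:
                self.b[j] = bprop[j]
                self._accept_item(j, s, A_s, mix_s, ax_all[:, j], at_all[:, j])
        # --- time-intensity offsets (>= 0; negatives have zero prior mass) ----
        bsprop = self.bstar + self.ad_bstar.scale * rng.standard_normal(d.J)
        at_all = self.att_t_logp(bstar=bsprop)
        dpr_all = norm.logpdf(bsprop, 0, sd) - norm.logpdf(self.bstar, 0, sd)
        for j in range(d.J):
            if bsprop[j] < 0:
                self.ad_bstar.update_at(j, False)
                continue
            s, A_s, mix_s, dll = self._item_col_delta(j, self.ax[:, j], at_all[:, j])
            acc = np.log(rng.random()) < dll + float(dpr_all[j])
            self.ad_bstar.update_at(j, acc)
            if acc:
                self.bstar[j] = bsprop[j]
                self._accept_item(j, s, A_s, mix_s, self.ax[:, j], at_all[:, j])

    def update_iota(self) -> None:
        rng, sd = self.rng, self.pr.normal_sd
        for s in range(self.d.S):
            prop = self.iota[s] + self.ad_iota.scale[s] * rng.standard_normal()
            dlin = self.P[:, 0] - prop
            lp1n, lp0n = log_expit(dlin), log_expit(-dlin)
            mix_s = np.logaddexp(lp1n + self.A[:, s], lp0n + self.C[:, s])
            dll = float((mix_s - self.mix[:, s]).sum())
            dpr = float(norm.logpdf(prop, 0, sd) - norm.logpdf(self.iota[s], 0, sd))
            acc = np.log(rng.random()) < dll + dpr
            self.ad_iota.update_at(s, acc)
            if acc:
                self.iota[s] = prop
                self.lp1[:, s] = lp1n
                self.lp0[:, s] = lp0n
                self.mix[:, s] = mix_s

    def _try_global(self, name: str, prop_val: float, dpr: float,
                    new_at=None, new_ct=None, new_cx=None) -> bool:
        """Generic accept/reject for a global parameter affecting the caches."""
        A = self.screen_sums(self.ax + new_at) if new_at is not None else self.A
        if new_ct is not None or new_cx is not None:
            ct = new_ct if new_ct is not None else self.ct
            cx = new_cx if new_cx is not None else self.cx
            C = self.screen_sums(cx + ct)
        else:
            C = self.C
        mixn = self.mix_from(self.lp1, self.lp0, A, C)
        dll = float((mixn - self.mix).sum())
        if np.log(self.rng.random()) < dll + dpr:
            setattr(self, name, prop_val)
            if new_at is not None:
                self.at, self.A = new_at, A
            if new_ct is not None:
                self.ct = new_ct
            if new_cx is not None:
                self.cx = new_cx
            if new_ct is not None or new_cx is not None:
                self.C = C
            self.mix = mixn
            return True
        return False

    def update_globals(self) -> None:
        rng, sd, hc = self.rng, self.pr.normal_sd, self.pr.half_cauchy_scale
        # gamma
        prop = self.gamma + self.ad_scalars["gamma"].scale * rng.standard_normal()
        atn = self.att_t_logp(gamma=prop)
        dpr = float(norm.logpdf(prop, 0, sd) - norm.logpdf(self.gamma, 0, sd))
        self.ad_scalars["gamma"].update(
            self._try_global("gamma", prop, dpr, new_at=atn))
        # beta_C (enters attentive means via beta_C + beta* and the careless RT law)
        prop = self.beta_C + self.ad_scalars["beta_C"].scale * rng.standard_normal()
        atn = self.att_t_logp(beta_C=prop)
        ctn = self.cier_t_logp(beta_C=prop)
        dpr = float(norm.logpdf(prop, 0, sd) - norm.logpdf(self.beta_C, 0, sd))
        self.ad_scalars["beta_C"].update(
            self._try_global("beta_C", prop, dpr, new_at=atn, new_ct=ctn))
        # sigma_A (log scale)
        prop = self.lsA + self.ad_scalars["lsA"].scale * rng.standard_normal()
        atn = self.att_t_logp(sigma_A=float(np.exp(prop)))
        dpr = float(half_cauchy_logpdf(np.exp(prop), hc) + prop
                    - half_cauchy_logpdf(self.sigma_A, hc) - self.lsA)
        self.ad_scalars["lsA"].update(self._try_global("lsA", prop, dpr, new_at=atn))
        # sigma_C (log scale)
        prop = self.lsC + self.ad_scalars["lsC"].scale * rng.standard_normal()
        ctn = self.cier_t_logp(sigma_C=float(np.exp(prop)))
        dpr = float(half_cauchy_logpdf(np.exp(prop), hc) + prop
                    - half_cauchy_logpdf(self.sigma_C, hc) - self.lsC)
        self.ad_scalars["lsC"].update(self._try_global("lsC", prop, dpr, new_ct=ctn))
        self.update_kappa()

    def update_kappa(self) -> None:
        """Joint + per-coordinate moves on the careless category simplex."""
        a0 = self.pr.dirichlet_kappa

        def try_z(zprop, adapt):
            kprop = simplex_from_z(zprop)
            dpr = float(
                (a0 - 1) * (np.sum(np.log(kprop)) - np.sum(np.log(self.kappa)))
                + simplex_logjac(kprop) - simplex_logjac(self.kappa))
            cxn = self.cier_x_logp(kappa=kprop)
            adapt(self._try_global("zk", zprop, dpr, new_cx=cxn))

        zprop = self.zk + self.ad_zk.scale * self.rng.standard_normal(self.d.K)
        try_z(zprop, self.ad_zk.update)
        for k in range(self.d.K):
            zprop = self.zk.copy()
            zprop[k] += self.ad_zk_coord.scale[k] * self.rng.standard_normal()
            try_z(zprop, lambda acc, k=k: self.ad_zk_coord.update_at(k, acc))

    def update_covariance(self, rounds: int = 4) -> None:
        """Omega (LKJ via cpcs) and the psi/tau scale parameters.

        These conditionals touch only the cheap person prior, so several
        rounds per iteration buy mixing of the hierarchy almost for free.
        """
        for _ in range(rounds):
            self._covariance_round()
        self._scale_coupled("lspsi")
        self._scale_coupled("lstau")

    def _covariance_round(self) -> None:
        rng, hc, eta_lkj = self.rng, self.pr.half_cauchy_scale, self.pr.lkj_shape
        lp_cur = float(self.person_logprior().sum())
        # cpcs one at a time: the weakly identified psi-correlations need
        # far larger steps than the data-rich trait correlations
        for k in range(self.y.size):
            yprop = self.y.copy()
            yprop[k] += self.ad_y.scale[k] * rng.standard_normal()
            Lp = self.sigma_chol(y=yprop)
            lp_new = float(self.person_logprior(L=Lp).sum())
            dpr = (lkj_cpc_logprior(yprop, self.D, eta_lkj)
                   - lkj_cpc_logprior(self.y, self.D, eta_lkj))
            acc = np.log(rng.random()) < lp_new - lp_cur + dpr
            self.ad_y.update_at(k, acc)
            if acc:
                self.y = yprop
                lp_cur = lp_new
        # sigma_psi, sigma_tau
        for name in ("lspsi", "lstau"):
            cur = getattr(self, name)
            prop = cur + self.ad_scalars[name].scale * rng.standard_normal()
            Lp = self.sigma_chol(**{name: prop})
            lp_new = float(self.person_logprior(L=Lp).sum())
            dpr = (half_cauchy_logpdf(np.exp(prop), hc) + prop
                   - half_cauchy_logpdf(np.exp(cur), hc) - cur)
            acc = np.log(rng.random()) < lp_new - lp_cur + dpr
            self.ad_scalars[name].update(acc)
            if acc:
                setattr(self, name, prop)
                lp_cur = lp_new

    def _scale_coupled(self, name: str) -> None:
        """Joint rescale of a person column together with its SD parameter.

        Proposes ``lspsi' = lspsi + eps`` with ``psi_i' = psi_i * exp(eps)``
        (analogously for tau).  The standardized person residuals are
        invariant under the coupled move, so the MVN-prior change cancels the
        transformation Jacobian exactly; only the likelihood and the
        half-Cauchy prior (with the log-scale Jacobian) enter the ratio.
        This breaks the funnel between weakly identified latents and their
        scale, which plain componentwise updates traverse very slowly.
        """
        rng, hc = self.rng, self.pr.half_cauchy_scale
        ad = self.ad_coupled[name]
        eps = float(ad.scale) * rng.standard_normal()
        cur = getattr(self, name)
        prop = cur + eps
        col = 0 if name == "lspsi" else 1
        Pc = self.P.copy()
        Pc[:, col] = self.P[:, col] * np.exp(eps)
        dpr = (half_cauchy_logpdf(np.exp(prop), hc) + prop
               - half_cauchy_logpdf(np.exp(cur), hc) - cur)
        if col == 0:
            dlin = Pc[:, [0]] - self.iota[None, :]
            lp1n, lp0n = log_expit(dlin), log_expit(-dlin)
            mixn = self.mix_from(lp1n, lp0n, self.A, self.C)
            dll = float((mixn - self.mix).sum())
            acc = np.log(rng.random()) < dll + dpr
            ad.update(acc)
            if acc:
                self.P, self.lspsi = Pc, prop
                self.lp1, self.lp0, self.mix = lp1n, lp0n, mixn
        else:
            atn = self.att_t_logp(P=Pc)
            An = self.screen_sums(self.ax + atn)
            mixn = self.mix_from(self.lp1, self.lp0, An, self.C)
            dll = float((mixn - self.mix).sum())
            acc = np.log(rng.random()) < dll + dpr
            ad.update(acc)
            if acc:
                self.P, self.lstau = Pc, prop
                self.at, self.A, self.mix = atn, An, mixn

    def _betaC_tau_coupled(self) -> None:
        """Shift beta_C and every tau jointly (attentive RT means invariant).

        The attentive log-RT mean ``(beta_C + beta*) - tau`` is constant
        under ``beta_C += c, tau += c``, so the move travels the ridge those
        parameters share; only the careless RT density, the person prior on
        tau and the prior on beta_C respond.
        """
        rng, sd = self.rng, self.pr.normal_sd
        ad = self.ad_coupled["betaC_tau"]
        c = float(ad.scale) * rng.standard_normal()
        prop = self.beta_C + c
        Pc = self.P.copy()
        Pc[:, 1] = self.P[:, 1] + c
        ctn = self.cier_t_logp(beta_C=prop)
        Cn = self.screen_sums(self.cx + ctn)
        mixn = self.mix_from(self.lp1, self.lp0, self.A, Cn)
        dll = float((mixn - self.mix).sum())
        dpr = float(norm.logpdf(prop, 0, sd) - norm.logpdf(self.beta_C, 0, sd))
        dpr += float((self.person_logprior(Pc) - self.person_logprior()).sum())
        acc = np.log(rng.random()) < dll + dpr
        ad.update(acc)
        if acc:
            self.P, self.beta_C = Pc, prop
            self.ct, self.C, self.mix = ctn, Cn, mixn

    def _betaC_bstar_coupled(self) -> None:
        """Shift beta_C against every beta* (item time intensities invariant).

        ``beta_C += c, beta*_j -= c`` keeps all attentive time intensities
        ``beta_C + beta*_j`` fixed, so only the careless RT density and the
        priors respond; proposals pushing any beta* negative are rejected
        (zero prior mass).
        """
        rng, sd = self.rng, self.pr.normal_sd
        ad = self.ad_coupled["betaC_bstar"]
        c = float(ad.scale) * rng.standard_normal()
        bsprop = self.bstar - c
        if np.any(bsprop < 0):
            ad.update(False)
            return
        prop = self.beta_C + c
        ctn = self.cier_t_logp(beta_C=prop)
        Cn = self.screen_sums(self.cx + ctn)
        mixn = self.mix_from(self.lp1, self.lp0, self.A, Cn)
        dll = float((mixn - self.mix).sum())
        dpr = float(norm.logpdf(prop, 0, sd) - norm.logpdf(self.beta_C, 0, sd))
        dpr += float(norm.logpdf(bsprop, 0, sd).sum()
                     - norm.logpdf(self.bstar, 0, sd).sum())
        acc = np.log(rng.random()) < dll + dpr
        ad.update(acc)
        if acc:
            self.beta_C, self.bstar = prop, bsprop
            self.ct, self.C, self.mix = ctn, Cn, mixn

    def update_psi_column(self) -> None:
        """Extra cheap refresh of the attentiveness latents (mix weights only)."""
        d, rng = self.d, self.rng
        L = self.sigma_chol()
        ad = self.ad_P[0]
        prop = self.P[:, 0] + ad.scale * rng.standard_normal(d.N)
        Pc = self.P.copy()
        Pc[:, 0] = prop
        dlin = prop[:, None] - self.iota[None, :]
        lp1n, lp0n = log_expit(dlin), log_expit(-dlin)
        mixn = self.mix_from(lp1n, lp0n, self.A, self.C)
        dll = (mixn - self.mix).sum(axis=1)
        dpr = self.person_logprior(Pc, L) - self.person_logprior(self.P, L)
        acc = np.log(rng.random(d.N)) < dll + dpr
        self.P[acc, 0] = prop[acc]
        self.lp1[acc] = lp1n[acc]
        self.lp0[acc] = lp0n[acc]
        self.mix[acc] = mixn[acc]

    def update_psi_prior_refresh(self) -> None:
        """Metropolized independence proposal for psi from its conditional prior.

        Each psi_i is proposed from N(m_i, s2), its MVN conditional given
        (tau_i, eta_i) under the current covariance; prior and proposal
        densities cancel, so acceptance depends only on the mixture-weight
        likelihood ratio.  Because most persons' likelihood is nearly flat in
        psi, this re-equilibrates the attentiveness latents almost instantly
        after covariance moves.
        """
        d, rng = self.d, self.rng
        L = self.sigma_chol()
        Sigma = L @ L.T
        w = np.linalg.solve(Sigma[1:, 1:], Sigma[0, 1:])
        m = self.P[:, 1:] @ w
        s2 = float(Sigma[0, 0] - Sigma[0, 1:] @ w)
        prop = m + np.sqrt(max(s2, 1e-12)) * rng.standard_normal(d.N)
        dlin = prop[:, None] - self.iota[None, :]
        lp1n, lp0n = log_expit(dlin), log_expit(-dlin)
        mixn = self.mix_from(lp1n, lp0n, self.A, self.C)
        acc = np.log(rng.random(d.N)) < (mixn - self.mix).sum(axis=1)
        self.P[acc, 0] = prop[acc]
        self.lp1[acc] = lp1n[acc]
        self.lp0[acc] = lp0n[acc]
        self.mix[acc] = mixn[acc]

    def update_psi_block(self) -> None:
        """Joint move on the psi hierarchy: psi-cpcs, sigma_psi and all psi.

        Perturbs the canonical partial correlations that involve psi together
        with log sigma_psi, then redraws every psi_i from its conditional
        prior under the *proposed* covariance.  The conditional-prior
        proposal cancels against the prior, leaving the mixture-weight
        likelihood, the (tau, eta) marginal-prior change (the cpcs alter
        that block of Omega), the LKJ term and the half-Cauchy term.  This
        is what lets the weakly identified attentiveness hierarchy mix on
        the same time scale as the data-rich parameters.
        """
        from scipy.linalg import solve_triangular

        d, rng = self.d, self.rng
        n_psi = self.D - 1
        start = n_psi * (n_psi - 1) // 2  # psi-cpcs: the last D-1 entries
        yprop = self.y.copy()
        lspprop = self.lspsi
        # alternate between the sigma_psi scale direction and the psi-cpc
        # directions; each needs a very different proposal scale
        which = self._psi_block_turn % 2
        self._psi_block_turn += 1
        ad = self.ad_psi_scale if which == 0 else self.ad_psi_corr
        if which == 0:
            lspprop = self.lspsi + float(ad.scale) * rng.standard_normal()
        else:
            yprop[start:] += float(ad.scale) * rng.standard_normal(n_psi)
        # psi is last in the cpc ordering, so the (tau, eta) block of Omega
        # is untouched: no marginal-prior term enters the ratio.  psi is
        # transported deterministically through its standardized conditional
        # residual, psi' = m' + (s'/s)(psi - m); the conditional-prior ratio
        # cancels the transformation Jacobian exactly.
        def cond(y, lspsi):
            L = self.sigma_chol(y=y, lspsi=lspsi)
            Sig = L @ L.T
            w = np.linalg.solve(Sig[1:, 1:], Sig[0, 1:])
            s2 = float(Sig[0, 0] - Sig[0, 1:] @ w)
            return self.P[:, 1:] @ w, np.sqrt(max(s2, 1e-12))

        m_cur, s_cur = cond(self.y, self.lspsi)
        m_new, s_new = cond(yprop, lspprop)
        psin = m_new + (s_new / s_cur) * (self.P[:, 0] - m_cur)
        # transport iota along the rate-preserving direction of the
        # logistic-normal integral (probit approximation with scale 1.702):
        # scaling sigma_psi rescales the whole attentiveness scale, so the
        # screen difficulties follow to keep marginal careless rates stable
        c = np.sqrt((1.702 ** 2 + np.exp(2 * lspprop))
                    / (1.702 ** 2 + np.exp(2 * self.lspsi)))
        iotan = c * self.iota
        dlin = psin[:, None] - iotan[None, :]
        lp1n, lp0n = log_expit(dlin), log_expit(-dlin)
        mixn = self.mix_from(lp1n, lp0n, self.A, self.C)
        dll = float((mixn - self.mix).sum())
        hc, eta_lkj = self.pr.half_cauchy_scale, self.pr.lkj_shape
        sd = self.pr.normal_sd
        dpr = (lkj_cpc_logprior(yprop, self.D, eta_lkj)
               - lkj_cpc_logprior(self.y, self.D, eta_lkj)
               + half_cauchy_logpdf(np.exp(lspprop), hc) + lspprop
               - half_cauchy_logpdf(np.exp(self.lspsi), hc) - self.lspsi
               + float(norm.logpdf(iotan, 0, sd).sum()
                       - norm.logpdf(self.iota, 0, sd).sum())
               + self.d.S * float(np.log(c)))  # Jacobian of the iota map
        acc = np.log(rng.random()) < dll + dpr
        ad.update(acc)
        if acc:
            self.y, self.lspsi = yprop, lspprop
            self.P[:, 0] = psin
            self.iota = iotan
            self.lp1, self.lp0, self.mix = lp1n, lp0n, mixn

    def slice_psi(self) -> None:
        """Shrinkage slice sampling of every psi_i (exact, rejection-free).

        The conditional target of psi_i given everything else is
        one-dimensional: its MVN conditional prior given (tau_i, eta_i)
        times the per-screen mixture weights.  A fixed wide bracket with
        pure shrinkage (no stepping out) is an exact slice sampler and
        needs only ~15 vectorized target evaluations for all persons.
        """
        d, rng = self.d, self.rng
        L = self.sigma_chol()
        Sigma = L @ L.T
        w = np.linalg.solve(Sigma[1:, 1:], Sigma[0, 1:])
        m = self.P[:, 1:] @ w
        s2 = float(max(Sigma[0, 0] - Sigma[0, 1:] @ w, 1e-12))

        def logf(psi):
            dlin = psi[:, None] - self.iota[None, :]
            mixv = np.logaddexp(log_expit(dlin) + self.A,
                                log_expit(-dlin) + self.C).sum(axis=1)
            return -0.5 * (psi - m) ** 2 / s2 + mixv

        cur = self.P[:, 0].copy()
        logy = logf(cur) - rng.exponential(size=d.N)
        half = 25.0 * max(np.sqrt(s2), 1.0)
        lo = cur - half
        hi = cur + half
        x = lo + (hi - lo) * rng.random(d.N)
        active = np.ones(d.N, dtype=bool)
        for _ in range(100):
            lf = logf(x)
            bad = active & (lf < logy)
            if not bad.any():
                break
            below = bad & (x < cur)
            lo = np.where(below, x, lo)
            hi = np.where(bad & ~below, x, hi)
            x = np.where(bad, lo + (hi - lo) * rng.random(d.N), x)
        else:  # pragma: no cover - extremely unlikely; keep current value
            x = np.where(logf(x) < logy, cur, x)
        self.P[:, 0] = x
        dlin = x[:, None] - self.iota[None, :]
        self.lp1 = log_expit(dlin)
        self.lp0 = log_expit(-dlin)
        self.mix = self.mix_from(self.lp1, self.lp0, self.A, self.C)

    def _update_gamma(self) -> None:
        rng, sd = self.rng, self.pr.normal_sd
        prop = self.gamma + self.ad_scalars["gamma"].scale * rng.standard_normal()
        atn = self.att_t_logp(gamma=prop)
        dpr = float(norm.logpdf(prop, 0, sd) - norm.logpdf(self.gamma, 0, sd))
        self.ad_scalars["gamma"].update(
            self._try_global("gamma", prop, dpr, new_at=atn))

    def iterate(self) -> None:
        # several sweeps of the data-rich blocks per recorded iteration;
        # counts are tuned so every block reaches a comparable effective
        # sample size per recorded draw
        for _ in range(4):
            self.update_persons()
        self.slice_psi()
        for _ in range(8):
            self.update_items()
        self.update_kappa()
        self.update_iota()
        self.update_globals()
        for _ in range(2):
            self._update_gamma()
        self._betaC_tau_coupled()
        self._betaC_bstar_coupled()
        self.update_covariance(rounds=3)
        for _ in range(32):
            self.update_psi_block()
        self.slice_psi()
        # the attentiveness hierarchy is weakly identified; give it extra,
        # cheap passes so it mixes as fast as the data-rich blocks
        for _ in range(3):
            self.update_psi_column()
            self.update_psi_prior_refresh()
            self.update_iota()
            self._scale_coupled("lspsi")
            self.update_covariance(rounds=3)

    # -- recorded quantities -------------------------------------------------

    def omega(self) -> np.ndarray:
        return self._omega_from_y(self.y)

    def responsibilities(self) -> np.ndarray:
        """P(delta = 0 | data, current parameters) per person-screen."""
        return np.exp(self.lp0 + self.C - self.mix)

    def log_posterior(self) -> float:
        """Joint log-density (likelihood + person prior + parameter priors)."""
        pr, sd, hc = self.pr, self.pr.normal_sd, self.pr.half_cauchy_scale
        lp = float(self.mix.sum()) + float(self.person_logprior().sum())
        v = np.exp(self.logv)
        lp += float(half_cauchy_logpdf(v, hc).sum() + self.logv.sum())
        lp += float(norm.logpdf(self.b, 0, sd).sum())
        lp += float(norm.logpdf(self.bstar, 0, sd).sum())
        lp += float(norm.logpdf(self.iota, 0, sd).sum())
        lp += float(norm.logpdf(self.gamma, 0, sd) + norm.logpdf(self.beta_C, 0, sd))
        for ls in (self.lsA, self.lsC, self.lspsi, self.lstau):
            lp += float(half_cauchy_logpdf(np.exp(ls), hc)) + ls
        kappa = self.kappa
        lp += float((pr.dirichlet_kappa - 1) * np.sum(np.log(kappa)))
        lp += simplex_logjac(kappa)
        lp += lkj_cpc_logprior(self.y, self.D, pr.lkj_shape)
        return lp




# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------


def fit_item_model(data: ResponseDataset, priors: PriorConfig | None = None,
                   mcmc: McmcConfig | None = None) -> PosteriorResult:
    """Fit the item-level mixture model by MCMC.

    Returns a :class:`PosteriorResult` with draws for all global, screen and
    item parameters (and person parameters), split-R-hat per component,
    posterior careless probabilities per person-screen, and careless rates.
    Non-convergence (any R-hat above the threshold) sets
    ``result.converged = False`` but never raises.
    """
    priors = priors or PriorConfig()
    mcmc = mcmc or McmcConfig()
    d = _ItemData(data)
    if d.S < 2:
        import warnings

        warnings.warn("fewer than 2 screens; trait correlations are not estimable",
                      stacklevel=2)

    n_keep = mcmc.iterations - mcmc.warmup
    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.chains)
    names_shapes = None
    all_draws: list[dict] = []
    resp_draws = np.zeros((mcmc.chains, n_keep, d.N, d.S), dtype=np.float32)
    for c in range(mcmc.chains):
        rng = np.random.default_rng(seeds[c])
        smp = _ItemSampler(d, priors, mcmc, rng)
        chain: dict[str, list] = {}
        for it in range(mcmc.iterations):
            smp.iterate()
            if it >= mcmc.warmup:
                k = it - mcmc.warmup
                rec = {
                    "gamma": smp.gamma, "beta_C": smp.beta_C,
                    "sigma_A": smp.sigma_A, "sigma_C": smp.sigma_C,
                    "sigma_psi": float(np.exp(smp.lspsi)),
                    "sigma_tau": float(np.exp(smp.lstau)),
                    "iota": smp.iota.copy(), "kappa": smp.kappa,
                    "omega": smp.omega(), "v": np.exp(smp.logv),
                    "b": smp.b.copy(), "beta_star": smp.bstar.copy(),
                    "persons": smp.P.astype(np.float32),
                }
                for key, val in rec.items():
                    chain.setdefault(key, []).append(val)
                resp_draws[c, k] = smp.responsibilities()
        stacked = {key: np.asarray(val) for key, val in chain.items()}
        if names_shapes is None:
            names_shapes = {key: val.shape[1:] for key, val in stacked.items()}
        all_draws.append(stacked)

    draws = {
        key: np.stack([ch[key] for ch in all_draws], axis=0)
        for key in all_draws[0]
    }
    draws["p_cier_draws"] = resp_draws

    rhat_input = {k: v for k, v in draws.items() if k != "p_cier_draws"}
    rhats = split_rhat_all(rhat_input)
    psrf_series = _flatten_rhats(rhats, d)
    max_psrf = float(psrf_series.max())

    p_cier = resp_draws.reshape(-1, d.N, d.S).mean(axis=0)
    J_s = np.array([len(ix) for ix in d.items_of_screen])
    per_screen = p_cier.mean(axis=0)
    overall = float((per_screen * J_s).sum() / J_s.sum())
    rates = {
        "overall": overall,
        "per_screen": dict(zip(d.screen_ids, per_screen.tolist())),
        "hard_overall": float(((p_cier > 0.5).mean(axis=0) * J_s).sum() / J_s.sum()),
    }

    summaries = _summaries(draws, d)
    return PosteriorResult(
        draws=draws, summaries=summaries, psrf=psrf_series, p_cier=p_cier,
        rates=rates, converged=bool(max_psrf < mcmc.psrf_threshold),
        max_psrf=max_psrf, person_ids=d.person_ids, screen_ids=d.screen_ids,
        meta={"model": "item", "psrf_threshold": mcmc.psrf_threshold,
              "chains": mcmc.chains, "iterations": mcmc.iterations,
              "warmup": mcmc.warmup, "seed": mcmc.seed},
    )


def _flatten_rhats(rhats: dict, d: _ItemData) -> pd.Series:
    vals, idx = [], []
    for name, arr in rhats.items():
        arr = np.atleast_1d(arr)
        for k, v in enumerate(arr):
            idx.append(name if arr.size == 1 else f"{name}[{k}]")
            vals.append(v)
    return pd.Series(vals, index=idx, name="psrf")


def _summaries(draws: dict, d) -> pd.DataFrame:
    rows = {}
    for name, arr in draws.items():
        if name in ("persons", "p_cier_draws"):
            continue
        flat = np.asarray(arr, dtype=float).reshape(-1, int(np.prod(arr.shape[2:])) or 1)
        for k in range(flat.shape[1]):
            label = name if flat.shape[1] == 1 else f"{name}[{k}]"
            col = flat[:, k]
            rows[label] = {
                "median": float(np.median(col)),
                "q2.5": float(np.quantile(col, 0.025)),
                "q97.5": float(np.quantile(col, 0.975)),
            }
    return pd.DataFrame(rows).T


def classify_attentiveness(result: PosteriorResult, data=None) -> np.ndarray:
    """Posterior P(delta = 0) per (person, screen), averaged over draws.

    The per-draw responsibility is ``(1 - p1) C / (p1 A + (1 - p1) C)``;
    the returned array is its posterior mean as computed during sampling.
    """
    return result.p_cier


def cier_rate(result: PosteriorResult) -> dict:
    """Overall (item-weighted) and per-screen careless rates.

    The default rate is the posterior mean of P(delta = 0), weighted by
    items per screen so it is a response-level rate; a hard-classification
    (0.5 threshold) count rate is included as ``hard_overall``.
    """
    return result.rates
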