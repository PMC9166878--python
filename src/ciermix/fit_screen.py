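"""Bayesian estimation of the screen-level (aggregated-timing) model variant.

When only screen-level timing is available, the model simplifies: the
mixture sits at the *person* level (a respondent is attentive on all
screens with probability ``pi_i`` or careless on all screens otherwise),
the attentiveness trait ``psi`` is dropped from the person-parameter
covariance, and the RT measurement model acts on the mean time per item
``t_bar`` with screen-level time-intensity offsets and screen aggregates of
the item parameters (geometric-mean discrimination ``v_dot``,
arithmetic-mean middle step difficulty ``o_dot``).

The attentiveness probabilities have a hierarchical Dirichlet (= Beta)
prior ``(pi_i, 1 - pi_i) ~ Dir(lambda * pi_P, lambda * (1 - pi_P))`` with a
uniform prior on the population proportion ``pi_P`` and a half-Cauchy(0, 5)
prior on the concentration ``lambda``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import beta as beta_dist
from scipy.stats import norm

from ._mcmc import (
    AdaptiveScale,
    corr_chol_from_y,
    half_cauchy_logpdf,
    lkj_cpc_logprior,
    simplex_from_z,
    simplex_logjac,
    split_rhat_all,
)
from .fit_item import (
    McmcConfig,
    PosteriorResult,
    PriorConfig,
    _flatten_rhats,
    _gpcm_logp_obs,
    _ItemData,
    _lognorm_logpdf_obs,
    _middle_of_b,
    _summaries,
    _LOG_SQRT_2PI,
)
from .simulator import ResponseDataset
from .timing import TimingTable

__all__ = ["ScreenLevelData", "screen_aggregates", "fit_screen_model"]


def screen_aggregates(items) -> tuple[float, float]:
    """Screen aggregates of item parameters: (v_dot, o_dot).

    ``v_dot`` is the geometric mean of the member discriminations and
    ``o_dot`` the arithmetic mean of the middle step difficulties.
    """
    v = np.array([it.v for it in items], dtype=float)
    if np.any(v <= 0):
        raise ValueError("discriminations must be positive")
    o = np.array([it.o for it in items], dtype=float)
    return float(np.exp(np.mean(np.log(v)))), float(np.mean(o))


@dataclass
class ScreenLevelData:
    """Responses plus one aggregated timing value per person-screen."""

    dataset: ResponseDataset
    t_bar: pd.DataFrame  # person_id, screen_id, t_bar (NaN = missing)

    @classmethod
    def from_dataset(cls, dataset: ResponseDataset, timing: TimingTable | None,
                     measure: str = "tt_per_item") -> "ScreenLevelData":
        """Aggregate a timing measure into t_bar.

        ``tt_per_item`` / ``ttfrt`` / ``aat`` come from the timing table
        (and therefore include or exclude reading time per their
        definitions); ``item_mean`` is the mean of the observed item-level
        RTs per person-screen, the purest aggregate when item RTs exist.
        """
        if measure == "item_mean":
            tb = (dataset.df.groupby(["person_id", "screen_id"], sort=False)["t"]
                  .mean().rename("t_bar").reset_index())
            return cls(dataset=dataset, t_bar=tb)
        if measure not in ("tt_per_item", "ttfrt", "aat"):
            raise ValueError(f"unknown timing measure {measure!r}")
        tb = timing.table[["person_id", "screen_id", measure]].rename(
            columns={measure: "t_bar"}
        )
        return cls(dataset=dataset, t_bar=tb)


class _ScreenData(_ItemData):
    """Dense arrays for the screen-level sampler."""

    def __init__(self, sdata: ScreenLevelData):
        super().__init__(sdata.dataset)
        person_pos = {pid: k for k, pid in enumerate(self.person_ids)}
        screen_pos = {sid: k for k, sid in enumerate(self.screen_ids)}
        self.TB = np.full((self.N, self.S), np.nan)
        for _, row in sdata.t_bar.iterrows():
            self.TB[person_pos[row["person_id"]], screen_pos[row["screen_id"]]] = \
                row["t_bar"]
        if np.any(self.TB[~np.isnan(self.TB)] <= 0):
            raise ValueError("observed t_bar values must be positive")
        self.MTB = ~np.isnan(self.TB)
        self.logTB = np.where(self.MTB, np.log(np.where(self.MTB, self.TB, 1.0)), 0.0)


class _ScreenSampler:
    """One chain of the screen-level model."""

    def __init__(self, data: _ScreenData, priors: PriorConfig, mcmc: McmcConfig,
                 rng: np.random.Generator):
        self.d = data
        self.pr = priors
        self.rng = rng
        self.D = 1 + data.S  # tau, eta_1..eta_S
        self.warmup = mcmc.warmup
        self._init_state(mcmc.init_jitter)
        self._init_adapt()
        self.refresh_all()

    def _init_state(self, jitter: float) -> None:
        d, rng = self.d, self.rng
        logtb = np.where(d.MTB, d.logTB, np.nan)
        person_mean = np.nanmean(logtb, axis=1)
        person_mean = np.where(np.isfinite(person_mean), person_mean,
                               np.nanmean(logtb))
        tau0 = np.nanmean(person_mean) - person_mean
        self.P = np.zeros((d.N, self.D))
        self.P[:, 0] = tau0 + rng.normal(0, 0.3 * jitter + 0.05, d.N)
        for s in range(d.S):
            idx = d.items_of_screen[s]
            score = np.where(d.MX[:, idx], d.X[:, idx], np.nan).mean(axis=1)
            score = np.where(np.isfinite(score), score, np.nanmean(score))
            sd = np.nanstd(score)
            eta0 = (score - np.nanmean(score)) / (sd if sd > 0 else 1.0)
            self.P[:, 1 + s] = eta0 + rng.normal(0, 0.3 * jitter + 0.05, d.N)
        self.logit_pi = rng.normal(2.0, 0.5 * jitter + 0.1, d.N)
        self.logit_piP = rng.normal(2.0, 0.5 * jitter + 0.1)
        self.loglam = np.log(5.0) + rng.normal(0, 0.3 * jitter)
        self.logv = rng.normal(0.0, 0.2 * jitter, d.J)
        self.b = np.linspace(-0.8, 0.8, d.K)[None, :] + \
            rng.normal(0, 0.3 * jitter, (d.J, d.K))
        self.bstar_s = np.abs(rng.normal(0.3, 0.15 * jitter + 0.02, d.S))
        self.gamma = rng.normal(0.02, 0.05 * jitter)
        all_logtb = d.logTB[d.MTB]
        self.beta_C = float(np.quantile(all_logtb, 0.1)) + rng.normal(0, 0.3 * jitter)
        self.lsA = np.log(0.5) + rng.normal(0, 0.2 * jitter)
        self.lsC = np.log(0.8) + rng.normal(0, 0.2 * jitter)
        self.zk = rng.normal(0, 0.3 * jitter, d.K)
        self.y = rng.normal(0, 0.2 * jitter, self.D * (self.D - 1) // 2)
        self.lstau = np.log(0.4) + rng.normal(0, 0.3 * jitter)

    def _init_adapt(self) -> None:
        d, w = self.d, self.warmup
        self.ad_P = [AdaptiveScale((d.N,), 0.5, 0.44, w) for _ in range(self.D)]
        self.ad_pi = AdaptiveScale((d.N,), 1.0, 0.44, w)
        self.ad_logv = AdaptiveScale((d.J,), 0.1, 0.44, w)
        self.ad_b = AdaptiveScale((d.J,), 0.1, 0.28, w)
        self.ad_bstar = AdaptiveScale((d.S,), 0.1, 0.44, w)
        self.ad_scalars = {
            name: AdaptiveScale((), 0.1, 0.44, w)
            for name in ("gamma", "beta_C", "lsA", "lsC", "lstau",
                         "logit_piP", "loglam")
        }
        self.ad_zk = AdaptiveScale((), 0.1, 0.28, w)
        self.ad_zk_coord = AdaptiveScale((d.K,), 0.2, 0.44, w)
        self.ad_y = AdaptiveScale((self.D * (self.D - 1) // 2,), 0.2, 0.44, w)
        self.ad_coupled = AdaptiveScale((), 0.1, 0.44, w)
        self.ad_coupled_b = AdaptiveScale((), 0.1, 0.44, w)
        self.ad_coupled_bt = AdaptiveScale((), 0.1, 0.44, w)
        self.ad_hyper_t = AdaptiveScale((), 0.3, 0.28, w)

    # -- derived quantities --------------------------------------------------

    @property
    def sigma_A(self) -> float:
        return float(np.exp(self.lsA))

    @property
    def sigma_C(self) -> float:
        return float(np.exp(self.lsC))

    @property
    def kappa(self) -> np.ndarray:
        return simplex_from_z(self.zk)

    @property
    def pi(self) -> np.ndarray:
        return expit(self.logit_pi)

    def aggregates(self, logv=None, b=None):
        """Per-screen (v_dot, o_dot) from the current item parameters."""
        logv = self.logv if logv is None else logv
        b = self.b if b is None else b
        o = _middle_of_b(b)
        v_dot = np.array([
            float(np.exp(np.mean(logv[idx]))) for idx in self.d.items_of_screen
        ])
        o_dot = np.array([float(np.mean(o[idx])) for idx in self.d.items_of_screen])
        return v_dot, o_dot

    def sigma_chol(self, y=None, lstau=None) -> np.ndarray:
        y = self.y if y is None else y
        lstau = self.lstau if lstau is None else lstau
        L = corr_chol_from_y(y, self.D)
        sd = np.ones(self.D)
        sd[0] = np.exp(lstau)
        return sd[:, None] * L

    def person_logprior(self, P=None, L=None) -> np.ndarray:
        from scipy.linalg import solve_triangular

        P = self.P if P is None else P
        L = self.sigma_chol() if L is None else L
        z = solve_triangular(L, P.T, lower=True)
        logdet = np.sum(np.log(np.diag(L)))
        return -0.5 * np.sum(z * z, axis=0) - logdet - self.D * _LOG_SQRT_2PI

    def pi_logprior(self, logit_pi=None, logit_piP=None, loglam=None) -> np.ndarray:
        """Per-person Beta(lam*piP, lam*(1-piP)) prior on pi, logit scale."""
        logit_pi = self.logit_pi if logit_pi is None else logit_pi
        logit_piP = self.logit_piP if logit_piP is None else logit_piP
        loglam = self.loglam if loglam is None else loglam
        piP = expit(logit_piP)
        lam = np.exp(loglam)
        from scipy.special import log_expit

        pi = expit(logit_pi)
        # Beta density + logit-transform Jacobian pi(1-pi), all log-stable
        return (beta_dist.logpdf(np.clip(pi, 1e-12, 1 - 1e-12),
                                 lam * piP, lam * (1 - piP))
                + log_expit(logit_pi) + log_expit(-logit_pi))

    # -- caches ----------------------------------------------------------------

    def att_x_logp(self, P=None, logv=None, b=None, cols=None) -> np.ndarray:
        d = self.d
        P = self.P if P is None else P
        v = np.exp(self.logv if logv is None else logv)
        b = self.b if b is None else b
        trait_cols = 1 + d.trait_of_screen[d.screen_of_item]
        eta = P[:, trait_cols]
        if cols is not None:
            v, b = v[cols], b[cols]
            eta = eta[:, cols]
            Xc, MX = d.Xc[:, cols], d.MX[:, cols]
        else:
            Xc, MX = d.Xc, d.MX
        return _gpcm_logp_obs(eta, v, b, Xc, MX)

    def att_t_logp(self, P=None, bstar_s=None, gamma=None, beta_C=None,
                   sigma_A=None, v_dot=None, o_dot=None) -> np.ndarray:
        """Attentive lognormal density of t_bar per (person, screen)."""
        d = self.d
        P = self.P if P is None else P
        bstar_s = self.bstar_s if bstar_s is None else bstar_s
        gamma = self.gamma if gamma is None else gamma
        beta_C = self.beta_C if beta_C is None else beta_C
        sigma_A = self.sigma_A if sigma_A is None else sigma_A
        if v_dot is None or o_dot is None:
            v_dot, o_dot = self.aggregates()
        eta = P[:, 1 + d.trait_of_screen]  # (N, S)
        dist = np.abs(v_dot[None, :] * eta - o_dot[None, :])
        mu = (beta_C + bstar_s)[None, :] - P[:, 0][:, None] - gamma * dist
        return _lognorm_logpdf_obs(d.logTB, d.MTB, mu, sigma_A)

    def cier_t_logp(self, beta_C=None, sigma_C=None) -> np.ndarray:
        d = self.d
        beta_C = self.beta_C if beta_C is None else beta_C
        sigma_C = self.sigma_C if sigma_C is None else sigma_C
        return _lognorm_logpdf_obs(d.logTB, d.MTB, beta_C, sigma_C)

    def cier_x_logp(self, kappa=None) -> np.ndarray:
        d = self.d
        kappa = self.kappa if kappa is None else kappa
        return np.where(d.MX, np.log(kappa)[d.Xc], 0.0)

    def mix_from(self, logit_pi, A, C) -> np.ndarray:
        from scipy.special import log_expit

        return np.logaddexp(log_expit(logit_pi) + A, log_expit(-logit_pi) + C)

    def refresh_all(self) -> None:
        self.ax = self.att_x_logp()
        self.cx = self.cier_x_logp()
        self.at = self.att_t_logp()
        self.ct = self.cier_t_logp()
        self.A = self.ax.sum(axis=1) + self.at.sum(axis=1)
        self.C = self.cx.sum(axis=1) + self.ct.sum(axis=1)
        self.mix = self.mix_from(self.logit_pi, self.A, self.C)

    # -- updates ----------------------------------------------------------------

    def update_persons(self) -> None:
        d, rng = self.d, self.rng
        L = self.sigma_chol()
        for c in range(self.D):
            ad = self.ad_P[c]
            prop = self.P[:, c] + ad.scale * rng.standard_normal(d.N)
            Pc = self.P.copy()
            Pc[:, c] = prop
            if c == 0:  # tau: all screens' attentive t densities
                atn = self.att_t_logp(P=Pc)
                axn_c, idx, s = None, None, None
                An = self.ax.sum(axis=1) + atn.sum(axis=1)
            else:  # trait: responses of its screen + its t_bar density
                s = int(np.flatnonzero(self.d.trait_of_screen == c - 1)[0])
                idx = d.items_of_screen[s]
                axn_c = self.att_x_logp(P=Pc, cols=idx)
                atn = self.at.copy()
                atn[:, s] = self.att_t_logp(P=Pc)[:, s]
                An = (self.A - self.ax[:, idx].sum(axis=1) + axn_c.sum(axis=1)
                      - self.at[:, s] + atn[:, s])
            mixn = self.mix_from(self.logit_pi, An, self.C)
            dll = mixn - self.mix
            dpr = self.person_logprior(Pc, L) - self.person_logprior(self.P, L)
            acc = np.log(rng.random(d.N)) < dll + dpr
            ad.update(acc)
            if not acc.any():
                continue
            rows = np.flatnonzero(acc)
            self.P[acc, c] = prop[acc]
            self.mix[acc] = mixn[acc]
            self.A[acc] = An[acc]
            if c == 0:
                self.at[acc] = atn[acc]
            else:
                self.ax[np.ix_(rows, idx)] = axn_c[acc]
                self.at[acc, s] = atn[acc, s]

    def update_pi(self) -> None:
        d, rng = self.d, self.rng
        prop = self.logit_pi + self.ad_pi.scale * rng.standard_normal(d.N)
        mixn = self.mix_from(prop, self.A, self.C)
        dll = mixn - self.mix
        dpr = self.pi_logprior(logit_pi=prop) - self.pi_logprior()
        acc = np.log(rng.random(d.N)) < dll + dpr
        self.ad_pi.update(acc)
        self.logit_pi[acc] = prop[acc]
        self.mix[acc] = mixn[acc]

    def update_hyper_pi(self) -> None:
        """pi_P (uniform prior) and lambda (half-Cauchy)."""
        rng, hc = self.rng, self.pr.half_cauchy_scale
        lp_cur = float(self.pi_logprior().sum())
        # pi_P on the logit scale: uniform prior + Jacobian pi_P(1-pi_P)
        prop = self.logit_piP + self.ad_scalars["logit_piP"].scale * \
            rng.standard_normal()
        from scipy.special import log_expit

        lp_new = float(self.pi_logprior(logit_piP=prop).sum())
        djac = (log_expit(prop) + log_expit(-prop)
                - log_expit(self.logit_piP) - log_expit(-self.logit_piP))
        acc = np.log(rng.random()) < lp_new - lp_cur + djac
        self.ad_scalars["logit_piP"].update(acc)
        if acc:
            self.logit_piP = prop
            lp_cur = lp_new
        # lambda on the log scale
        prop = self.loglam + self.ad_scalars["loglam"].scale * rng.standard_normal()
        lp_new = float(self.pi_logprior(loglam=prop).sum())
        dpr = (half_cauchy_logpdf(np.exp(prop), hc) + prop
               - half_cauchy_logpdf(np.exp(self.loglam), hc) - self.loglam)
        acc = np.log(rng.random()) < lp_new - lp_cur + dpr
        self.ad_scalars["loglam"].update(acc)
        if acc:
            self.loglam = prop

    def _try_state(self, dll: float, dpr: float) -> bool:
        return np.log(self.rng.random()) < dll + dpr

    def update_items(self) -> None:
        """Sweep over item parameters; candidates batched per parameter type.

        Response-probability columns are independent given the person
        parameters, so all candidate columns come from one vectorized call;
        the sequential loop recomputes only the aggregate-dependent t_bar
        density of the item's screen, keeping within-screen coupling exact.
        """
        d, rng, sd, hc = self.d, self.rng, self.pr.normal_sd, self.pr.half_cauchy_scale
        for which in ("v", "b"):
            if which == "v":
                prop_lv = self.logv + self.ad_logv.scale * rng.standard_normal(d.J)
                ax_all = self.att_x_logp(logv=prop_lv)
                dpr_all = (half_cauchy_logpdf(np.exp(prop_lv), hc) + prop_lv
                           - half_cauchy_logpdf(np.exp(self.logv), hc) - self.logv)
            else:
                prop_b = self.b + self.ad_b.scale[:, None] * \
                    rng.standard_normal((d.J, d.K))
                ax_all = self.att_x_logp(b=prop_b)
                dpr_all = (norm.logpdf(prop_b, 0, sd).sum(axis=1)
                           - norm.logpdf(self.b, 0, sd).sum(axis=1))
            for j in range(d.J):
                s = int(d.screen_of_item[j])
                if which == "v":
                    logv_n = self.logv.copy()
                    logv_n[j] = prop_lv[j]
                    b_n = self.b
                else:
                    logv_n = self.logv
                    b_n = self.b.copy()
                    b_n[j] = prop_b[j]
                axn_j = ax_all[:, j]
                v_dot, o_dot = self.aggregates(logv=logv_n, b=b_n)
                atn_s = self.att_t_logp(v_dot=v_dot, o_dot=o_dot)[:, s]
                An = (self.A - self.ax[:, j] + axn_j - self.at[:, s] + atn_s)
                mixn = self.mix_from(self.logit_pi, An, self.C)
                dll = float((mixn - self.mix).sum())
                acc = self._try_state(dll, float(dpr_all[j]))
                (self.ad_logv if which == "v" else self.ad_b).update_at(j, acc)
                if acc:
                    if which == "v":
                        self.logv = logv_n
                    else:
                        self.b = b_n
                    self.ax[:, j] = axn_j
                    self.at[:, s] = atn_s
                    self.A = An
                    self.mix = mixn

    def update_bstar(self) -> None:
        rng, sd = self.rng, self.pr.normal_sd
        for s in range(self.d.S):
            prop = self.bstar_s.copy()
            prop[s] += self.ad_bstar.scale[s] * rng.standard_normal()
            if prop[s] < 0:
                self.ad_bstar.update_at(s, False)
                continue
            atn = self.at.copy()
            atn[:, s] = self.att_t_logp(bstar_s=prop)[:, s]
            An = self.A - self.at[:, s] + atn[:, s]
            mixn = self.mix_from(self.logit_pi, An, self.C)
            dll = float((mixn - self.mix).sum())
            dpr = float(norm.logpdf(prop[s], 0, sd)
                        - norm.logpdf(self.bstar_s[s], 0, sd))
            acc = self._try_state(dll, dpr)
            self.ad_bstar.update_at(s, acc)
            if acc:
                self.bstar_s = prop
                self.at = atn
                self.A = An
                self.mix = mixn

    def _try_global(self, name, prop_val, dpr, new_at=None, new_ct=None,
                    new_cx=None) -> bool:
        A = self.A if new_at is None else \
            self.ax.sum(axis=1) + new_at.sum(axis=1)
        if new_ct is not None or new_cx is not None:
            ct = new_ct if new_ct is not None else self.ct
            cx = new_cx if new_cx is not None else self.cx
            C = cx.sum(axis=1) + ct.sum(axis=1)
        else:
            C = self.C
        mixn = self.mix_from(self.logit_pi, A, C)
        dll = float((mixn - self.mix).sum())
        if self._try_state(dll, dpr):
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
        prop = self.gamma + self.ad_scalars["gamma"].scale * rng.standard_normal()
        atn = self.att_t_logp(gamma=prop)
        dpr = float(norm.logpdf(prop, 0, sd) - norm.logpdf(self.gamma, 0, sd))
        self.ad_scalars["gamma"].update(
            self._try_global("gamma", prop, dpr, new_at=atn))

        prop = self.beta_C + self.ad_scalars["beta_C"].scale * rng.standard_normal()
        atn = self.att_t_logp(beta_C=prop)
        ctn = self.cier_t_logp(beta_C=prop)
        dpr = float(norm.logpdf(prop, 0, sd) - norm.logpdf(self.beta_C, 0, sd))
        self.ad_scalars["beta_C"].update(
            self._try_global("beta_C", prop, dpr, new_at=atn, new_ct=ctn))

        prop = self.lsA + self.ad_scalars["lsA"].scale * rng.standard_normal()
        atn = self.att_t_logp(sigma_A=float(np.exp(prop)))
        dpr = float(half_cauchy_logpdf(np.exp(prop), hc) + prop
                    - half_cauchy_logpdf(self.sigma_A, hc) - self.lsA)
        self.ad_scalars["lsA"].update(self._try_global("lsA", prop, dpr, new_at=atn))

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
        for _ in range(rounds):
            self._covariance_round()
        self._tau_scale_coupled()

    def _covariance_round(self) -> None:
        rng, hc, eta_lkj = self.rng, self.pr.half_cauchy_scale, self.pr.lkj_shape
        lp_cur = float(self.person_logprior().sum())
        for k in range(self.y.size):
            yprop = self.y.copy()
            yprop[k] += self.ad_y.scale[k] * rng.standard_normal()
            lp_new = float(self.person_logprior(L=self.sigma_chol(y=yprop)).sum())
            dpr = (lkj_cpc_logprior(yprop, self.D, eta_lkj)
                   - lkj_cpc_logprior(self.y, self.D, eta_lkj))
            acc = np.log(rng.random()) < lp_new - lp_cur + dpr
            self.ad_y.update_at(k, acc)
            if acc:
                self.y = yprop
                lp_cur = lp_new
        prop = self.lstau + self.ad_scalars["lstau"].scale * rng.standard_normal()
        lp_new = float(self.person_logprior(L=self.sigma_chol(lstau=prop)).sum())
        dpr = (half_cauchy_logpdf(np.exp(prop), hc) + prop
               - half_cauchy_logpdf(np.exp(self.lstau), hc) - self.lstau)
        acc = np.log(rng.random()) < lp_new - lp_cur + dpr
        self.ad_scalars["lstau"].update(acc)
        if acc:
            self.lstau = prop

    def _tau_scale_coupled(self) -> None:
        """Joint rescale of all tau with sigma_tau (funnel-breaking move).

        The standardized residuals are invariant, so the MVN prior change
        cancels the transformation Jacobian; only the likelihood and the
        half-Cauchy prior remain in the ratio.
        """
        rng, hc = self.rng, self.pr.half_cauchy_scale
        eps = float(self.ad_coupled.scale) * rng.standard_normal()
        prop = self.lstau + eps
        Pc = self.P.copy()
        Pc[:, 0] = self.P[:, 0] * np.exp(eps)
        atn = self.att_t_logp(P=Pc)
        An = self.ax.sum(axis=1) + atn.sum(axis=1)
        mixn = self.mix_from(self.logit_pi, An, self.C)
        dll = float((mixn - self.mix).sum())
        dpr = (half_cauchy_logpdf(np.exp(prop), hc) + prop
               - half_cauchy_logpdf(np.exp(self.lstau), hc) - self.lstau)
        acc = np.log(rng.random()) < dll + dpr
        self.ad_coupled.update(acc)
        if acc:
            self.P, self.lstau = Pc, prop
            self.at, self.A, self.mix = atn, An, mixn

    def _betaC_bstar_coupled(self) -> None:
        """beta_C += c, beta*_s -= c: screen time intensities invariant."""
        rng, sd = self.rng, self.pr.normal_sd
        ad = self.ad_coupled_b
        c = float(ad.scale) * rng.standard_normal()
        bsprop = self.bstar_s - c
        if np.any(bsprop < 0):
            ad.update(False)
            return
        prop = self.beta_C + c
        ctn = self.cier_t_logp(beta_C=prop)
        Cn = self.cx.sum(axis=1) + ctn.sum(axis=1)
        mixn = self.mix_from(self.logit_pi, self.A, Cn)
        dll = float((mixn - self.mix).sum())
        dpr = float(norm.logpdf(prop, 0, sd) - norm.logpdf(self.beta_C, 0, sd)
                    + norm.logpdf(bsprop, 0, sd).sum()
                    - norm.logpdf(self.bstar_s, 0, sd).sum())
        acc = np.log(rng.random()) < dll + dpr
        ad.update(acc)
        if acc:
            self.beta_C, self.bstar_s = prop, bsprop
            self.ct, self.C, self.mix = ctn, Cn, mixn

    def _betaC_tau_coupled(self) -> None:
        """beta_C += c, tau += c: attentive t_bar means invariant."""
        rng, sd = self.rng, self.pr.normal_sd
        ad = self.ad_coupled_bt
        c = float(ad.scale) * rng.standard_normal()
        prop = self.beta_C + c
        Pc = self.P.copy()
        Pc[:, 0] = self.P[:, 0] + c
        ctn = self.cier_t_logp(beta_C=prop)
        Cn = self.cx.sum(axis=1) + ctn.sum(axis=1)
        mixn = self.mix_from(self.logit_pi, self.A, Cn)
        dll = float((mixn - self.mix).sum())
        dpr = float(norm.logpdf(prop, 0, sd) - norm.logpdf(self.beta_C, 0, sd))
        dpr += float((self.person_logprior(Pc) - self.person_logprior()).sum())
        acc = np.log(rng.random()) < dll + dpr
        ad.update(acc)
        if acc:
            self.P, self.beta_C = Pc, prop
            self.ct, self.C, self.mix = ctn, Cn, mixn

    def update_hyper_pi_transport(self) -> None:
        """Joint (pi_P, lambda) move with quantile transport of all pi_i.

        Each pi_i is mapped through its Beta CDF under the current
        hyperparameters and back through the PPF under the proposed ones,
        so the per-person prior ratio cancels the transport Jacobian
        exactly; only the likelihood and the hyperpriors enter.  Breaks the
        funnel between the attentiveness probabilities and their hierarchy.
        """
        from scipy.special import log_expit, logit

        rng, hc = self.rng, self.pr.half_cauchy_scale
        ad = self.ad_hyper_t
        step = float(ad.scale)
        lpp = self.logit_piP + step * rng.standard_normal()
        llm = self.loglam + step * rng.standard_normal()
        a_c = np.exp(self.loglam) * expit(self.logit_piP)
        b_c = np.exp(self.loglam) * expit(-self.logit_piP)
        a_n = np.exp(llm) * expit(lpp)
        b_n = np.exp(llm) * expit(-lpp)
        pi_cur = np.clip(expit(self.logit_pi), 1e-12, 1 - 1e-12)
        u = np.clip(beta_dist.cdf(pi_cur, a_c, b_c), 1e-12, 1 - 1e-12)
        pi_new = np.clip(beta_dist.ppf(u, a_n, b_n), 1e-10, 1 - 1e-10)
        lp_new = logit(pi_new)
        mixn = self.mix_from(lp_new, self.A, self.C)
        dll = float((mixn - self.mix).sum())
        # hyperpriors: uniform pi_P (+ logit Jacobian), half-Cauchy lambda
        dpr = float(log_expit(lpp) + log_expit(-lpp)
                    - log_expit(self.logit_piP) - log_expit(-self.logit_piP)
                    + half_cauchy_logpdf(np.exp(llm), hc) + llm
                    - half_cauchy_logpdf(np.exp(self.loglam), hc) - self.loglam)
        acc = np.log(rng.random()) < dll + dpr
        ad.update(acc)
        if acc:
            self.logit_piP, self.loglam = lpp, llm
            self.logit_pi = lp_new
            self.mix = mixn

    def slice_pi(self) -> None:
        """Shrinkage slice sampling of every logit pi_i (exact)."""
        d, rng = self.d, self.rng

        def logf(lp):
            return self.pi_logprior(logit_pi=lp) + self.mix_from(lp, self.A, self.C)

        cur = self.logit_pi.copy()
        logy = logf(cur) - rng.exponential(size=d.N)
        lo = cur - 30.0
        hi = cur + 30.0
        x = lo + (hi - lo) * rng.random(d.N)
        for _ in range(100):
            lf = logf(x)
            bad = lf < logy
            if not bad.any():
                break
            below = bad & (x < cur)
            lo = np.where(below, x, lo)
            hi = np.where(bad & ~below, x, hi)
            x = np.where(bad, lo + (hi - lo) * rng.random(d.N), x)
        else:  # pragma: no cover
            x = np.where(logf(x) < logy, cur, x)
        self.logit_pi = x
        self.mix = self.mix_from(x, self.A, self.C)

    def iterate(self) -> None:
        for _ in range(3):
            self.update_persons()
        for _ in range(4):
            self.update_items()
        self.update_kappa()
        self.update_bstar()
        self.update_globals()
        self._betaC_bstar_coupled()
        self._betaC_tau_coupled()
        self.update_pi()
        self.slice_pi()
        for _ in range(4):
            self.update_hyper_pi()
            self.update_hyper_pi_transport()
        self.update_covariance()

    def omega(self) -> np.ndarray:
        L = corr_chol_from_y(self.y, self.D)
        return L @ L.T

    def responsibilities(self) -> np.ndarray:
        """Posterior P(careless | data, params) per person at the current state."""
        from scipy.special import log_expit

        return np.exp(log_expit(-self.logit_pi) + self.C - self.mix)

    def log_posterior(self) -> float:
        pr, sd, hc = self.pr, self.pr.normal_sd, self.pr.half_cauchy_scale
        lp = float(self.mix.sum()) + float(self.person_logprior().sum())
        lp += float(self.pi_logprior().sum())
        piP = expit(self.logit_piP)
        lp += float(np.log(piP) + np.log1p(-piP))  # uniform prior + Jacobian
        lp += float(half_cauchy_logpdf(np.exp(self.loglam), hc)) + self.loglam
        v = np.exp(self.logv)
        lp += float(half_cauchy_logpdf(v, hc).sum() + self.logv.sum())
        lp += float(norm.logpdf(self.b, 0, sd).sum())
        lp += float(norm.logpdf(self.bstar_s, 0, sd).sum())
        lp += float(norm.logpdf(self.gamma, 0, sd) + norm.logpdf(self.beta_C, 0, sd))
        for ls in (self.lsA, self.lsC, self.lstau):
            lp += float(half_cauchy_logpdf(np.exp(ls), hc)) + ls
        kappa = self.kappa
        lp += float((pr.dirichlet_kappa - 1) * np.sum(np.log(kappa)))
        lp += simplex_logjac(kappa)
        lp += lkj_cpc_logprior(self.y, self.D, pr.lkj_shape)
        return lp




def fit_screen_model(data: ScreenLevelData, priors: PriorConfig | None = None,
                     mcmc: McmcConfig | None = None) -> PosteriorResult:
    """Fit the screen-level model by MCMC.

    Per-person careless probabilities are the posterior means of the
    mixture responsibilities (conditioning on each person's full data),
    not of ``1 - pi_i`` alone.
    """
    priors = priors or PriorConfig()
    mcmc = mcmc or McmcConfig()
    d = _ScreenData(data)

    n_keep = mcmc.iterations - mcmc.warmup
    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.chains)
    all_draws: list[dict] = []
    resp_draws = np.zeros((mcmc.chains, n_keep, d.N), dtype=np.float32)
    for c in range(mcmc.chains):
        rng = np.random.default_rng(seeds[c])
        smp = _ScreenSampler(d, priors, mcmc, rng)
        chain: dict[str, list] = {}
        for it in range(mcmc.iterations):
            smp.iterate()
            if it >= mcmc.warmup:
                k = it - mcmc.warmup
                rec = {
                    "gamma": smp.gamma, "beta_C": smp.beta_C,
                    "sigma_A": smp.sigma_A, "sigma_C": smp.sigma_C,
                    "sigma_tau": float(np.exp(smp.lstau)),
                    "pi_pop": float(expit(smp.logit_piP)),
                    "lambda": float(np.exp(smp.loglam)),
                    "kappa": smp.kappa, "omega": smp.omega(),
                    "v": np.exp(smp.logv), "b": smp.b.copy(),
                    "beta_star_screen": smp.bstar_s.copy(),
                    "persons": smp.P.astype(np.float32),
                    "pi": expit(smp.logit_pi).astype(np.float32),
                }
                for key, val in rec.items():
                    chain.setdefault(key, []).append(val)
                resp_draws[c, k] = smp.responsibilities()
        all_draws.append({key: np.asarray(val) for key, val in chain.items()})

    draws = {
        key: np.stack([ch[key] for ch in all_draws], axis=0)
        for key in all_draws[0]
    }
    draws["p_cier_draws"] = resp_draws

    rhat_input = {k: v for k, v in draws.items()
                  if k not in ("p_cier_draws", "pi")}
    rhats = split_rhat_all(rhat_input)
    psrf_series = _flatten_rhats(rhats, d)
    max_psrf = float(psrf_series.max())

    p_cier = resp_draws.reshape(-1, d.N).mean(axis=0)
    rates = {
        "overall": float(p_cier.mean()),
        "population": float(1.0 - np.median(draws["pi_pop"])),
        "hard_overall": float((p_cier > 0.5).mean()),
    }

    summaries = _summaries(draws, d)
    return PosteriorResult(
        draws=draws, summaries=summaries, psrf=psrf_series, p_cier=p_cier,
        rates=rates, converged=bool(max_psrf < mcmc.psrf_threshold),
        max_psrf=max_psrf, person_ids=d.person_ids, screen_ids=d.screen_ids,
        meta={"model": "screen", "psrf_threshold": mcmc.psrf_threshold,
              "chains": mcmc.chains, "iterations": mcmc.iterations,
              "warmup": mcmc.warmup, "seed": mcmc.seed},
    )
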