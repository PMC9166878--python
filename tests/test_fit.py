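"""Tests for the MCMC machinery and small-scale fitter behavior.

Full-scale parameter recovery lives in test_acceptance.py; here the fits
are small and fast and check structural properties: PSRF correctness,
log-posterior decomposition against the enumeration oracle, classification
bounds, prior reproduction, and permutation invariance.
"""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import beta as beta_dist
from scipy.stats import kstest, norm

import ciermix as cm
from ciermix._mcmc import corr_chol_from_y, lkj_cpc_logprior, simplex_from_z
from ciermix.fit_item import _ItemData, _ItemSampler
from ciermix.fit_screen import _ScreenData, _ScreenSampler
from ciermix.model_core import ObservationRecord


class TestPsrf:
    def test_identical_chains_give_one(self):
        x = np.sin(np.arange(200.0))
        assert cm.psrf(np.stack([x, x])) == pytest.approx(1.0, abs=1e-8)

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 400)
        b = rng.normal(10, 1, 400)
        assert cm.psrf(np.stack([a, b])) > 1.10

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            cm.psrf(np.ones((1, 100)))

    def test_matches_textbook_formula(self):
        # independent split-R-hat implementation, written from the formula
        rng = np.random.default_rng(1)
        draws = rng.normal(size=(3, 200)) + np.array([[0.0], [0.1], [0.3]])
        m, n = draws.shape
        half = n // 2
        split = np.concatenate([draws[:, :half], draws[:, half:]], axis=0)
        mm, nn = split.shape
        means = split.mean(axis=1)
        W = split.var(axis=1, ddof=1).mean()
        B = nn * means.var(ddof=1)
        expected = np.sqrt(((nn - 1) / nn * W + B / nn) / W)
        assert cm.psrf(draws) == pytest.approx(expected, abs=1e-8)


class TestConstrainedTransforms:
    def test_simplex_roundtrip_and_normalization(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            z = rng.normal(0, 3, size=4)
            k = simplex_from_z(z)
            assert k.sum() == pytest.approx(1.0, abs=1e-12)
            assert (k > 0).all()

    def test_corr_chol_valid_for_extreme_inputs(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            y = rng.normal(0, 5, size=6)
            L = corr_chol_from_y(y, 4)
            Om = L @ L.T
            assert np.allclose(np.diag(Om), 1.0, atol=1e-9)
            assert np.all(np.linalg.eigvalsh(Om) > -1e-12)

    def test_lkj_marginal_of_single_correlation(self):
        # under LKJ(1) in dimension d, each correlation has marginal
        # Beta(d/2, d/2) stretched to (-1, 1); check via MH sampling of y
        rng = np.random.default_rng(4)
        d = 3
        n_y = d * (d - 1) // 2
        y = np.zeros(n_y)
        lp = lkj_cpc_logprior(y, d)
        draws = []
        for it in range(20000):
            prop = y + 0.8 * rng.standard_normal(n_y)
            lp_new = lkj_cpc_logprior(prop, d)
            if np.log(rng.random()) < lp_new - lp:
                y, lp = prop, lp_new
            if it % 10 == 0:
                L = corr_chol_from_y(y, d)
                draws.append((L @ L.T)[1, 0])
        u = (np.asarray(draws[200:]) + 1) / 2
        stat = kstest(u, beta_dist(d / 2, d / 2).cdf)
        assert stat.pvalue > 0.01


def _tiny_dataset(N=3, seed=5):
    cfg = cm.SimConfig(N=N, S=2, J=(3, 2), seed=seed, target_cier_rate=0.2)
    return cm.simulate_dataset(cfg)


class TestItemSamplerInternals:
    def test_incremental_caches_match_full_refresh(self):
        ds, _ = _tiny_dataset(N=25)
        d = _ItemData(ds)
        smp = _ItemSampler(d, cm.PriorConfig(),
                           cm.McmcConfig(chains=2, iterations=50, seed=0),
                           np.random.default_rng(1))
        for _ in range(5):
            smp.iterate()
        mix = smp.mix.copy()
        smp.refresh_all()
        assert np.allclose(mix, smp.mix, atol=1e-10)

    def test_log_posterior_decomposition_oracle(self, toy_globals):
        """Likelihood part of the log-posterior equals the enumeration oracle."""
        ds, truth = _tiny_dataset(N=3)
        d = _ItemData(ds)
        smp = _ItemSampler(d, cm.PriorConfig(),
                           cm.McmcConfig(chains=2, iterations=50, seed=0),
                           np.random.default_rng(2))
        # oracle: sum of per-person-screen mixture logliks at the sampler state
        g = cm.GlobalParams(beta_C=smp.beta_C, sigma_C=smp.sigma_C,
                            sigma_A=smp.sigma_A, gamma=smp.gamma,
                            kappa=smp.kappa, Sigma=np.eye(4), K=d.K, S=d.S)
        items = [
            cm.ItemParams(iid, d.screen_ids[d.screen_of_item[k]],
                          v=float(np.exp(smp.logv[k])), b=smp.b[k].copy(),
                          beta_star=float(smp.bstar[k]))
            for k, iid in enumerate(d.item_ids)
        ]
        total = 0.0
        for i, pid in enumerate(d.person_ids):
            person = cm.PersonParams(pid, psi=smp.P[i, 0], tau=smp.P[i, 1],
                                     eta=smp.P[i, 2:])
            for s, sid in enumerate(d.screen_ids):
                screen = cm.ScreenParams(sid, iota=float(smp.iota[s]),
                                         trait_index=s,
                                         items=[it.item_id for it in items
                                                if it.screen_id == sid])
                obs = []
                sub = ds.df[(ds.df.person_id == pid) & (ds.df.screen_id == sid)]
                for r in sub.itertuples():
                    obs.append(ObservationRecord(
                        pid, r.item_id, sid,
                        x=None if r.d_x else int(r.x),
                        t=None if r.d_t else float(r.t),
                        d_x=int(r.d_x), d_t=int(r.d_t)))
                total += cm.screen_mixture_loglik_item(
                    obs, person, screen,
                    [it for it in items if it.screen_id == sid], g)
        assert float(smp.mix.sum()) == pytest.approx(total, abs=1e-8)

    def test_classification_bounds_and_prior_reproduction(self):
        ds, _ = _tiny_dataset(N=20)
        res = cm.fit_item_model(ds, mcmc=cm.McmcConfig(chains=2, iterations=200,
                                                       seed=9))
        p = cm.classify_attentiveness(res)
        assert ((p >= 0) & (p <= 1)).all()

    def test_fully_missing_screen_reproduces_prior(self):
        # a person-screen with everything missing: posterior P(delta=0)
        # equals the posterior mean of 1 - logistic(psi - iota)
        ds, _ = _tiny_dataset(N=15)
        df = ds.df.copy()
        mask = (df.person_id == ds.person_ids[0]) & (df.screen_id == "s1")
        df.loc[mask, ["x", "t"]] = np.nan
        df.loc[mask, ["d_x", "d_t"]] = 1
        ds2 = cm.ResponseDataset(df=df, items=ds.items, screens=ds.screens,
                                 reading_time=ds.reading_time)
        res = cm.fit_item_model(ds2, mcmc=cm.McmcConfig(chains=2, iterations=300,
                                                        seed=10))
        psis = res.draws["persons"][:, :, 0, 0].astype(float)  # person 0 psi
        iotas = res.draws["iota"][:, :, 0]
        prior_p0 = float(np.mean(1 - expit(psis - iotas)))
        assert res.p_cier[0, 0] == pytest.approx(prior_p0, abs=1e-3)

    def test_beta_star_nonnegative_draws(self):
        ds, _ = _tiny_dataset(N=10)
        res = cm.fit_item_model(ds, mcmc=cm.McmcConfig(chains=2, iterations=150,
                                                       seed=11))
        assert (res.draws["beta_star"] >= 0).all()
        # trait variances are fixed at one by construction
        om = res.draws["omega"]
        assert np.allclose(om[..., 2, 2], 1.0) and np.allclose(om[..., 3, 3], 1.0)

    def test_relabeling_invariance(self):
        """Classification depends on data only, never on id strings.

        Renaming screens and items (order preserved) must reproduce the
        posterior bit for bit: labels are opaque to the sampler.
        """
        ds, _ = _tiny_dataset(N=12, seed=8)
        res_a = cm.fit_item_model(ds, mcmc=cm.McmcConfig(chains=2,
                                                         iterations=200, seed=3))
        smap = {"s1": "screenA", "s2": "screenB"}
        imap = {it.item_id: f"item_{it.item_id}" for it in ds.items}
        df = ds.df.copy()
        df["screen_id"] = df["screen_id"].map(smap)
        df["item_id"] = df["item_id"].map(imap)
        items = [cm.ItemParams(imap[it.item_id], smap[it.screen_id], v=it.v,
                               b=it.b.copy(), beta_star=it.beta_star)
                 for it in ds.items]
        screens = [cm.ScreenParams(smap[sc.screen_id], iota=sc.iota,
                                   trait_index=sc.trait_index,
                                   items=[imap[i] for i in sc.items])
                   for sc in ds.screens]
        ds_b = cm.ResponseDataset(df=df, items=items, screens=screens,
                                  reading_time=ds.reading_time)
        res_b = cm.fit_item_model(ds_b, mcmc=cm.McmcConfig(chains=2,
                                                           iterations=200, seed=3))
        assert np.array_equal(res_a.p_cier, res_b.p_cier)

    def test_error_contracts(self):
        ds, _ = _tiny_dataset(N=5)
        bad = ds.df.copy()
        bad.loc[bad.index[0], "t"] = -1.0
        ds_bad = cm.ResponseDataset(df=bad, items=ds.items, screens=ds.screens)
        with pytest.raises(ValueError):
            cm.fit_item_model(ds_bad,
                              mcmc=cm.McmcConfig(chains=2, iterations=50, seed=0))
        with pytest.raises(ValueError):
            cm.McmcConfig(chains=1, iterations=100, seed=0)


class TestScreenSamplerInternals:
    def _screen_data(self, N=20, seed=6):
        cfg = cm.SimConfig(N=N, S=2, J=(3, 2), seed=seed, target_cier_rate=0.2)
        ds, truth = cm.simulate_dataset(cfg)
        tt = cm.compute_timing_measures(ds)
        return cm.ScreenLevelData.from_dataset(ds, tt, "tt_per_item"), truth

    def test_incremental_caches_match_full_refresh(self):
        sdata, _ = self._screen_data()
        d = _ScreenData(sdata)
        smp = _ScreenSampler(d, cm.PriorConfig(),
                             cm.McmcConfig(chains=2, iterations=50, seed=0),
                             np.random.default_rng(4))
        for _ in range(5):
            smp.iterate()
        mix = smp.mix.copy()
        smp.refresh_all()
        assert np.allclose(mix, smp.mix, atol=1e-10)

    def test_log_posterior_against_personlevel_oracle(self):
        """Sampler mixture loglik equals the person-level enumeration oracle."""
        sdata, _ = self._screen_data(N=2, seed=12)
        d = _ScreenData(sdata)
        smp = _ScreenSampler(d, cm.PriorConfig(),
                             cm.McmcConfig(chains=2, iterations=50, seed=0),
                             np.random.default_rng(5))
        g = cm.GlobalParams(beta_C=smp.beta_C, sigma_C=smp.sigma_C,
                            sigma_A=smp.sigma_A, gamma=smp.gamma,
                            kappa=smp.kappa, Sigma=np.eye(4), K=d.K, S=d.S)
        v_dot, o_dot = smp.aggregates()
        items = [cm.ItemParams(iid, d.screen_ids[d.screen_of_item[k]],
                               v=float(np.exp(smp.logv[k])), b=smp.b[k].copy())
                 for k, iid in enumerate(d.item_ids)]
        screens = [cm.ScreenParams(sid, iota=0.0, trait_index=s,
                                   items=[it.item_id for it in items
                                          if it.screen_id == sid],
                                   beta_star_screen=float(smp.bstar_s[s]),
                                   v_dot=float(v_dot[s]), o_dot=float(o_dot[s]))
                   for s, sid in enumerate(d.screen_ids)]
        total = 0.0
        df = sdata.dataset.df
        tbar = sdata.t_bar.set_index(["person_id", "screen_id"])["t_bar"]
        for i, pid in enumerate(d.person_ids):
            person = cm.PersonParams(pid, psi=None, tau=smp.P[i, 0],
                                     eta=smp.P[i, 1:])
            obs = []
            seen = set()
            for r in df[df.person_id == pid].itertuples():
                tb = float(tbar.loc[(pid, r.screen_id)]) \
                    if r.screen_id not in seen else None
                seen.add(r.screen_id)
                obs.append(ObservationRecord(
                    pid, r.item_id, r.screen_id,
                    x=None if r.d_x else int(r.x),
                    t=None, d_x=int(r.d_x), d_t=1, t_bar=tb))
            total += cm.screenlevel_mixture_loglik(
                obs, person, screens, items, g,
                pi_i=float(expit(smp.logit_pi[i])))
        assert float(smp.mix.sum()) == pytest.approx(total, abs=1e-8)

    def test_pi_draws_bounded_and_shrinkage(self):
        sdata, _ = self._screen_data(N=25, seed=13)
        res = cm.fit_screen_model(sdata,
                                  mcmc=cm.McmcConfig(chains=2, iterations=300,
                                                     seed=14))
        pi = res.draws["pi"]
        assert ((pi >= 0) & (pi <= 1)).all()
        assert ((res.p_cier >= 0) & (res.p_cier <= 1)).all()
        # monotone shrinkage: larger concentration pulls pi_i toward pi_P
        lam = res.draws["lambda"].ravel()
        piP = res.draws["pi_pop"].ravel()
        spread = pi.reshape(-1, pi.shape[-1]).std(axis=1)
        hi = lam > np.median(lam)
        assert spread[hi].mean() < spread[~hi].mean() + 0.05

    def test_all_attentive_boundary(self):
        cfg = cm.SimConfig(N=60, seed=15, iota=(-40.0, -40.0))
        ds, _ = cm.simulate_dataset(cfg)
        tt = cm.compute_timing_measures(ds)
        sdata = cm.ScreenLevelData.from_dataset(ds, tt, "tt_per_item")
        res = cm.fit_screen_model(sdata,
                                  mcmc=cm.McmcConfig(chains=2, iterations=400,
                                                     seed=16))
        assert res.rates["population"] < 0.05


class TestScreenAggregates:
    def test_identical_items(self):
        items = [cm.ItemParams("a", "s", v=1.7, b=[-0.2, 0.1, 0.9])] * 3
        v_dot, o_dot = cm.screen_aggregates(items)
        assert v_dot == pytest.approx(1.7)
        assert o_dot == pytest.approx(0.1)

    def test_log_space_identity_random_items(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            items = [cm.ItemParams(f"i{k}", "s", v=float(rng.uniform(0.2, 3)),
                                   b=rng.normal(0, 1, 3))
                     for k in range(rng.integers(2, 8))]
            v_dot, _ = cm.screen_aggregates(items)
            alt = np.exp(np.mean([np.log(it.v) for it in items]))
            assert v_dot == pytest.approx(alt, abs=1e-12)
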