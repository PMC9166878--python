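"""Unit and oracle tests for the density/probability components."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import expit
from scipy.stats import norm

import ciermix as cm
from ciermix.model_core import ObservationRecord


def gpcm_bruteforce(eta, v, b):
    """Direct loop evaluation of the partial-credit category probabilities."""
    K = len(b)
    num = []
    for k in range(K + 1):
        tot = 0.0
        for l in range(1, k + 1):
            tot += v * eta - b[l - 1]
        num.append(np.exp(tot))
    num = np.array(num)
    return num / num.sum()


class TestGpcm:
    def test_symmetric_two_category(self):
        item = cm.ItemParams("i", "s", v=1.0, b=[0.0])
        assert np.allclose(cm.gpcm_category_probs(0.0, item), [0.5, 0.5])

    @pytest.mark.parametrize("eta", [-2.0, 0.0, 0.7, 3.5])
    @pytest.mark.parametrize("v,b", [
        (1.3, [-1.0, 0.2, 1.1]),
        (0.5, [0.3]),
        (2.0, [-2.0, -0.5, 0.5, 2.0]),
    ])
    def test_matches_bruteforce_and_normalizes(self, eta, v, b):
        item = cm.ItemParams("i", "s", v=v, b=np.array(b))
        p = cm.gpcm_category_probs(eta, item)
        assert np.allclose(p, gpcm_bruteforce(eta, v, b), atol=1e-12)
        assert abs(p.sum() - 1.0) < 1e-12
        assert (p >= 0).all()

    def test_monotone_in_eta_for_top_category(self):
        item = cm.ItemParams("i", "s", v=1.1, b=[-0.5, 0.3, 0.9])
        grid = np.linspace(-4, 4, 41)
        top = np.array([cm.gpcm_category_probs(e, item)[-1] for e in grid])
        assert (np.diff(top) > 0).all()

    def test_nonfinite_eta_rejected(self, toy_item):
        with pytest.raises(ValueError):
            cm.gpcm_category_probs(np.nan, toy_item)


class TestMiddleStepDifficulty:
    @pytest.mark.parametrize("b,expected", [
        ([-1, 0.3, 2], 0.3),     # four categories: o = b_2
        ([5], 5.0),
        ([-1, 1], 0.0),          # even number of steps: central mean
        ([0, 1, 2, 3], 1.5),
    ])
    def test_values(self, b, expected):
        assert cm.middle_step_difficulty(b) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cm.middle_step_difficulty([])


class TestAttentiveLogrtMean:
    def test_distance_term_off(self, toy_globals):
        g = toy_globals
        item = cm.ItemParams("i", "s1", v=1.0, b=[0.0], beta_star=0.5)
        person = cm.PersonParams("p", psi=0.0, tau=0.0, eta=[2.7, 0.0])
        mu = cm.attentive_logrt_mean(
            person, item, cm.GlobalParams(beta_C=1.0, sigma_C=g.sigma_C,
                                          sigma_A=g.sigma_A, gamma=0.0,
                                          kappa=np.full(2, 0.5), Sigma=g.Sigma,
                                          K=1, S=2))
        assert mu == pytest.approx(1.5)

    def test_distance_slows_then_shrinks_rt(self, toy_globals, toy_item):
        # per unit of |v*eta - o| the expected RT scale changes by exp(-gamma)
        p0 = cm.PersonParams("p", psi=0.0, tau=0.0,
                             eta=[toy_item.o / toy_item.v, 0.0])
        p1 = cm.PersonParams("p", psi=0.0, tau=0.0,
                             eta=[(toy_item.o + 1.0) / toy_item.v, 0.0])
        mu0 = cm.attentive_logrt_mean(p0, toy_item, toy_globals)
        mu1 = cm.attentive_logrt_mean(p1, toy_item, toy_globals)
        assert np.exp(mu1 - mu0) == pytest.approx(np.exp(-0.04))

    def test_monte_carlo_mean(self, toy_globals, toy_item):
        rng = np.random.default_rng(42)
        person = cm.PersonParams("p", psi=0.0, tau=0.3, eta=[0.8, 0.0])
        mu = cm.attentive_logrt_mean(person, toy_item, toy_globals)
        draws = rng.normal(mu, toy_globals.sigma_A, size=100_000)
        se = toy_globals.sigma_A / np.sqrt(draws.size)
        assert abs(draws.mean() - mu) < 3 * se


class TestCierLogrt:
    def test_median_is_exp_beta(self):
        # CDF at exp(beta_C) is one half: the lognormal median
        beta_C, sigma_C = 0.74, 0.6
        med = np.exp(beta_C)
        assert med == pytest.approx(2.0959, abs=1e-3)  # ~2.10 s
        cdf = quad(lambda t: np.exp(cm.cier_logrt_logdensity(t, beta_C, sigma_C)),
                   1e-9, med)[0]
        assert cdf == pytest.approx(0.5, abs=1e-6)

    def test_integrates_to_one(self):
        val = quad(lambda t: np.exp(cm.cier_logrt_logdensity(t, 0.74, 0.883)),
                   1e-12, np.inf)[0]
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_nonpositive_t_rejected(self):
        with pytest.raises(ValueError):
            cm.cier_logrt_logdensity(0.0, 0.5, 1.0)

    def test_representation_invariance(self):
        t = 3.7
        a = cm.cier_logrt_logdensity(t, 0.5, 0.9)
        b = cm.cier_logrt_logdensity(np.exp(np.log(t)), 0.5, 0.9)
        assert a == b


class TestAttentivenessProb:
    def test_symmetry_and_limits(self):
        assert cm.attentiveness_prob(1.3, 1.3) == pytest.approx(0.5)
        assert cm.attentiveness_prob(800.0, 0.0) == 1.0
        assert cm.attentiveness_prob(-800.0, 0.0) == 0.0

    def test_high_precision_value(self):
        # logistic(5.48) computed with mpmath-free high-precision formula
        expected = 1.0 / (1.0 + np.exp(-5.48))
        assert cm.attentiveness_prob(2.74, -2.74) == pytest.approx(
            expected, abs=1e-15)


def _make_obs(xs, ts, items):
    out = []
    for it, x, t in zip(items, xs, ts):
        out.append(ObservationRecord(
            person_id="p", item_id=it.item_id, screen_id=it.screen_id,
            x=x, t=t, d_x=int(x is None), d_t=int(t is None)))
    return out


class TestItemMixtureLoglik:
    def setup_method(self):
        self.items = [
            cm.ItemParams(f"i{j}", "s1", v=1.0 + 0.2 * j,
                          b=np.array([-1.0, 0.0, 1.0]) + 0.1 * j,
                          beta_star=0.3 * j)
            for j in range(3)
        ]
        self.screen = cm.ScreenParams("s1", iota=-1.0, trait_index=0,
                                      items=[it.item_id for it in self.items])

    def test_fully_missing_screen_is_zero(self, toy_globals):
        person = cm.PersonParams("p", psi=0.4, tau=0.1, eta=[0.5, 0.0])
        obs = _make_obs([None] * 3, [None] * 3, self.items)
        ll = cm.screen_mixture_loglik_item(obs, person, self.screen,
                                           self.items, toy_globals)
        assert ll == pytest.approx(0.0, abs=1e-12)

    def test_collapsed_mixture(self):
        # degenerate kappa on the observed category, gamma=0, identical RT laws
        g = cm.GlobalParams(beta_C=0.7, sigma_C=0.5, sigma_A=0.5, gamma=0.0,
                            kappa=np.array([1e-12, 1 - 3e-12, 1e-12, 1e-12]),
                            Sigma=cm.default_sigma(2), K=3, S=2)
        item = cm.ItemParams("i0", "s1", v=1.0, b=[-1.0, 0.0, 1.0], beta_star=0.0)
        screen = cm.ScreenParams("s1", iota=0.0, trait_index=0, items=["i0"])
        person = cm.PersonParams("p", psi=0.0, tau=0.0, eta=[0.0, 0.0])
        # choose the response kappa concentrates on and skip RT, so both
        # components carry the same density when the GPCM prob matches kappa
        obs = _make_obs([1], [None], [item])
        ll = cm.screen_mixture_loglik_item(obs, person, screen, [item], g)
        p_att = cm.gpcm_category_probs(0.0, item)[1]
        expected = np.log(0.5 * p_att + 0.5 * (1 - 3e-12))
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_enumeration_oracle(self, toy_globals):
        # explicit enumeration of delta in {0, 1} with plain float products
        rng = np.random.default_rng(7)
        for person in [
            cm.PersonParams("a", psi=0.3, tau=-0.2, eta=[0.9, 0.0]),
            cm.PersonParams("b", psi=-1.1, tau=0.4, eta=[-0.6, 0.0]),
        ]:
            xs = rng.integers(0, 4, size=3).tolist()
            ts = np.exp(rng.normal(1.0, 0.5, size=3)).tolist()
            obs = _make_obs(xs, ts, self.items)
            ll = cm.screen_mixture_loglik_item(obs, person, self.screen,
                                               self.items, toy_globals)
            p1 = expit(person.psi - self.screen.iota)
            att = 1.0
            cier = 1.0
            for it, x, t in zip(self.items, xs, ts):
                att *= gpcm_bruteforce(person.eta[0], it.v, it.b)[x]
                mu = (toy_globals.beta_C + it.beta_star) - person.tau \
                    - toy_globals.gamma * abs(it.v * person.eta[0] - it.o)
                att *= norm.pdf(np.log(t), mu, toy_globals.sigma_A) / t
                cier *= toy_globals.kappa[x]
                cier *= norm.pdf(np.log(t), toy_globals.beta_C,
                                 toy_globals.sigma_C) / t
            assert ll == pytest.approx(np.log(p1 * att + (1 - p1) * cier),
                                       abs=1e-10)

    def test_unknown_item_rejected(self, toy_globals):
        person = cm.PersonParams("p", psi=0.0, tau=0.0, eta=[0.0, 0.0])
        obs = [ObservationRecord(person_id="p", item_id="ghost",
                                 screen_id="s1", x=1, t=None, d_x=0, d_t=1)]
        with pytest.raises(KeyError):
            cm.screen_mixture_loglik_item(obs, person, self.screen,
                                          self.items, toy_globals)


class TestScreenLevelModel:
    def test_single_item_aggregation_identity(self, toy_globals, toy_item):
        person = cm.PersonParams("p", psi=None, tau=0.2, eta=[0.7, 0.0])
        screen = cm.ScreenParams("s1", iota=0.0, trait_index=0,
                                 items=[toy_item.item_id],
                                 beta_star_screen=toy_item.beta_star,
                                 v_dot=toy_item.v, o_dot=toy_item.o)
        mu_screen = cm.screenlevel_logrt_mean(person.tau, 0.7, screen, toy_globals)
        person_full = cm.PersonParams("p", psi=0.0, tau=0.2, eta=[0.7, 0.0])
        mu_item = cm.attentive_logrt_mean(person_full, toy_item, toy_globals)
        assert mu_screen == pytest.approx(mu_item)

    def test_stated_means(self):
        items = [cm.ItemParams("a", "s", v=2.0, b=[-1.0]),
                 cm.ItemParams("b", "s", v=8.0, b=[3.0])]
        v_dot, o_dot = cm.screen_aggregates(items)
        assert v_dot == pytest.approx(4.0)
        assert o_dot == pytest.approx(1.0)

    def test_scalar_oracle(self, toy_globals):
        screen = cm.ScreenParams("s1", iota=0.0, trait_index=0, items=["x"],
                                 beta_star_screen=0.25, v_dot=1.2, o_dot=0.4)
        mu = cm.screenlevel_logrt_mean(0.3, 0.9, screen, toy_globals)
        # independent scalar arithmetic
        expected = (0.74 + 0.25) - 0.3 - 0.04 * abs(1.2 * 0.9 - 0.4)
        assert mu == pytest.approx(expected, abs=1e-12)

    def test_personlevel_mixture_boundaries_and_oracle(self, toy_globals):
        items = [cm.ItemParams("i0", "s1", v=1.0, b=[-1.0, 0.0, 1.0]),
                 cm.ItemParams("i1", "s2", v=1.4, b=[-0.5, 0.1, 0.8])]
        screens = [
            cm.ScreenParams("s1", iota=0.0, trait_index=0, items=["i0"],
                            beta_star_screen=0.2, v_dot=1.0, o_dot=0.0),
            cm.ScreenParams("s2", iota=0.0, trait_index=1, items=["i1"],
                            beta_star_screen=0.1, v_dot=1.4, o_dot=0.1),
        ]
        person = cm.PersonParams("p", psi=None, tau=0.1, eta=[0.4, -0.3])
        obs = [
            ObservationRecord("p", "i0", "s1", x=2, t=None, d_x=0, d_t=1,
                              t_bar=2.5),
            ObservationRecord("p", "i1", "s2", x=0, t=None, d_x=0, d_t=1,
                              t_bar=3.1),
        ]

        def comp(attentive):
            tot = 1.0
            for ob, sc, it in zip(obs, screens, items):
                eta = person.eta[sc.trait_index]
                if attentive:
                    tot *= gpcm_bruteforce(eta, it.v, it.b)[ob.x]
                    mu = (toy_globals.beta_C + sc.beta_star_screen) - person.tau \
                        - toy_globals.gamma * abs(sc.v_dot * eta - sc.o_dot)
                    tot *= norm.pdf(np.log(ob.t_bar), mu,
                                    toy_globals.sigma_A) / ob.t_bar
                else:
                    tot *= toy_globals.kappa[ob.x]
                    tot *= norm.pdf(np.log(ob.t_bar), toy_globals.beta_C,
                                    toy_globals.sigma_C) / ob.t_bar
            return tot

        ll_att = cm.screenlevel_mixture_loglik(obs, person, screens, items,
                                               toy_globals, pi_i=1.0)
        assert ll_att == pytest.approx(np.log(comp(True)), abs=1e-10)
        ll_cier = cm.screenlevel_mixture_loglik(obs, person, screens, items,
                                                toy_globals, pi_i=0.0)
        assert ll_cier == pytest.approx(np.log(comp(False)), abs=1e-10)
        for pi in (0.3, 0.85):
            ll = cm.screenlevel_mixture_loglik(obs, person, screens, items,
                                               toy_globals, pi_i=pi)
            assert ll == pytest.approx(
                np.log(pi * comp(True) + (1 - pi) * comp(False)), abs=1e-10)

    def test_bad_pi_rejected(self, toy_globals):
        with pytest.raises(ValueError):
            cm.screenlevel_mixture_loglik([], cm.PersonParams("p", tau=0, eta=[0]),
                                          [], [], toy_globals, pi_i=1.2)


class TestMarginalCierRate:
    def test_degenerate_and_limits(self):
        assert cm.marginal_cier_rate_for_screen(0.0, 1e-9) == pytest.approx(0.5, abs=1e-6)
        assert cm.marginal_cier_rate_for_screen(-40.0, 1.0) < 1e-10

    def test_monte_carlo_oracle(self):
        rng = np.random.default_rng(3)
        iota, sigma = -2.74, np.sqrt(1.98)
        psi = rng.normal(0, sigma, size=1_000_000)
        mc = expit(iota - psi)
        est = mc.mean()
        se = mc.std() / np.sqrt(mc.size)
        assert abs(cm.marginal_cier_rate_for_screen(iota, sigma) - est) < 3 * se


class TestParamContainers:
    def test_item_invariants(self):
        with pytest.raises(ValueError):
            cm.ItemParams("i", "s", v=-1.0, b=[0.0])
        with pytest.raises(ValueError):
            cm.ItemParams("i", "s", v=1.0, b=[0.0], beta_star=-0.1)

    def test_beta_exceeds_beta_C(self, toy_globals, small_dataset):
        # beta_js = beta_C + beta*_js >= beta_C by construction
        ds, truth = small_dataset
        for it in truth.items:
            assert truth.g.beta_C + it.beta_star >= truth.g.beta_C

    def test_global_invariants(self):
        with pytest.raises(ValueError):
            cm.GlobalParams(beta_C=0.0, sigma_C=-1.0, sigma_A=0.5, gamma=0.0,
                            kappa=np.array([0.5, 0.5]), Sigma=np.eye(4), K=1, S=2)
        with pytest.raises(ValueError):
            cm.GlobalParams(beta_C=0.0, sigma_C=1.0, sigma_A=0.5, gamma=0.0,
                            kappa=np.array([0.6, 0.6]), Sigma=np.eye(4), K=1, S=2)

    def test_observation_record_consistency(self):
        with pytest.raises(ValueError):
            ObservationRecord("p", "i", "s", x=1, t=2.0, d_x=1, d_t=0)
        with pytest.raises(ValueError):
            ObservationRecord("p", "i", "s", x=1, t=-2.0, d_x=0, d_t=0)
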