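"""Density and probability components of the careless-responding mixture model.

Two observation modes drive every quantity here. When a respondent approaches
a screen *attentively* (latent indicator ``delta = 1``), ordinal responses
follow a generalized partial credit model (GPCM) in the screen's trait and
log response times are normal around a mean that encodes the
distance--difficulty hypothesis: items well targeted to the respondent's
trait take longer. When the respondent is *careless* (``delta = 0``),
responses follow a content-free category distribution ``kappa`` and response
times are lognormal with a shared mean ``beta_C`` and SD ``sigma_C``.

Everything in this module is a pure function of explicit parameters; the
simulator and the MCMC fitters are built on top of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, log_expit, logsumexp
from scipy.stats import norm

__all__ = [
    "ItemParams",
    "ScreenParams",
    "PersonParams",
    "GlobalParams",
    "AttentivenessState",
    "ObservationRecord",
    "gpcm_category_probs",
    "middle_step_difficulty",
    "attentive_logrt_mean",
    "cier_logrt_logdensity",
    "attentiveness_prob",
    "screen_mixture_loglik_item",
    "screenlevel_logrt_mean",
    "screenlevel_mixture_loglik",
    "marginal_cier_rate_for_screen",
]


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass
class ItemParams:
    """GPCM and response-time parameters of a single item.

    Attributes
    ----------
    item_id, screen_id
        Identifiers; ``screen_id`` ties the item to the screen (= trait)
        it is displayed on.
    v
        Discrimination, ``v > 0``.
    b
        Step difficulties, length ``K`` (categories are coded ``0..K``).
    beta_star
        Non-negative time-intensity offset (log-seconds): how much longer an
        attentive response takes than a careless one, on the log scale.
    """

    item_id: str
    screen_id: str
    v: float
    b: np.ndarray
    beta_star: float = 0.0

    def __post_init__(self) -> None:
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        if self.b.ndim != 1 or self.b.size < 1:
            raise ValueError("b must be a non-empty 1-d vector of step difficulties")
        if not np.isfinite(self.v) or self.v <= 0:
            raise ValueError(f"discrimination v must be positive, got {self.v}")
        if self.beta_star < 0:
            raise ValueError(f"beta_star must be non-negative, got {self.beta_star}")

    @property
    def K(self) -> int:
        """Highest category index (number of categories minus one)."""
        return self.b.size

    @property
    def o(self) -> float:
        """Middle step difficulty, a deterministic function of ``b``."""
        return middle_step_difficulty(self.b)


@dataclass
class ScreenParams:
    """Screen-level parameters: attentiveness difficulty and RT aggregates.

    ``trait_index`` is the 0-based position of the screen's trait in the
    person-parameter vector (one trait per screen).
    """

    screen_id: str
    iota: float
    trait_index: int = 0
    items: list = field(default_factory=list)
    beta_star_screen: float = 0.0
    v_dot: float | None = None
    o_dot: float | None = None

    def __post_init__(self) -> None:
        if self.beta_star_screen < 0:
            raise ValueError("beta_star_screen must be non-negative")
        if self.v_dot is not None and self.v_dot <= 0:
            raise ValueError("v_dot must be positive")


@dataclass
class PersonParams:
    """Latent person parameters: attentiveness, speed and one trait per screen."""

    person_id: str
    tau: float
    eta: np.ndarray
    psi: float | None = None  # absent in the screen-level model

    def __post_init__(self) -> None:
        self.eta = np.atleast_1d(np.asarray(self.eta, dtype=float))


@dataclass
class GlobalParams:
    """Parameters shared across persons and items.

    ``Sigma`` is the covariance of the person-parameter vector
    ``(psi, tau, eta_1, .., eta_S)`` (``(tau, eta_1, .., eta_S)`` in the
    screen-level variant).  For identification the person means are zero and
    the trait variances are one, so ``Sigma = diag(s) @ Omega @ diag(s)``
    with unit entries of ``s`` for the traits.
    """

    beta_C: float
    sigma_C: float
    sigma_A: float
    gamma: float
    kappa: np.ndarray
    Sigma: np.ndarray
    K: int
    S: int

    def __post_init__(self) -> None:
        self.kappa = np.asarray(self.kappa, dtype=float)
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        if self.sigma_C <= 0 or self.sigma_A <= 0:
            raise ValueError("sigma_C and sigma_A must be positive")
        if self.kappa.size != self.K + 1:
            raise ValueError("kappa must have length K + 1")
        if np.any(self.kappa < 0) or abs(self.kappa.sum() - 1.0) > 1e-8:
            raise ValueError("kappa must be a probability vector")
        if not np.allclose(self.Sigma, self.Sigma.T):
            raise ValueError("Sigma must be symmetric")
        # positive-definiteness check; raises LinAlgError if not PD
        np.linalg.cholesky(self.Sigma)

    @property
    def Omega(self) -> np.ndarray:
        """Correlation matrix implied by ``Sigma``."""
        s = np.sqrt(np.diag(self.Sigma))
        return self.Sigma / np.outer(s, s)

    @property
    def mu(self) -> np.ndarray:
        """Person-parameter mean vector (zero, by identification)."""
        return np.zeros(self.Sigma.shape[0])


@dataclass
class AttentivenessState:
    """Latent attentiveness quantities for one model run."""

    delta: np.ndarray | None = None  # (N, S) binary, 1 = attentive
    pi_i: np.ndarray | None = None  # per-person attentive prob (screen model)
    pi_pop: float | None = None  # population proportion attentive
    lambda_conc: float | None = None  # Dirichlet concentration

    def __post_init__(self) -> None:
        if self.delta is not None:
            d = np.asarray(self.delta)
            if not np.isin(d, (0, 1)).all():
                raise ValueError("delta entries must be 0 or 1")
        for p in (self.pi_i, self.pi_pop):
            if p is not None and (np.any(np.asarray(p) < 0) or np.any(np.asarray(p) > 1)):
                raise ValueError("attentiveness probabilities must lie in [0, 1]")


@dataclass
class ObservationRecord:
    """One (person, item) observation: response, RT and missingness flags."""

    person_id: str
    item_id: str
    screen_id: str
    x: int | None = None
    t: float | None = None
    d_x: int = 0
    d_t: int = 0
    t_bar: float | None = None

    def __post_init__(self) -> None:
        if (self.x is None) != bool(self.d_x):
            raise ValueError("d_x = 1 iff x is missing")
        if (self.t is None) != bool(self.d_t):
            raise ValueError("d_t = 1 iff t is missing")
        if self.t is not None and self.t <= 0:
            raise ValueError("observed response times must be positive")


# ---------------------------------------------------------------------------
# Attentive components
# ---------------------------------------------------------------------------


def gpcm_category_probs(eta, item: ItemParams) -> np.ndarray:
    """Category probabilities of an attentive response under the GPCM.

    The cumulative logit of category ``k`` is ``sum_{l=1..k} (v*eta - b_l)``
    with the empty sum for ``k = 0`` equal to zero; probabilities are the
    softmax of these cumulative logits over ``k = 0..K``.

    Parameters
    ----------
    eta
        Trait value(s); scalar or array (vectorized over leading axes).
    item
        Item parameters supplying ``v`` and the step difficulties ``b``.

    Returns
    -------
    numpy.ndarray
        Probabilities over categories ``0..K`` along the last axis; each
        vector sums to one.
    """
    eta = np.asarray(eta, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise ValueError("eta must be finite")
    return _gpcm_probs_arrays(eta, item.v, item.b)


def _gpcm_probs_arrays(eta: np.ndarray, v, b: np.ndarray) -> np.ndarray:
    """Vectorized GPCM kernel on raw arrays (softmax of cumulative logits)."""
    steps = v * eta[..., None] - b  # (.., K)
    cum = np.concatenate(
        [np.zeros(steps.shape[:-1] + (1,)), np.cumsum(steps, axis=-1)], axis=-1
    )
    cum -= cum.max(axis=-1, keepdims=True)
    e = np.exp(cum)
    return e / e.sum(axis=-1, keepdims=True)


def middle_step_difficulty(b) -> float:
    """Middle step difficulty ``o`` of a step-difficulty vector.

    For an odd number of steps this is the middle one (with four response
    categories, i.e. three steps, ``o = b_2``); for an even number it is the
    mean of the two central steps, which reduces to the same convention.
    """
    b = np.atleast_1d(np.asarray(b, dtype=float))
    if b.size == 0:
        raise ValueError("step-difficulty vector must be non-empty")
    n = b.size
    if n % 2 == 1:
        return float(b[n // 2])
    return float(0.5 * (b[n // 2 - 1] + b[n // 2]))


def attentive_logrt_mean(person: PersonParams, item: ItemParams, g: GlobalParams,
                         beta_C: float | None = None, screen_index: int = 0) -> float:
    """Mean of log RT for an attentive response to ``item``.

    Implements the distance--difficulty hypothesis: the log-RT mean is
    ``(beta_C + beta_star) - tau - gamma * |v*eta - o|``, so responses get
    *faster* (by factor ``exp(-gamma)`` per unit) as the item's middle step
    difficulty moves away from the respondent's weighted trait level.  The
    log RT is normal with this mean and SD ``sigma_A``.
    """
    bc = g.beta_C if beta_C is None else beta_C
    eta = float(person.eta[screen_index])
    dist = abs(item.v * eta - item.o)
    return (bc + item.beta_star) - person.tau - g.gamma * dist


def cier_logrt_logdensity(t, beta_C: float, sigma_C: float):
    """Log-density of a careless response time.

    Careless RTs are lognormal with log-mean ``beta_C`` and log-SD
    ``sigma_C`` irrespective of person or item; the density includes the
    ``1/t`` Jacobian so it normalizes over ``t in (0, inf)``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("response times must be positive")
    if sigma_C <= 0:
        raise ValueError("sigma_C must be positive")
    logt = np.log(t)
    out = norm.logpdf(logt, loc=beta_C, scale=sigma_C) - logt
    return float(out) if out.ndim == 0 else out


def _attentive_logrt_logpdf(t, mean, sigma_A):
    """Lognormal log-density of attentive RTs around ``mean`` on the log scale."""
    logt = np.log(t)
    return norm.logpdf(logt, loc=mean, scale=sigma_A) - logt


def attentiveness_prob(psi, iota):
    """Probability of approaching a screen attentively.

    A Rasch model in the respondent's attentiveness ``psi`` and the screen's
    attentiveness difficulty ``iota``: ``logistic(psi - iota)``.  Computed
    via ``scipy.special.expit``, stable for large ``|psi - iota|``.
    """
    psi = np.asarray(psi, dtype=float)
    iota = np.asarray(iota, dtype=float)
    if not (np.all(np.isfinite(psi)) and np.all(np.isfinite(iota))):
        raise ValueError("psi and iota must be finite")
    out = expit(psi - iota)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Mixture likelihoods
# ---------------------------------------------------------------------------


def screen_mixture_loglik_item(obs, person: PersonParams, screen: ScreenParams,
                               items, g: GlobalParams) -> float:
    """Log-likelihood of one person-screen under the item-level mixture.

    The two-component sum over the latent attentiveness indicator::

        log[ p1 * prod_j p(x|GPCM)^(1-d_x) f(t|attentive)^(1-d_t)
             + (1-p1) * prod_j kappa_x^(1-d_x) f(t|careless)^(1-d_t) ]

    with ``p1 = logistic(psi - iota)``, evaluated in log space with
    log-sum-exp.  Missing responses / RTs contribute a factor of one via the
    ``d`` indicators; a fully missing screen yields ``0.0``.

    Parameters
    ----------
    obs
        ``ObservationRecord`` list covering the screen's items for one person.
    items
        ``ItemParams`` for the screen, keyed by ``item_id`` (list or dict).
    """
    if person.psi is None:
        raise ValueError("item-level mixture requires person.psi")
    item_map = {it.item_id: it for it in items} if not isinstance(items, dict) else items
    screen_index = screen.trait_index

    log_att = 0.0
    log_cier = 0.0
    for ob in obs:
        if ob.item_id not in item_map:
            raise KeyError(f"observation references unknown item {ob.item_id!r}")
        it = item_map[ob.item_id]
        if not ob.d_x:
            p_att = gpcm_category_probs(person.eta[screen_index], it)[ob.x]
            log_att += np.log(p_att)
            log_cier += np.log(g.kappa[ob.x])
        if not ob.d_t:
            mu = attentive_logrt_mean(person, it, g, screen_index=screen_index)
            log_att += float(_attentive_logrt_logpdf(ob.t, mu, g.sigma_A))
            log_cier += float(cier_logrt_logdensity(ob.t, g.beta_C, g.sigma_C))

    lp1 = float(log_expit(person.psi - screen.iota))
    lp0 = float(log_expit(screen.iota - person.psi))
    return float(logsumexp([lp1 + log_att, lp0 + log_cier]))


def screenlevel_logrt_mean(tau: float, eta_s: float, screen: ScreenParams,
                           g: GlobalParams, beta_C: float | None = None) -> float:
    """Mean log screen time per item for an attentive person-screen.

    Same structure as the item-level attentive mean, with the item
    discrimination replaced by the screen's geometric-mean discrimination
    ``v_dot`` and the middle step difficulty by the arithmetic mean
    ``o_dot``:  ``(beta_C + beta_star_s) - tau - gamma * |v_dot*eta - o_dot|``.
    """
    if screen.v_dot is None or screen.o_dot is None:
        raise ValueError("screen aggregates v_dot / o_dot must be set")
    bc = g.beta_C if beta_C is None else beta_C
    dist = abs(screen.v_dot * eta_s - screen.o_dot)
    return (bc + screen.beta_star_screen) - tau - g.gamma * dist


def screenlevel_mixture_loglik(obs, person: PersonParams, screens, items,
                               g: GlobalParams, pi_i: float) -> float:
    """Log-likelihood of one person under the screen-level (aggregated) model.

    The mixture is at the *person* level: with probability ``pi_i`` the person
    is attentive on every screen, otherwise careless on every screen::

        log[ pi_i * prod_s A_s  +  (1 - pi_i) * prod_s C_s ]

    where ``A_s`` multiplies the GPCM response probabilities with the
    lognormal density of the mean per-item screen time ``t_bar``, and ``C_s``
    uses ``kappa`` and the careless RT density.
    """
    if not 0.0 <= pi_i <= 1.0:
        raise ValueError("pi_i must lie in [0, 1]")
    item_map = {it.item_id: it for it in items} if not isinstance(items, dict) else items
    screen_map = {sc.screen_id: sc for sc in screens} if not isinstance(screens, dict) else screens

    log_att = 0.0
    log_cier = 0.0
    seen_tbar: set = set()
    for ob in obs:
        sc = screen_map[ob.screen_id]
        s_idx = sc.trait_index
        if not ob.d_x:
            it = item_map[ob.item_id]
            p_att = gpcm_category_probs(person.eta[s_idx], it)[ob.x]
            log_att += np.log(p_att)
            log_cier += np.log(g.kappa[ob.x])
        # t_bar enters once per screen
        if ob.t_bar is not None and ob.screen_id not in seen_tbar:
            seen_tbar.add(ob.screen_id)
            mu = screenlevel_logrt_mean(person.tau, float(person.eta[s_idx]), sc, g)
            log_att += float(_attentive_logrt_logpdf(ob.t_bar, mu, g.sigma_A))
            log_cier += float(cier_logrt_logdensity(ob.t_bar, g.beta_C, g.sigma_C))

    with np.errstate(divide="ignore"):
        terms = []
        if pi_i > 0:
            terms.append(np.log(pi_i) + log_att)
        if pi_i < 1:
            terms.append(np.log1p(-pi_i) + log_cier)
    return float(logsumexp(terms))


# ---------------------------------------------------------------------------
# Reporting utility
# ---------------------------------------------------------------------------


def marginal_cier_rate_for_screen(iota: float, sigma_psi: float, n_nodes: int = 80) -> float:
    """Population careless rate implied by a screen's attentiveness difficulty.

    Integrates ``1 - logistic(psi - iota)`` over ``psi ~ N(0, sigma_psi^2)``
    with Gauss-Hermite quadrature; the inverse mapping (choosing ``iota`` to
    hit a target rate) is used by the simulator.
    """
    if sigma_psi <= 0:
        raise ValueError("sigma_psi must be positive")
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    psi = nodes * sigma_psi
    vals = expit(iota - psi)  # 1 - logistic(psi - iota)
    return float(np.sum(weights * vals) / np.sqrt(2.0 * np.pi))
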