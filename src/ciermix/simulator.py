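"""Synthetic questionnaire data with known careless-responding ground truth.

The generator follows the item-level data-generating model: person
parameters ``(psi, tau, eta_1..eta_S)`` are multivariate normal, per-screen
attentiveness indicators are Bernoulli in ``logistic(psi - iota_s)``,
attentive screens produce GPCM responses with distance--difficulty lognormal
RTs, and careless screens produce one of four content-free response
patterns -- uniform random, endpoint random, straight lining, diagonal
lining -- with RTs drawn from the shared careless lognormal regardless of
pattern.  A lognormal per-screen stem-reading time is added so that
aggregated timing measures (total screen time, time to first response) are
derivable downstream.

Default parameter values resemble the estimates of the empirical analysis
the model was developed on (e.g. ``sigma_psi^2 = 1.98``, trait correlation
``0.43``, ``gamma = 0.04``, ``beta_C = 0.74``, ``sigma_C^2 = 0.78``); all
are overridable through :class:`SimConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model_core import (
    GlobalParams,
    ItemParams,
    PersonParams,
    ScreenParams,
    attentive_logrt_mean,
    attentiveness_prob,
    gpcm_category_probs,
    marginal_cier_rate_for_screen,
)

__all__ = [
    "SimConfig",
    "TruthRecord",
    "ResponseDataset",
    "PATTERNS",
    "default_sigma",
    "iota_for_target_rate",
    "draw_persons",
    "simulate_attentiveness",
    "simulate_attentive_screen",
    "simulate_cier_screen",
    "simulate_dataset",
]

PATTERNS = ("uniform_random", "endpoint_random", "straight_line", "diagonal_line")


def default_sigma(S: int = 2) -> np.ndarray:
    """Person-parameter covariance resembling the empirical estimates.

    Order ``(psi, tau, eta_1, .., eta_S)`` with unit trait variances,
    ``sigma_psi^2 = 1.98`` and ``sigma_tau^2 = 0.11``; correlations are the
    reported ones for the first two traits and taper mildly for any further
    traits.
    """
    d = 2 + S
    corr = np.eye(d)
    base = {  # (row, col): correlation
        (0, 1): 0.05,  # psi-tau
        (0, 2): 0.24,  # psi-eta1
        (0, 3): 0.17,  # psi-eta2
        (1, 2): -0.14,  # tau-eta1
        (1, 3): -0.06,  # tau-eta2
        (2, 3): 0.43,  # eta1-eta2
    }
    for (i, j), r in base.items():
        if i < d and j < d:
            corr[i, j] = corr[j, i] = r
    # additional traits (S > 2): reuse the trait-trait correlation
    for a in range(2, d):
        for b in range(a + 1, d):
            if corr[a, b] == 0:
                corr[a, b] = corr[b, a] = 0.43
            if corr[0, b] == 0:
                corr[0, b] = corr[b, 0] = 0.17
            if corr[1, b] == 0:
                corr[1, b] = corr[b, 1] = -0.06
    sd = np.ones(d)
    sd[0] = np.sqrt(1.98)
    sd[1] = np.sqrt(0.11)
    return np.outer(sd, sd) * corr


@dataclass
class SimConfig:
    """Configuration of one synthetic dataset.

    ``iota`` may be given per screen; when ``None`` it is chosen by
    inverting the marginal careless rate so each screen's population
    C/IER rate equals ``target_cier_rate``.
    """

    N: int = 300
    S: int = 2
    J: tuple = (7, 5)
    n_categories: int = 4
    seed: int = 0  # mandatory; every run is reproducible
    Sigma: np.ndarray | None = None
    iota: tuple | None = None
    target_cier_rate: float = 0.05
    gamma: float = 0.04
    beta_C: float = 0.74
    sigma_C: float = float(np.sqrt(0.78))
    sigma_A: float = 0.5
    kappa: np.ndarray | None = None  # implied by pattern_mix when None
    pattern_mix: tuple = (0.25, 0.25, 0.25, 0.25)
    pattern_per_person: bool = False
    diagonal_descending: bool = False
    items: list | None = None  # explicit ItemParams; generated when None
    v_range: tuple = (0.8, 1.6)
    b_center_range: tuple = (-0.8, 0.8)
    b_spread: float = 1.0
    beta_star_range: tuple = (0.0, 0.7)
    reading_logmean: float = float(np.log(8.0))  # median 8 s stem reading
    reading_logsd: float = 0.35
    miss_x_rate: float = 0.0
    miss_t_rate: float = 0.0

    def __post_init__(self) -> None:
        if len(self.J) != self.S:
            raise ValueError("J must give an item count per screen")
        pm = np.asarray(self.pattern_mix, dtype=float)
        if pm.size != 4 or np.any(pm < 0) or abs(pm.sum() - 1.0) > 1e-8:
            raise ValueError("pattern_mix must be a length-4 probability vector")
        if self.Sigma is None:
            self.Sigma = default_sigma(self.S)
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        if not np.allclose(np.diag(self.Sigma)[2:], 1.0):
            raise ValueError("trait variances must be one (identification)")
        np.linalg.cholesky(self.Sigma)

    @property
    def K(self) -> int:
        return self.n_categories - 1

    @property
    def sigma_psi(self) -> float:
        return float(np.sqrt(self.Sigma[0, 0]))


@dataclass
class TruthRecord:
    """Ground truth of one simulated dataset, for recovery experiments."""

    delta: np.ndarray  # (N, S), 1 = attentive
    patterns: pd.DataFrame  # person_id, screen_id, pattern (careless only)
    persons: list  # true PersonParams
    items: list  # true ItemParams
    screens: list  # true ScreenParams
    g: GlobalParams


@dataclass
class ResponseDataset:
    """Long-format responses and RTs plus the design needed to model them."""

    df: pd.DataFrame  # person_id, screen_id, item_id, pos, x, t, d_x, d_t
    items: list  # ItemParams (identifiers + design; values are truth when simulated)
    screens: list  # ScreenParams
    reading_time: pd.DataFrame | None = None  # person_id, screen_id, reading_time
    truth: TruthRecord | None = None

    @property
    def person_ids(self) -> list:
        return list(pd.unique(self.df["person_id"]))

    @property
    def n_persons(self) -> int:
        return len(self.person_ids)


# ---------------------------------------------------------------------------
# Component draws
# ---------------------------------------------------------------------------


def iota_for_target_rate(rate: float, sigma_psi: float) -> float:
    """Attentiveness difficulty yielding a population careless rate ``rate``."""
    if not 0 < rate < 1:
        raise ValueError("rate must lie in (0, 1)")
    return float(
        brentq(lambda i: marginal_cier_rate_for_screen(i, sigma_psi) - rate, -40, 40)
    )


def draw_persons(cfg: SimConfig, rng: np.random.Generator | None = None) -> list:
    """Draw N person-parameter vectors from MVN(0, Sigma)."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    draws = rng.multivariate_normal(np.zeros(2 + cfg.S), cfg.Sigma, size=cfg.N,
                                    method="cholesky")
    return [
        PersonParams(person_id=f"p{i:04d}", psi=draws[i, 0], tau=draws[i, 1],
                     eta=draws[i, 2:])
        for i in range(cfg.N)
    ]


def _generate_items(cfg: SimConfig, rng: np.random.Generator) -> list:
    items = []
    K = cfg.K
    offsets = np.linspace(-1.0, 1.0, K) * cfg.b_spread
    for s in range(cfg.S):
        for j in range(cfg.J[s]):
            v = rng.uniform(*cfg.v_range)
            center = rng.uniform(*cfg.b_center_range)
            b = center + offsets + rng.normal(0, 0.15, size=K)
            beta_star = rng.uniform(*cfg.beta_star_range)
            items.append(
                ItemParams(item_id=f"s{s + 1}i{j + 1}", screen_id=f"s{s + 1}",
                           v=v, b=b, beta_star=beta_star)
            )
    return items


def _build_screens(cfg: SimConfig, items: list, iota: np.ndarray) -> list:
    screens = []
    for s in range(cfg.S):
        sid = f"s{s + 1}"
        members = [it for it in items if it.screen_id == sid]
        v_dot = float(np.exp(np.mean(np.log([it.v for it in members]))))
        o_dot = float(np.mean([it.o for it in members]))
        screens.append(
            ScreenParams(screen_id=sid, iota=float(iota[s]), trait_index=s,
                         items=[it.item_id for it in members],
                         beta_star_screen=float(np.mean([it.beta_star for it in members])),
                         v_dot=v_dot, o_dot=o_dot)
        )
    return screens


def simulate_attentiveness(cfg: SimConfig, persons: list,
                           rng: np.random.Generator | None = None,
                           iota: np.ndarray | None = None) -> np.ndarray:
    """Bernoulli attentiveness indicators Delta[i, s], independent given params."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    if iota is None:
        if cfg.iota is not None:
            iota = np.asarray(cfg.iota, dtype=float)
        else:
            iota = np.full(cfg.S, iota_for_target_rate(cfg.target_cier_rate, cfg.sigma_psi))
    psi = np.array([p.psi for p in persons])
    p1 = attentiveness_prob(psi[:, None], iota[None, :])
    return (rng.random((len(persons), cfg.S)) < p1).astype(int)


def simulate_attentive_screen(person: PersonParams, screen: ScreenParams, items: list,
                              g: GlobalParams, rng: np.random.Generator):
    """Responses and item RTs for one attentive person-screen."""
    xs, ts = [], []
    eta = float(person.eta[screen.trait_index])
    for it in items:
        probs = gpcm_category_probs(eta, it)
        xs.append(int(rng.choice(probs.size, p=probs)))
        mu = attentive_logrt_mean(person, it, g, screen_index=screen.trait_index)
        ts.append(float(np.exp(rng.normal(mu, g.sigma_A))))
    return np.array(xs), np.array(ts)


def simulate_cier_screen(pattern: str, screen: ScreenParams, items: list,
                         g: GlobalParams, rng: np.random.Generator,
                         descending: bool = False):
    """Responses and item RTs for one careless person-screen.

    Responses follow the requested content-free pattern; RTs are iid
    lognormal(beta_C, sigma_C) irrespective of the pattern.
    """
    J = len(items)
    K = g.K
    if pattern == "uniform_random":
        xs = rng.integers(0, K + 1, size=J)
    elif pattern == "endpoint_random":
        xs = rng.choice([0, K], size=J)
    elif pattern == "straight_line":
        xs = np.full(J, rng.integers(0, K + 1))
    elif pattern == "diagonal_line":
        start = rng.integers(0, K + 1)
        step = -1 if descending else 1
        xs = (start + step * np.arange(J)) % (K + 1)
    else:
        raise ValueError(f"unknown careless pattern {pattern!r}")
    ts = np.exp(rng.normal(g.beta_C, g.sigma_C, size=J))
    return xs.astype(int), ts


def _implied_kappa(cfg: SimConfig) -> np.ndarray:
    """Marginal careless category probabilities implied by the pattern mix.

    Uniform-random, straight-line and diagonal-line patterns are all
    marginally uniform over 0..K; endpoint-random splits its mass between
    the two extreme categories.
    """
    K = cfg.K
    mix = np.asarray(cfg.pattern_mix, dtype=float)
    kappa = np.zeros(K + 1)
    uniform_mass = mix[0] + mix[2] + mix[3]
    kappa += uniform_mass / (K + 1)
    kappa[0] += mix[1] / 2
    kappa[K] += mix[1] / 2
    return kappa


def _globals_from_cfg(cfg: SimConfig) -> GlobalParams:
    kappa = _implied_kappa(cfg) if cfg.kappa is None else np.asarray(cfg.kappa, float)
    return GlobalParams(beta_C=cfg.beta_C, sigma_C=cfg.sigma_C, sigma_A=cfg.sigma_A,
                        gamma=cfg.gamma, kappa=kappa, Sigma=cfg.Sigma,
                        K=cfg.K, S=cfg.S)


def simulate_dataset(cfg: SimConfig) -> tuple[ResponseDataset, TruthRecord]:
    """Generate a full long-format dataset with ground truth.

    Returns the dataset (responses, item RTs, per-screen reading time,
    missingness flags) and a :class:`TruthRecord` with the latent
    attentiveness states, careless pattern labels and generating parameters.
    """
    rng = np.random.default_rng(cfg.seed)
    g = _globals_from_cfg(cfg)
    persons = draw_persons(cfg, rng)
    items = cfg.items if cfg.items is not None else _generate_items(cfg, rng)
    if cfg.iota is not None:
        iota = np.asarray(cfg.iota, dtype=float)
    else:
        iota = np.full(cfg.S, iota_for_target_rate(cfg.target_cier_rate, cfg.sigma_psi))
    screens = _build_screens(cfg, items, iota)
    delta = simulate_attentiveness(cfg, persons, rng, iota=iota)

    mix = np.asarray(cfg.pattern_mix, dtype=float)
    person_pattern = rng.choice(4, size=cfg.N, p=mix)  # used if pattern_per_person

    rows = []
    pattern_rows = []
    reading_rows = []
    for i, person in enumerate(persons):
        for s, screen in enumerate(screens):
            members = [it for it in items if it.screen_id == screen.screen_id]
            if delta[i, s] == 1:
                xs, ts = simulate_attentive_screen(person, screen, members, g, rng)
            else:
                k = person_pattern[i] if cfg.pattern_per_person else rng.choice(4, p=mix)
                pattern = PATTERNS[k]
                xs, ts = simulate_cier_screen(pattern, screen, members, g, rng,
                                              descending=cfg.diagonal_descending)
                pattern_rows.append(
                    {"person_id": person.person_id, "screen_id": screen.screen_id,
                     "pattern": pattern}
                )
            read = float(np.exp(rng.normal(cfg.reading_logmean, cfg.reading_logsd)))
            reading_rows.append(
                {"person_id": person.person_id, "screen_id": screen.screen_id,
                 "reading_time": read}
            )
            for j, it in enumerate(members):
                d_x = int(rng.random() < cfg.miss_x_rate)
                d_t = int(rng.random() < cfg.miss_t_rate)
                rows.append(
                    {"person_id": person.person_id, "screen_id": screen.screen_id,
                     "item_id": it.item_id, "pos": j,
                     "x": np.nan if d_x else float(xs[j]),
                     "t": np.nan if d_t else float(ts[j]),
                     "d_x": d_x, "d_t": d_t}
                )

    df = pd.DataFrame(rows)
    truth = TruthRecord(delta=delta, patterns=pd.DataFrame(pattern_rows),
                        persons=persons, items=items, screens=screens, g=g)
    dataset = ResponseDataset(df=df, items=items, screens=screens,
                              reading_time=pd.DataFrame(reading_rows), truth=truth)
    return dataset, truth
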