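"""Classical indicator-based careless-responding screens.

These are the survey-methods baselines the model-based approach is compared
against: the long string index (longest run of identical consecutive
responses), the even--odd consistency index, squared Mahalanobis distance
with a chi-square cutoff, and a sequential multiple-hurdle procedure
(RT threshold, then long string, then Mahalanobis on the survivors).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy.stats import chi2

__all__ = [
    "HurdleConfig",
    "CONSERVATIVE",
    "LIBERAL",
    "long_string",
    "even_odd",
    "mahalanobis_flags",
    "multiple_hurdle",
]


@dataclass
class HurdleConfig:
    """Cutoffs of the sequential multiple-hurdle screen.

    ``long_string_per_scale`` maps scale (screen) id to the minimum run
    length that flags the scale; when ``None`` the rule is the conservative
    one: the longest run over all items must equal ``long_string_total``
    (a response vector that is one single run).
    """

    rt_threshold: float = 1.0  # seconds of mean time per item
    long_string_total: int | None = None  # None -> infer = total item count
    long_string_per_scale: dict | None = None  # e.g. {"s1": 5, "s2": 4}
    mahalanobis_quantile: float = 0.99
    rt_measure: str = "aat"

    def __post_init__(self) -> None:
        if self.rt_threshold <= 0:
            raise ValueError("rt_threshold must be positive")
        if not 0 < self.mahalanobis_quantile < 1:
            raise ValueError("mahalanobis_quantile must lie in (0, 1)")


#: Conservative settings: 1 s per item, all-items long string, chi2 .99.
CONSERVATIVE = HurdleConfig(rt_threshold=1.0, long_string_per_scale=None,
                            mahalanobis_quantile=0.99)

#: Liberal settings: 2 s per item, per-scale long string (5/7 and 4/5 style),
#: chi2 .95.  The per-scale run lengths must be adapted to the instrument.
LIBERAL = HurdleConfig(rt_threshold=2.0,
                       long_string_per_scale={"s1": 5, "s2": 4},
                       mahalanobis_quantile=0.95)


def long_string(responses) -> int:
    """Length of the longest run of identical consecutive responses.

    Missing entries (NaN / None) break runs; an empty vector scores 0.
    """
    best = run = 0
    prev = object()
    for x in responses:
        if x is None or (isinstance(x, float) and np.isnan(x)):
            run = 0
            prev = object()
            continue
        run = run + 1 if x == prev else 1
        prev = x
        best = max(best, run)
    return best


def even_odd(responses: pd.DataFrame, scale_col: str = "screen_id",
             pos_col: str = "pos", value_col: str = "x") -> float:
    """Even--odd consistency index for one person.

    Within each scale the items are split by odd/even presentation position
    and averaged into half-scores; the index is the correlation between the
    odd and even half-score vectors across scales.  Undefined (NaN) when
    fewer than two scales are available or either half-score vector has zero
    variance (e.g. a person answering identically everywhere).
    """
    odd_means, even_means = [], []
    for _, grp in responses.groupby(scale_col, sort=False):
        grp = grp.sort_values(pos_col)
        vals = grp[value_col].to_numpy(dtype=float)
        odd = vals[0::2]
        even = vals[1::2]
        odd = odd[~np.isnan(odd)]
        even = even[~np.isnan(even)]
        if odd.size < 1 or even.size < 1:
            continue
        odd_means.append(odd.mean())
        even_means.append(even.mean())
    if len(odd_means) < 2:
        warnings.warn("even-odd index needs at least two scales", stacklevel=2)
        return float("nan")
    o = np.asarray(odd_means)
    e = np.asarray(even_means)
    if o.std() == 0 or e.std() == 0:
        return float("nan")
    return float(np.corrcoef(o, e)[0, 1])


def mahalanobis_flags(X, quantile: float = 0.99, df: int | None = None):
    """Squared Mahalanobis distances to the sample mean with chi-square flags.

    Uses the sample covariance (``n - 1`` denominator).  Squared distances
    approximately follow a chi-square with df = number of variables, so rows
    beyond its ``quantile`` are flagged as multivariate outliers.

    Returns
    -------
    (d2, flags, cutoff)
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-d response matrix")
    if np.isnan(X).any():
        raise ValueError("X must be complete; apply listwise deletion first")
    n, p = X.shape
    df = p if df is None else df
    center = X.mean(axis=0)
    S = np.cov(X, rowvar=False)
    S = np.atleast_2d(S)
    sign, logdet = np.linalg.slogdet(S)
    if sign <= 0 or logdet < -1e10 or not np.isfinite(logdet):
        raise np.linalg.LinAlgError(
            "singular response covariance; consider regularizing or dropping "
            "constant items"
        )
    try:
        Sinv = np.linalg.inv(S)
    except np.linalg.LinAlgError as err:  # pragma: no cover - slogdet caught above
        raise np.linalg.LinAlgError(
            "singular response covariance; consider regularizing"
        ) from err
    diff = X - center
    d2 = np.einsum("ij,jk,ik->i", diff, Sinv, diff)
    cutoff = float(chi2.ppf(quantile, df))
    return d2, d2 > cutoff, cutoff


@dataclass
class HurdleResult:
    """Outcome of the sequential multiple-hurdle procedure."""

    flags: pd.Series  # person_id -> bool (flagged as careless)
    flagged_at: pd.Series  # person_id -> hurdle name or "" when passing
    counts: dict = field(default_factory=dict)  # per-hurdle flag counts
    n_listwise_dropped: int = 0  # persons excluded from Mahalanobis


def multiple_hurdle(dataset, timing, cfg: HurdleConfig = CONSERVATIVE) -> HurdleResult:
    """Sequential screening: RT threshold, long string, Mahalanobis.

    A person flagged at one hurdle is removed before the next is computed;
    in particular the Mahalanobis mean and covariance are re-estimated on
    the survivors of the first two hurdles, since outlier detection is
    sensitive to who has already been filtered out.
    """
    df = dataset.df
    person_ids = list(pd.unique(df["person_id"]))
    flags = pd.Series(False, index=person_ids)
    flagged_at = pd.Series("", index=person_ids)
    counts = {"rt": 0, "long_string": 0, "mahalanobis": 0}

    # --- hurdle 1: mean time per item -------------------------------------
    rt_person = timing.person_level(cfg.rt_measure)
    for pid in person_ids:
        val = rt_person.get(pid, np.nan)
        if np.isfinite(val) and val < cfg.rt_threshold:
            flags[pid] = True
            flagged_at[pid] = "rt"
            counts["rt"] += 1

    # --- hurdle 2: long string on survivors --------------------------------
    survivors = [pid for pid in person_ids if not flags[pid]]
    by_person = dict(tuple(df.groupby("person_id", sort=False)))
    for pid in survivors:
        grp = by_person[pid].sort_values(["screen_id", "pos"])
        hit = False
        if cfg.long_string_per_scale is not None:
            for sid, min_run in cfg.long_string_per_scale.items():
                sub = grp[grp["screen_id"] == sid]
                if len(sub) and long_string(sub["x"]) >= min_run:
                    hit = True
                    break
        else:
            total = cfg.long_string_total or grp["x"].notna().sum()
            hit = long_string(grp["x"]) >= total > 0
        if hit:
            flags[pid] = True
            flagged_at[pid] = "long_string"
            counts["long_string"] += 1

    # --- hurdle 3: Mahalanobis on remaining survivors ----------------------
    survivors = [pid for pid in person_ids if not flags[pid]]
    wide = (
        df[df["person_id"].isin(survivors)]
        .pivot_table(index="person_id", columns="item_id", values="x", sort=False)
    )
    complete = wide.dropna()
    n_dropped = len(wide) - len(complete)
    if len(complete) > complete.shape[1] + 1:
        d2, mflags, _ = mahalanobis_flags(
            complete.to_numpy(), quantile=cfg.mahalanobis_quantile
        )
        for pid, f in zip(complete.index, mflags):
            if f:
                flags[pid] = True
                flagged_at[pid] = "mahalanobis"
                counts["mahalanobis"] += 1

    return HurdleResult(flags=flags, flagged_at=flagged_at, counts=counts,
                        n_listwise_dropped=n_dropped)
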