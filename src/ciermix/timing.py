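"""Aggregated response-time measures and RT trimming.

From item-level RTs plus per-screen stem-reading time the module derives the
screen-level timing measures used as proxies when item-level RTs are
unavailable:

* ``TT`` — total time on screen (reading time + all item RTs),
* ``FRT`` — time to first response (reading time + first item RT),
* ``tt_per_item`` — TT divided by the number of items,
* ``ttfrt`` — (TT − FRT) / (J − 1), stripping reading time and the first item,
* ``aat`` — mean of item-level RTs excluding the first answered item
  (the first item's RT is confounded with reading the question stem when
  RTs are reconstructed from log events, so it is excluded by convention).

On complete data ``ttfrt`` and ``aat`` coincide: both average the RTs of
items 2..J.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .simulator import ResponseDataset

__all__ = ["TimingTable", "compute_timing_measures", "trim_rts", "TrimReport"]


@dataclass
class TimingTable:
    """Per person-screen timing measures (seconds)."""

    table: pd.DataFrame  # person_id, screen_id, J, TT, FRT, tt_per_item, ttfrt, aat

    def person_level(self, measure: str = "aat") -> pd.Series:
        """Average a measure over screens, indexed by person."""
        return self.table.groupby("person_id", sort=False)[measure].mean()


@dataclass
class TrimReport:
    """Accounting of an RT trimming pass."""

    n_total: int
    n_excluded: int
    threshold: float

    @property
    def fraction_excluded(self) -> float:
        return self.n_excluded / self.n_total if self.n_total else 0.0


def compute_timing_measures(dataset: ResponseDataset) -> TimingTable:
    """Build the timing table from item RTs and per-screen reading times.

    Items missing their RT are skipped in AAT; TT and FRT require the
    reading time and become missing if any constituent RT is missing.
    For single-item screens ``ttfrt`` and ``aat`` are undefined (NaN).
    """
    if dataset.reading_time is None:
        raise ValueError("dataset has no reading-time component")
    read = dataset.reading_time.set_index(["person_id", "screen_id"])["reading_time"]

    rows = []
    for (pid, sid), grp in dataset.df.groupby(["person_id", "screen_id"], sort=False):
        grp = grp.sort_values("pos")
        t = grp["t"].to_numpy(dtype=float)
        J = len(grp)
        rt_read = float(read.loc[(pid, sid)])
        complete = not np.isnan(t).any()
        TT = rt_read + float(np.nansum(t)) if complete else np.nan
        FRT = rt_read + float(t[0]) if complete and J >= 1 else np.nan
        if J >= 2:
            later = t[1:]
            later = later[~np.isnan(later)]
            aat = float(later.mean()) if later.size else np.nan
            ttfrt = (TT - FRT) / (J - 1) if complete else np.nan
        else:
            warnings.warn(
                f"screen {sid!r} has a single item; ttfrt/aat undefined", stacklevel=2
            )
            aat = np.nan
            ttfrt = np.nan
        rows.append(
            {"person_id": pid, "screen_id": sid, "J": J, "TT": TT, "FRT": FRT,
             "tt_per_item": TT / J if np.isfinite(TT) else np.nan,
             "ttfrt": ttfrt, "aat": aat}
        )
    return TimingTable(table=pd.DataFrame(rows))


def trim_rts(values, threshold_seconds: float = 90.0):
    """Set RTs above the threshold to missing and report the exclusions.

    Mirrors the trimming rule used to stabilize estimation on real data
    (default 99.9th-percentile-style cut at 90 s).  Applied to item-level
    RTs and to the AAT/TTFRT aggregates, but conventionally not to TT.

    Returns
    -------
    (numpy.ndarray, TrimReport)
        The values with exclusions set to NaN, and the exclusion report.
    """
    if threshold_seconds <= 0:
        raise ValueError("threshold must be positive")
    arr = np.asarray(values, dtype=float).copy()
    observed = ~np.isnan(arr)
    excl = observed & (arr > threshold_seconds)
    arr[excl] = np.nan
    return arr, TrimReport(n_total=int(observed.sum()), n_excluded=int(excl.sum()),
                           threshold=float(threshold_seconds))


def trim_dataset(dataset: ResponseDataset, threshold_seconds: float = 90.0):
    """Trim item-level RTs in place on a copy of the dataset's table."""
    df = dataset.df.copy()
    trimmed, report = trim_rts(df["t"].to_numpy(), threshold_seconds)
    newly_missing = np.isnan(trimmed) & (df["d_t"].to_numpy() == 0)
    df["t"] = trimmed
    df.loc[newly_missing, "d_t"] = 1
    out = ResponseDataset(df=df, items=dataset.items, screens=dataset.screens,
                          reading_time=dataset.reading_time, truth=dataset.truth)
    return out, report
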