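"""Readers, writers, report conversions and agreement tables.

The canonical on-disk format is a long CSV with one row per
(person, item): ``person_id, screen_id, item_id, pos, x, t, d_x, d_t``,
optionally accompanied by a reading-time CSV, an item-parameter CSV and a
JSON sidecar of generating parameters (for simulated data).
"""

from __future__ import annotations

from dataclasses import dataclass
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import ItemParams, ScreenParams
from .simulator import ResponseDataset

__all__ = [
    "read_long_csv",
    "write_dataset",
    "report_seconds",
    "report_distance_factor",
    "AgreementTable",
    "build_agreement_table",
]

_REQUIRED = ["person_id", "screen_id", "item_id", "x", "t", "d_x", "d_t"]


def read_long_csv(path, one_based: bool = False,
                  n_categories: int | None = None) -> ResponseDataset:
    """Read a long-format response CSV into a dataset.

    Responses must be coded ``0..K`` (or ``1..K+1`` with ``one_based=True``,
    which shifts them down).  Malformed rows — out-of-range or non-integer
    responses, non-positive RTs — are rejected with their row numbers.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    if "pos" not in df.columns:
        df["pos"] = df.groupby(["person_id", "screen_id"]).cumcount()
    if one_based:
        df["x"] = df["x"] - 1

    obs = df["x"].notna()
    x = df.loc[obs, "x"]
    K = n_categories - 1 if n_categories else int(x.max())
    bad = obs & (df["x"].fillna(0) % 1 != 0)
    bad |= obs & ((df["x"] < 0) | (df["x"] > K))
    if bad.any():
        rows = (df.index[bad] + 2).tolist()[:20]  # 1-based incl. header
        raise ValueError(f"out-of-range or non-integer responses at rows {rows}")
    bad_t = df["t"].notna() & (df["t"] <= 0)
    if bad_t.any():
        rows = (df.index[bad_t] + 2).tolist()[:20]
        raise ValueError(f"non-positive response times at rows {rows}")
    incons = (df["x"].isna() != (df["d_x"] == 1)) | (df["t"].isna() != (df["d_t"] == 1))
    if incons.any():
        rows = (df.index[incons] + 2).tolist()[:20]
        raise ValueError(f"missingness flags inconsistent with values at rows {rows}")

    # reconstruct design: items in first-appearance order, screens likewise
    item_rows = df.drop_duplicates("item_id")[["item_id", "screen_id"]]
    screen_ids = list(pd.unique(df["screen_id"]))
    items = [
        ItemParams(item_id=r.item_id, screen_id=r.screen_id, v=1.0,
                   b=np.zeros(max(K, 1)))
        for r in item_rows.itertuples()
    ]
    screens = [
        ScreenParams(screen_id=sid, iota=0.0, trait_index=k,
                     items=[it.item_id for it in items if it.screen_id == sid])
        for k, sid in enumerate(screen_ids)
    ]
    reading = None
    rpath = Path(path).with_name(Path(path).stem + "_reading.csv")
    if rpath.exists():
        reading = pd.read_csv(rpath)
    return ResponseDataset(df=df[_REQUIRED + ["pos"]], items=items,
                           screens=screens, reading_time=reading)


def write_dataset(dataset: ResponseDataset, out_dir, truth=None,
                  config: dict | None = None) -> dict:
    """Write a dataset (and optional truth / config sidecars) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"data": out / "data.csv"}
    dataset.df.to_csv(paths["data"], index=False)
    if dataset.reading_time is not None:
        paths["reading"] = out / "data_reading.csv"
        dataset.reading_time.to_csv(paths["reading"], index=False)
    if truth is not None:
        paths["truth"] = out / "truth.csv"
        n, s = truth.delta.shape
        rows = [
            {"person_id": truth.persons[i].person_id,
             "screen_id": truth.screens[j].screen_id,
             "delta": int(truth.delta[i, j])}
            for i in range(n) for j in range(s)
        ]
        tdf = pd.DataFrame(rows)
        if len(truth.patterns):
            tdf = tdf.merge(truth.patterns, how="left",
                            on=["person_id", "screen_id"])
        tdf.to_csv(paths["truth"], index=False)
    if config is not None:
        paths["config"] = out / "config.json"
        paths["config"].write_text(json.dumps(config, indent=2, default=_json_default))
    return {k: str(v) for k, v in paths.items()}


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def report_seconds(beta_like: float) -> float:
    """Convert a log-seconds location parameter to seconds (2 d.p.).

    E.g. a careless log-RT mean of 0.74 corresponds to a median of
    ``exp(0.74) = 2.10`` seconds.
    """
    if not np.isfinite(beta_like):
        raise ValueError("input must be finite")
    return round(float(np.exp(beta_like)), 2)


def report_distance_factor(gamma: float) -> float:
    """Multiplicative RT factor per unit of trait-difficulty distance.

    A distance--difficulty coefficient of 0.04 means attentive RTs shrink by
    ``exp(-0.04) = 0.96`` per unit distance.
    """
    if not np.isfinite(gamma):
        raise ValueError("input must be finite")
    return round(float(np.exp(-gamma)), 2)


@dataclass
class AgreementTable:
    """2x2 cross-tabulation of two careless/attentive classifications."""

    counts: pd.DataFrame  # index: method A flag, columns: method B flag
    median_attentiveness: pd.DataFrame | None  # same layout, median summary per cell
    n: int

    def __post_init__(self) -> None:
        if int(self.counts.to_numpy().sum()) != self.n:
            raise ValueError("agreement-table cells must sum to N")


def build_agreement_table(flags_a: pd.Series, flags_b: pd.Series,
                          attentiveness: pd.Series | None = None) -> AgreementTable:
    """Cross-tabulate two per-person flag vectors (True = careless).

    When a per-person attentiveness summary is supplied (for instance the
    posterior median attentiveness or ``pi_i``), its median within each
    cell is reported alongside the counts.
    """
    if set(flags_a.index) != set(flags_b.index):
        raise ValueError("flag vectors cover different person sets")
    flags_b = flags_b.reindex(flags_a.index)
    levels = [False, True]
    counts = pd.DataFrame(0, index=levels, columns=levels)
    med = pd.DataFrame(np.nan, index=levels, columns=levels) \
        if attentiveness is not None else None
    if attentiveness is not None:
        attentiveness = attentiveness.reindex(flags_a.index)
    for a in levels:
        for b in levels:
            cell = (flags_a == a) & (flags_b == b)
            counts.loc[a, b] = int(cell.sum())
            if attentiveness is not None and cell.any():
                med.loc[a, b] = float(attentiveness[cell].median())
    counts.index.name = "a_careless"
    counts.columns.name = "b_careless"
    return AgreementTable(counts=counts, median_attentiveness=med, n=len(flags_a))
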