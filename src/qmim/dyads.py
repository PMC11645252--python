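"""Dyad extraction from register-ordered transaction streams.

A *dyad* is an ordered pair of badge transactions — partner first, focal
second — executed at the same shop and the same cash register, within a
5-minute window, with no other transaction at that register strictly in
between.  Both members must carry the period-appropriate anchor (a meal at
lunch, a beverage otherwise) and belong to the same meal period; the same
person scanning twice forms no dyad.  Adjacency is judged against the *full*
register stream, so an anchored pair separated by an unanchored transaction
is not a dyad.

Dyads of casually adjacent strangers are removed by the repeated-pair
filter: only user pairs observed adjacent at least ``min_joint`` times
(default 10, both orderings pooled) are retained, so that the same partner
can later serve as his or her own control across days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "extract_dyads",
    "filter_frequent_pairs",
    "dyad_summary",
    "DyadSummary",
    "write_dyads_csv",
    "read_dyads_csv",
]

DYAD_COLUMNS = [
    "partner_txn",
    "focal_txn",
    "partner_user",
    "focal_user",
    "shop_id",
    "register_id",
    "date",
    "period",
    "lag_seconds",
    "partner_anchor",
    "focal_anchor",
    "partner_items",
    "focal_items",
    "partner_categories",
    "focal_categories",
    "partner_has_veg_meal",
    "focal_has_veg_meal",
    "partner_timestamp",
    "focal_timestamp",
]


def extract_dyads(log: pd.DataFrame, window_seconds: float = 300.0) -> pd.DataFrame:
    """Extract all partner→focal dyads from an annotated transaction log.

    *log* must come from :func:`qmim.transactions.annotate` (it needs the
    ``period``/``anchor``/``date`` columns) and be sorted by
    ``(shop_id, register_id, timestamp, txn_id)`` as the reader guarantees.

    Consecutive transactions at the same register form a dyad when the gap is
    at most *window_seconds*, the users differ, both transactions are
    anchored, and both fall in the same meal period on the same date.  A
    transaction may be focal in one dyad and partner in the next (chains are
    allowed).
    """
    order = log.sort_values(
        ["shop_id", "register_id", "timestamp", "txn_id"], kind="mergesort"
    ).index
    if not order.equals(log.index):
        raise ValueError("log must be sorted by (shop_id, register_id, timestamp, txn_id)")

    prev = log.shift(1)
    same_stream = (log["shop_id"] == prev["shop_id"]) & (
        log["register_id"] == prev["register_id"]
    )
    lag = (
        pd.to_datetime(log["timestamp"]) - pd.to_datetime(prev["timestamp"])
    ).dt.total_seconds()
    ok = (
        same_stream
        & (lag >= 0)
        & (lag <= window_seconds)
        & (log["user_id"] != prev["user_id"])
        & log["anchor"].notna()
        & prev["anchor"].notna()
        & (log["date"] == prev["date"])
        & (log["period"] == prev["period"])
    )
    focal = log[ok.fillna(False)]
    partner = prev[ok.fillna(False)]

    dyads = pd.DataFrame(
        {
            "partner_txn": partner["txn_id"].to_numpy(),
            "focal_txn": focal["txn_id"].to_numpy(),
            "partner_user": partner["user_id"].to_numpy(),
            "focal_user": focal["user_id"].to_numpy(),
            "shop_id": focal["shop_id"].to_numpy(),
            "register_id": focal["register_id"].to_numpy(),
            "date": focal["date"].to_numpy(),
            "period": focal["period"].to_numpy(),
            "lag_seconds": lag[ok.fillna(False)].to_numpy(),
            "partner_anchor": partner["anchor"].to_numpy(),
            "focal_anchor": focal["anchor"].to_numpy(),
            "partner_items": partner["items"].to_numpy(),
            "focal_items": focal["items"].to_numpy(),
            "partner_categories": partner["categories"].to_numpy(),
            "focal_categories": focal["categories"].to_numpy(),
            "partner_has_veg_meal": partner["has_veg_meal"].to_numpy(),
            "focal_has_veg_meal": focal["has_veg_meal"].to_numpy(),
            "partner_timestamp": partner["timestamp"].to_numpy(),
            "focal_timestamp": focal["timestamp"].to_numpy(),
        }
    )
    return dyads.reset_index(drop=True)


def _pair_key(dyads: pd.DataFrame, ordering: str) -> pd.Series:
    if ordering == "ordered":
        return dyads["partner_user"].astype(str) + "\x00" + dyads["focal_user"].astype(str)
    a = dyads["partner_user"].astype(str)
    b = dyads["focal_user"].astype(str)
    lo = a.where(a <= b, b)
    hi = b.where(a <= b, a)
    return lo + "\x00" + hi


def filter_frequent_pairs(
    dyads: pd.DataFrame, min_joint: int = 10, pair_count_ordering: str = "pooled"
) -> pd.DataFrame:
    """Keep dyads of user pairs observed adjacent at least *min_joint* times.

    With ``pair_count_ordering="pooled"`` (default) the two orderings of a
    pair are counted together; ``"ordered"`` counts partner→focal directions
    separately.
    """
    if pair_count_ordering not in {"pooled", "ordered"}:
        raise ValueError("pair_count_ordering must be 'pooled' or 'ordered'")
    if dyads.empty:
        return dyads.copy()
    key = _pair_key(dyads, pair_count_ordering)
    counts = key.map(key.value_counts())
    return dyads[counts >= min_joint].reset_index(drop=True)


_SET_COLUMNS = ("partner_items", "focal_items", "partner_categories", "focal_categories")


def write_dyads_csv(dyads: pd.DataFrame, path) -> None:
    """Write a dyad frame to CSV (item/category sets become ``;``-joined cells)."""
    out = dyads.copy()
    for col in _SET_COLUMNS:
        out[col] = out[col].map(lambda s: ";".join(sorted(s)))
    out["period"] = out["period"].map(lambda p: getattr(p, "value", str(p)))
    out.to_csv(path, index=False)


def read_dyads_csv(path) -> pd.DataFrame:
    """Read a dyad frame written by :func:`write_dyads_csv`."""
    from .transactions import MealPeriod

    df = pd.read_csv(
        path,
        dtype={
            "partner_user": str, "focal_user": str, "shop_id": str,
            "register_id": str, "partner_txn": str, "focal_txn": str,
        },
    )
    for col in _SET_COLUMNS:
        df[col] = df[col].map(lambda s: frozenset(str(s).split(";")) if pd.notna(s) else frozenset())
    df["period"] = df["period"].map(MealPeriod)
    df["date"] = pd.to_datetime(df["date"]).dt.date
    for col in ("partner_timestamp", "focal_timestamp"):
        df[col] = pd.to_datetime(df[col])
    for col in ("partner_has_veg_meal", "focal_has_veg_meal"):
        df[col] = df[col].astype(bool)
    return df


@dataclass(frozen=True)
class DyadSummary:
    """Descriptive statistics of a dyad collection."""

    n_dyads: int
    mean_lag: float
    sd_lag: float
    frac_lag_under_60s: float
    anchor_shares: dict  # period -> {anchor: share}

    @property
    def empty(self) -> bool:
        return self.n_dyads == 0


def dyad_summary(dyads: pd.DataFrame) -> DyadSummary:
    """Summarise dyad counts, inter-arrival lags, and per-period anchor shares."""
    if dyads.empty:
        return DyadSummary(0, float("nan"), float("nan"), float("nan"), {})
    lags = dyads["lag_seconds"].to_numpy(dtype=float)
    shares: dict = {}
    period_names = dyads["period"].map(lambda p: getattr(p, "value", str(p)))
    for period, grp in dyads.groupby(period_names):
        # share of dyad *members* (partner and focal pooled) per anchor label
        anchors = pd.concat([grp["partner_anchor"], grp["focal_anchor"]])
        shares[period] = anchors.value_counts(normalize=True).to_dict()
    return DyadSummary(
        n_dyads=len(dyads),
        mean_lag=float(np.mean(lags)),
        sd_lag=float(np.std(lags, ddof=1)) if len(lags) > 1 else 0.0,
        frac_lag_under_60s=float(np.mean(lags < 60.0)),
        anchor_shares=shares,
    )
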