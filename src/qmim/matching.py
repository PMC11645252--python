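"""Matched-pair construction for treated vs. control dyads.

The causal contrast is: did the focal person buy a focus item more often when
the partner just bought it (treated dyad) than when the same partner did not
(control dyad)?  The backdoor adjustment set — partner identity and the
common environmental context — is realised as matching keys: a matched pair
consists of one treated and one control dyad with the *same partner*, in the
*same shop*, during the *same meal period*, with the focus item *available*
in both dyads' (shop, date, period) strata and *equally popular* up to a
caliper (default 10%, relative).  Popularity is the fraction of the
stratum's transactions containing the item and doubles as the availability
indicator (available ⇔ bought at least once).

By default the popularity value used for the caliper is *leave-two-out*: the
dyad's own partner and focal transactions are removed from the stratum count
before taking the fraction.  Matching on the raw stratum fraction conditions
on the pair's own exposure and outcome, which at small stratum sizes biases
the paired contrast; the same applies to the availability filter (a control
dyad whose focal bought the item would otherwise always count as
"available").  The raw-count variant of both remains available as
``popularity_loo=False``.

Matching is one-to-one without replacement: greedy nearest-popularity within
each exact-key cell, treated dyads processed chronologically, ties broken by
popularity gap, then earliest control, then a seeded draw.  Covariate balance
is reported as the standardized mean difference (SMD) of popularity before
and after matching; groups are considered balanced when SMD < 0.2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .transactions import ADDITION_CATEGORIES, MealPeriod

__all__ = [
    "FocusItem",
    "ALL_FOCUS_ITEMS",
    "ADDITION_FOCUS_ITEMS",
    "focus_item",
    "PopularityIndex",
    "build_popularity_index",
    "match_pairs",
    "balance",
    "BalanceReport",
    "caliper_ok",
    "eligible_dyads",
]

#: item → the meal periods in which it is analysed as an addition
_ADDITION_PERIODS = {
    "condiment": (MealPeriod.lunch,),
    "salad": (MealPeriod.lunch,),
    "soup": (MealPeriod.lunch,),
    "soft_drink": (MealPeriod.lunch,),
    "pastry": (MealPeriod.lunch, MealPeriod.breakfast, MealPeriod.afternoon),
    "dessert": (MealPeriod.lunch, MealPeriod.breakfast, MealPeriod.afternoon),
    "fruit": (MealPeriod.lunch, MealPeriod.breakfast, MealPeriod.afternoon),
}


@dataclass(frozen=True)
class FocusItem:
    """One focus-item analysis: an addition in a period, or an anchor type.

    ``kind`` is ``"addition"`` for the 13 item×period analyses and
    ``"anchor_type"`` for the two anchor analyses (vegetarian vs. meat meal
    at lunch; tea vs. coffee at breakfast/afternoon).
    """

    label: str
    period: tuple[MealPeriod, ...]
    kind: str = "addition"

    def __post_init__(self) -> None:
        if self.kind == "addition":
            if self.label not in ADDITION_CATEGORIES:
                raise ValueError(f"not an addition category: {self.label}")
            allowed = _ADDITION_PERIODS[self.label]
            if any(p not in allowed for p in self.period):
                raise ValueError(f"{self.label} is not analysed in {self.period}")
        elif self.kind == "anchor_type":
            if self.label == "vegetarian_meal":
                if self.period != (MealPeriod.lunch,):
                    raise ValueError("vegetarian_meal is a lunch analysis")
            elif self.label == "tea":
                if any(p is MealPeriod.lunch for p in self.period):
                    raise ValueError("tea is a breakfast/afternoon analysis")
            else:
                raise ValueError(f"unknown anchor-type target: {self.label}")
        else:
            raise ValueError(f"unknown kind: {self.kind}")

    @property
    def name(self) -> str:
        pers = "+".join(p.value for p in self.period)
        return f"{self.label}@{pers}"

    # -- exposure / outcome semantics -------------------------------------
    def partner_exposed(self, dyads: pd.DataFrame) -> np.ndarray:
        if self.kind == "addition":
            return np.fromiter(
                (self.label in c for c in dyads["partner_categories"]), bool, len(dyads)
            )
        if self.label == "vegetarian_meal":
            return dyads["partner_has_veg_meal"].to_numpy(dtype=bool)
        return (dyads["partner_anchor"] == "tea").to_numpy(dtype=bool)

    def focal_bought(self, dyads: pd.DataFrame) -> np.ndarray:
        if self.kind == "addition":
            return np.fromiter(
                (self.label in c for c in dyads["focal_categories"]), bool, len(dyads)
            )
        if self.label == "vegetarian_meal":
            return dyads["focal_has_veg_meal"].to_numpy(dtype=bool)
        return (dyads["focal_anchor"] == "tea").to_numpy(dtype=bool)


def focus_item(label: str, period: MealPeriod | Iterable[MealPeriod] | None = None) -> FocusItem:
    """Build a :class:`FocusItem` from a label and an optional period restriction."""
    if label == "vegetarian_meal":
        return FocusItem("vegetarian_meal", (MealPeriod.lunch,), "anchor_type")
    if label == "tea":
        if period is None:
            pers = (MealPeriod.breakfast, MealPeriod.afternoon)
        elif isinstance(period, MealPeriod):
            pers = (period,)
        else:
            pers = tuple(period)
        return FocusItem("tea", pers, "anchor_type")
    if period is None:
        pers = _ADDITION_PERIODS[label]
    elif isinstance(period, MealPeriod):
        pers = (period,)
    else:
        pers = tuple(period)
    return FocusItem(label, pers, "addition")


#: The 13 addition analyses (7 lunch, 3 breakfast, 3 afternoon).
ADDITION_FOCUS_ITEMS: tuple[FocusItem, ...] = tuple(
    FocusItem(label, (per,), "addition")
    for per in (MealPeriod.lunch, MealPeriod.breakfast, MealPeriod.afternoon)
    for label, allowed in _ADDITION_PERIODS.items()
    if per in allowed
)

#: The 13 addition analyses plus the two anchor-type analyses.
ALL_FOCUS_ITEMS: tuple[FocusItem, ...] = ADDITION_FOCUS_ITEMS + (
    focus_item("vegetarian_meal"),
    focus_item("tea"),
)

#: labels whose popularity is tracked in the index
_POP_LABELS = tuple(ADDITION_CATEGORIES) + ("vegetarian_meal", "tea")


class PopularityIndex:
    """(shop, date, period, item label) → stratum purchase counts and fractions.

    ``get`` returns the raw fraction of stratum transactions containing the
    item (0 when never bought, i.e. unavailable).  ``lookup`` vectorises the
    lookup for a dyad frame and can subtract the dyad's own two member
    transactions (leave-two-out).
    """

    def __init__(self, counts: dict, stratum_sizes: dict):
        self._counts = counts  # (shop, date, period, label) -> count
        self._sizes = stratum_sizes  # (shop, date, period) -> n transactions

    @property
    def table(self) -> pd.DataFrame:
        rows = [
            (s, d, p, lab, c, self._sizes[(s, d, p)], c / self._sizes[(s, d, p)])
            for (s, d, p, lab), c in self._counts.items()
        ]
        return pd.DataFrame(
            rows,
            columns=["shop_id", "date", "period", "label", "count", "n", "popularity"],
        )

    def get(self, shop_id, date, period, label: str) -> float:
        key = (shop_id, date, str(period))
        n = self._sizes.get(key, 0)
        if n == 0:
            return 0.0
        return self._counts.get(key + (label,), 0) / n

    def lookup(
        self,
        dyads: pd.DataFrame,
        label: str,
        partner_member: np.ndarray | None = None,
        focal_member: np.ndarray | None = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-dyad (popularity, available) for *label*.

        With membership arrays supplied, the returned popularity and the
        availability indicator both exclude the dyad's own partner and focal
        transactions from the stratum count (leave-two-out), so that neither
        the matching variable nor the availability filter conditions on the
        pair's own exposure or outcome.
        """
        keys = list(zip(dyads["shop_id"], dyads["date"], (str(p) for p in dyads["period"])))
        count = np.array([self._counts.get(k + (label,), 0) for k in keys], dtype=float)
        n = np.array([self._sizes.get(k, 0) for k in keys], dtype=float)
        if partner_member is not None:
            count = count - partner_member.astype(float) - focal_member.astype(float)
            n = n - 2.0
        available = count > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            popv = np.where(n > 0, count / np.maximum(n, 1.0), 0.0)
        return np.clip(popv, 0.0, 1.0), available


def _label_membership(log: pd.DataFrame, label: str) -> np.ndarray:
    if label == "vegetarian_meal":
        return log["has_veg_meal"].to_numpy(dtype=bool)
    return np.fromiter((label in c for c in log["categories"]), bool, len(log))


def build_popularity_index(
    log: pd.DataFrame, labels: Iterable[str] = _POP_LABELS
) -> PopularityIndex:
    """Count each tracked label in every (shop, date, period) stratum.

    *log* must be annotated (:func:`qmim.transactions.annotate`).  Transactions
    outside the three meal periods belong to no stratum; the denominator is
    all of the stratum's transactions, anchored or not.
    """
    in_period = log["period"].notna()
    sub = log[in_period]
    key_frame = pd.DataFrame(
        {
            "shop_id": sub["shop_id"].to_numpy(),
            "date": sub["date"].to_numpy(),
            "period": [str(p) for p in sub["period"]],
        }
    )
    sizes = key_frame.groupby(["shop_id", "date", "period"], sort=False).size()
    stratum_sizes = {k: int(v) for k, v in sizes.items()}
    counts: dict = {}
    for label in labels:
        member = _label_membership(sub, label)
        grp = key_frame[member].groupby(["shop_id", "date", "period"], sort=False).size()
        for k, v in grp.items():
            counts[k + (label,)] = int(v)
    return PopularityIndex(counts, stratum_sizes)


def caliper_ok(pt: float, pc: float, caliper: float, mode: str = "relative") -> bool:
    """Admissibility of a popularity pair under the caliper."""
    if mode == "relative":
        return abs(pt - pc) <= caliper * max(pt, pc)
    if mode == "absolute":
        return abs(pt - pc) <= caliper
    raise ValueError("caliper_mode must be 'relative' or 'absolute'")


PAIR_COLUMNS = [
    "item",
    "partner_user",
    "shop_id",
    "period",
    "treated_index",
    "control_index",
    "pop_treated",
    "pop_control",
    "treated_focal_bought",
    "control_focal_bought",
    "treated_focal_user",
    "control_focal_user",
    "treated_date",
    "control_date",
    "treated_lag",
    "control_lag",
]


def eligible_dyads(dyads: pd.DataFrame, item: FocusItem) -> pd.DataFrame:
    """Dyads eligible for *item*: right period, annotated with ``exposed`` and
    ``outcome`` columns.  The original index is preserved."""
    mask = dyads["period"].isin(item.period)
    sub = dyads[mask].copy()
    sub["exposed"] = item.partner_exposed(sub)
    sub["outcome"] = item.focal_bought(sub)
    return sub


def _annotate_popularity(
    sub: pd.DataFrame, item: FocusItem, pop: PopularityIndex, popularity_loo: bool
) -> pd.DataFrame:
    """Add ``pop`` (matching variable) and ``available`` columns."""
    if item.kind == "addition":
        pm = item.partner_exposed(sub)
        fm = item.focal_bought(sub)
    elif item.label == "vegetarian_meal":
        pm = sub["partner_has_veg_meal"].to_numpy(bool)
        fm = sub["focal_has_veg_meal"].to_numpy(bool)
    else:  # tea: popularity counts tea-category purchases
        pm = np.fromiter(("tea" in c for c in sub["partner_categories"]), bool, len(sub))
        fm = np.fromiter(("tea" in c for c in sub["focal_categories"]), bool, len(sub))
    if popularity_loo:
        popv, avail = pop.lookup(sub, item.label, pm, fm)
    else:
        popv, avail = pop.lookup(sub, item.label)
    sub = sub.copy()
    sub["pop"] = popv
    sub["available"] = avail
    return sub


def match_pairs(
    dyads: pd.DataFrame,
    item: FocusItem,
    pop: PopularityIndex,
    caliper: float = 0.10,
    caliper_mode: str = "relative",
    exact_anchor: bool = False,
    popularity_loo: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Greedily match treated to control dyads for one focus item.

    Returns a frame with one row per matched pair (columns ``PAIR_COLUMNS``).
    Every pair satisfies: same partner user, shop and period; item available
    (bought at least once) in both strata; popularity gap within the caliper;
    with *exact_anchor*, identical partner and focal anchor labels across the
    two dyads.  One dyad is used in at most one pair.  Deterministic given
    *seed*.
    """
    if not (0 < caliper <= 1):
        raise ValueError("caliper must be in (0, 1]")
    rng = np.random.default_rng(seed)
    sub = eligible_dyads(dyads, item)
    if sub.empty:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    sub = _annotate_popularity(sub, item, pop, popularity_loo)
    sub = sub[sub["available"]]
    if sub.empty:
        return pd.DataFrame(columns=PAIR_COLUMNS)

    key_cols = [
        sub["partner_user"].to_numpy(),
        sub["shop_id"].to_numpy(),
        np.array([str(p) for p in sub["period"]]),
    ]
    if exact_anchor:
        key_cols += [
            sub["partner_anchor"].astype(str).to_numpy(),
            sub["focal_anchor"].astype(str).to_numpy(),
        ]
    cell_codes = pd.MultiIndex.from_arrays(key_cols).factorize(sort=False)[0]

    exposed = sub["exposed"].to_numpy(bool)
    popv = sub["pop"].to_numpy(float)
    ts = pd.to_datetime(sub["focal_timestamp"]).astype("int64").to_numpy()
    orig_index = sub.index.to_numpy()

    t_rows: list[int] = []
    c_rows: list[int] = []
    order = np.lexsort((ts, cell_codes))
    cc = cell_codes[order]
    boundaries = np.flatnonzero(np.r_[True, cc[1:] != cc[:-1], True])
    for b in range(len(boundaries) - 1):
        block = order[boundaries[b] : boundaries[b + 1]]
        t_ix = block[exposed[block]]  # chronological within cell
        c_ix = block[~exposed[block]]
        if len(t_ix) == 0 or len(c_ix) == 0:
            continue
        cpop = popv[c_ix]
        cts = ts[c_ix]
        used = np.zeros(len(c_ix), dtype=bool)
        for ti in t_ix:
            diffs = np.abs(cpop - popv[ti])
            lim = (
                caliper * np.maximum(cpop, popv[ti])
                if caliper_mode == "relative"
                else caliper
            )
            cand = ~used & (diffs <= lim)
            if not cand.any():
                continue
            best = diffs[cand].min()
            tied = cand & (diffs == best)
            if np.count_nonzero(tied) > 1:
                tied &= cts == cts[tied].min()
            choices = np.flatnonzero(tied)
            j = choices[0] if len(choices) == 1 else int(rng.choice(choices))
            used[j] = True
            t_rows.append(ti)
            c_rows.append(c_ix[j])

    if not t_rows:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    t = sub.iloc[t_rows]
    c = sub.iloc[c_rows]
    return pd.DataFrame(
        {
            "item": item.name,
            "partner_user": t["partner_user"].to_numpy(),
            "shop_id": t["shop_id"].to_numpy(),
            "period": np.array([str(p) for p in t["period"]]),
            "treated_index": orig_index[t_rows],
            "control_index": orig_index[c_rows],
            "pop_treated": t["pop"].to_numpy(float),
            "pop_control": c["pop"].to_numpy(float),
            "treated_focal_bought": t["outcome"].to_numpy(bool),
            "control_focal_bought": c["outcome"].to_numpy(bool),
            "treated_focal_user": t["focal_user"].to_numpy(),
            "control_focal_user": c["focal_user"].to_numpy(),
            "treated_date": t["date"].to_numpy(),
            "control_date": c["date"].to_numpy(),
            "treated_lag": t["lag_seconds"].to_numpy(float),
            "control_lag": c["lag_seconds"].to_numpy(float),
        }
    )


def read_pairs_csv(path) -> pd.DataFrame:
    """Read a matched-pair frame written with ``DataFrame.to_csv``."""
    df = pd.read_csv(path, dtype={"partner_user": str, "shop_id": str, "period": str})
    for col in ("treated_focal_bought", "control_focal_bought"):
        df[col] = df[col].map({True: True, False: False, "True": True, "False": False})
        df[col] = df[col].astype(bool)
    return df


@dataclass(frozen=True)
class BalanceReport:
    """Standardized mean differences before/after matching, per covariate."""

    smd_before: dict
    smd_after: dict
    threshold: float = 0.2

    @property
    def passed(self) -> bool:
        return all(v < self.threshold for v in self.smd_after.values())


def _smd(x: np.ndarray, y: np.ndarray) -> float:
    """|mean(x) − mean(y)| / pooled SD; 0 when degenerate with equal means."""
    mx, my = np.mean(x), np.mean(y)
    vx = np.var(x, ddof=1) if len(x) > 1 else 0.0
    vy = np.var(y, ddof=1) if len(y) > 1 else 0.0
    pooled = np.sqrt((vx + vy) / 2.0)
    if pooled == 0:
        return 0.0 if mx == my else float("inf")
    return float(abs(mx - my) / pooled)


def balance(
    pairs: pd.DataFrame,
    dyads: pd.DataFrame | None = None,
    item: FocusItem | None = None,
    pop: PopularityIndex | None = None,
    popularity_loo: bool = True,
) -> BalanceReport:
    """Popularity balance of a matched set.

    The after-matching SMD compares ``pop_treated`` with ``pop_control``
    across pairs.  When the eligible dyads and the index are supplied, the
    before-matching SMD compares popularity between all eligible treated and
    control dyads (restricted to strata where the item is available).
    """
    if len(pairs) < 2:
        raise ValueError("balance needs at least 2 matched pairs")
    after = _smd(pairs["pop_treated"].to_numpy(float), pairs["pop_control"].to_numpy(float))
    before = {}
    if dyads is not None and item is not None and pop is not None:
        sub = eligible_dyads(dyads, item)
        if not sub.empty:
            sub = _annotate_popularity(sub, item, pop, popularity_loo)
            sub = sub[sub["available"]]
            tr = sub.loc[sub["exposed"], "pop"].to_numpy(float)
            co = sub.loc[~sub["exposed"], "pop"].to_numpy(float)
            if len(tr) and len(co):
                before["popularity"] = _smd(tr, co)
    return BalanceReport(smd_before=before, smd_after={"popularity": after})
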