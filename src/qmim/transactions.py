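"""Transaction logs, item taxonomy, and meal-period assignment.

The unit record is a badge transaction: one person checking out at one cash
register at one point in time, purchasing a set of items.  Logs are plain CSV
with header ``txn_id,user_id,shop_id,register_id,timestamp,items``; the
``items`` cell holds ``;``-separated item codes and timestamps are ISO-8601,
timezone-naive, second resolution.

Items are mapped through an :class:`ItemCatalog` to a closed category
vocabulary (meal, coffee, tea, and the seven "addition" categories) plus a
tri-state vegetarian flag that is meaningful only for meals.  The day is split
into three half-open meal periods — breakfast 06:00–11:00, lunch 11:00–14:30,
afternoon 14:30–20:00 — and each period has an *anchor*: a meal at lunch, a
coffee or tea at breakfast and in the afternoon.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import time
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "CATEGORIES",
    "ADDITION_CATEGORIES",
    "MealPeriod",
    "ItemCatalog",
    "SchemaError",
    "TaxonomyError",
    "read_transactions",
    "write_transactions",
    "read_catalog",
    "read_demographics",
    "assign_period",
    "assign_periods",
    "anchor_of",
    "annotate",
]

#: Closed category vocabulary for item codes.
CATEGORIES = frozenset(
    {
        "meal",
        "coffee",
        "tea",
        "condiment",
        "salad",
        "pastry",
        "dessert",
        "soup",
        "soft_drink",
        "fruit",
        "other",
    }
)

#: The seven supplementary-item ("addition") categories studied alongside anchors.
ADDITION_CATEGORIES = (
    "condiment",
    "salad",
    "pastry",
    "dessert",
    "soup",
    "soft_drink",
    "fruit",
)

LOG_COLUMNS = ["txn_id", "user_id", "shop_id", "register_id", "timestamp", "items"]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class TaxonomyError(KeyError):
    """An item code is not present in the catalog."""


class MealPeriod(str, enum.Enum):
    """Daily meal periods with half-open boundaries [start, end)."""

    breakfast = "breakfast"
    lunch = "lunch"
    afternoon = "afternoon"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Period boundaries as half-open [start, end) clock-time intervals.
PERIOD_BOUNDS: Mapping[MealPeriod, tuple[time, time]] = {
    MealPeriod.breakfast: (time(6, 0), time(11, 0)),
    MealPeriod.lunch: (time(11, 0), time(14, 30)),
    MealPeriod.afternoon: (time(14, 30), time(20, 0)),
}


@dataclass(frozen=True)
class ItemCatalog:
    """Item code → (category, vegetarian flag) taxonomy.

    ``vegetarian`` is a tri-state flag: ``"yes"``/``"no"`` for meal items,
    ``"na"`` everywhere else.  Looking up a code that is absent from the
    catalog raises :class:`TaxonomyError`; nothing is silently coerced to
    ``"other"``.
    """

    category: Mapping[str, str]
    vegetarian: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {c: cat for c, cat in self.category.items() if cat not in CATEGORIES}
        if bad:
            raise ValueError(f"unknown categories in catalog: {bad}")

    def category_of(self, code: str) -> str:
        try:
            return self.category[code]
        except KeyError:
            raise TaxonomyError(f"unknown item code: {code!r}") from None

    def is_vegetarian(self, code: str) -> bool:
        """True when *code* is a meal flagged vegetarian."""
        self.category_of(code)
        return self.vegetarian.get(code, "na") == "yes"

    def check_codes(self, codes: Iterable[str]) -> None:
        """Raise :class:`TaxonomyError` listing every unresolvable code."""
        unknown = sorted({c for c in codes if c not in self.category})
        if unknown:
            raise TaxonomyError(f"item codes absent from catalog: {unknown}")

    def categories_of(self, items: frozenset[str]) -> frozenset[str]:
        return frozenset(self.category_of(c) for c in items)


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {missing}")


def read_catalog(path: str | Path) -> ItemCatalog:
    """Read an item catalog CSV ``item_code,category,vegetarian_flag``."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["item_code", "category", "vegetarian_flag"], "catalog")
    return ItemCatalog(
        category=dict(zip(df["item_code"], df["category"])),
        vegetarian=dict(zip(df["item_code"], df["vegetarian_flag"].fillna("na"))),
    )


def read_demographics(path: str | Path) -> pd.DataFrame:
    """Read a demographics CSV ``user_id,status,gender,birth_year``.

    Users absent from this table are treated as "unknown" downstream; this
    reader never imputes.
    """
    df = pd.read_csv(path, dtype={"user_id": str, "status": str, "gender": str})
    _require_columns(df, ["user_id", "status", "gender", "birth_year"], "demographics")
    df["birth_year"] = df["birth_year"].astype(int)
    return df.set_index("user_id")


def read_transactions(path: str | Path, catalog: ItemCatalog) -> pd.DataFrame:
    """Read a transaction log CSV into the canonical frame.

    Returns a DataFrame sorted by ``(shop_id, register_id, timestamp,
    txn_id)`` with an ``items`` column of frozensets of item codes.  Every
    item code must resolve in *catalog*.
    """
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, LOG_COLUMNS, "transaction log")
    df = df[LOG_COLUMNS].copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    items = df["items"].map(lambda s: frozenset(str(s).split(";")))
    if items.map(len).eq(0).any() or (df["items"].astype(str).str.len() == 0).any():
        raise ValueError("transaction with empty item set")
    catalog.check_codes(code for s in items for code in s)
    df["items"] = items
    df = df.sort_values(["shop_id", "register_id", "timestamp", "txn_id"], kind="mergesort")
    if df["txn_id"].duplicated().any():
        raise ValueError("duplicate txn_id in log")
    return df.reset_index(drop=True)


def write_transactions(df: pd.DataFrame, path: str | Path) -> None:
    """Write the canonical frame back to the CSV dialect of :func:`read_transactions`."""
    out = df[LOG_COLUMNS].copy()
    out["items"] = out["items"].map(lambda s: ";".join(sorted(s)))
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def assign_period(timestamp: pd.Timestamp) -> MealPeriod | None:
    """Map a timestamp to its meal period, or ``None`` outside 06:00–20:00."""
    t = pd.Timestamp(timestamp).time()
    for period, (start, end) in PERIOD_BOUNDS.items():
        if start <= t < end:
            return period
    return None


def assign_periods(timestamps: pd.Series) -> pd.Series:
    """Vectorised :func:`assign_period` over a datetime series."""
    secs = (
        pd.to_datetime(timestamps).dt.hour * 3600
        + pd.to_datetime(timestamps).dt.minute * 60
        + pd.to_datetime(timestamps).dt.second
    )
    out = pd.Series(pd.NA, index=timestamps.index, dtype=object)
    out[(secs >= 6 * 3600) & (secs < 11 * 3600)] = MealPeriod.breakfast
    out[(secs >= 11 * 3600) & (secs < 14 * 3600 + 1800)] = MealPeriod.lunch
    out[(secs >= 14 * 3600 + 1800) & (secs < 20 * 3600)] = MealPeriod.afternoon
    return out


def anchor_of(
    items: frozenset[str], period: MealPeriod | None, catalog: ItemCatalog
) -> str | None:
    """Anchor label of a transaction, or ``None`` if it has no anchor.

    The anchor is "meal" during lunch, "coffee" or "tea" during breakfast and
    afternoon.  A transaction containing both coffee and tea anchors on
    coffee (deterministic tie-break; coffee is by far the dominant beverage).
    """
    if period is None:
        return None
    cats = catalog.categories_of(items)
    if period is MealPeriod.lunch:
        return "meal" if "meal" in cats else None
    if "coffee" in cats:
        return "coffee"
    if "tea" in cats:
        return "tea"
    return None


def annotate(log: pd.DataFrame, catalog: ItemCatalog) -> pd.DataFrame:
    """Add derived columns used throughout the pipeline.

    Adds ``date``, ``period`` (object column of :class:`MealPeriod` or NA),
    ``anchor`` (object, possibly NA), ``categories`` (frozenset) and
    ``has_veg_meal`` (bool) to a copy of *log*.
    """
    out = log.copy()
    out["date"] = pd.to_datetime(out["timestamp"]).dt.date
    out["period"] = assign_periods(out["timestamp"])
    out["categories"] = out["items"].map(catalog.categories_of)
    out["anchor"] = [
        anchor_of(items, per if per is not pd.NA else None, catalog)
        for items, per in zip(out["items"], out["period"])
    ]
    veg_codes = {c for c in catalog.category if catalog.is_vegetarian(c)}
    out["has_veg_meal"] = out["items"].map(lambda s: bool(s & veg_codes))
    return out
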