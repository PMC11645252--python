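"""Shared fixtures: a hand-written catalog, log builders, and cached simulations."""

from __future__ import annotations

import pandas as pd
import pytest

from qmim import dyads as dy
from qmim import synthgen as sg
from qmim import transactions as tx


@pytest.fixture(scope="session")
def catalog() -> tx.ItemCatalog:
    return tx.ItemCatalog(
        category={
            "MEAL_V": "meal",
            "MEAL_M": "meal",
            "COFFEE": "coffee",
            "TEA": "tea",
            "COND": "condiment",
            "SALAD": "salad",
            "PASTRY": "pastry",
            "DESSERT": "dessert",
            "SOUP": "soup",
            "SOFT": "soft_drink",
            "FRUIT": "fruit",
            "MISC": "other",
        },
        vegetarian={"MEAL_V": "yes", "MEAL_M": "no"},
    )


def build_log(rows, catalog: tx.ItemCatalog) -> pd.DataFrame:
    """Annotated log from (txn_id, user, shop, register, timestamp, items) tuples."""
    df = pd.DataFrame(
        rows, columns=["txn_id", "user_id", "shop_id", "register_id", "timestamp", "items"]
    )
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["items"] = df["items"].map(frozenset)
    df = df.sort_values(
        ["shop_id", "register_id", "timestamp", "txn_id"], kind="mergesort"
    ).reset_index(drop=True)
    return tx.annotate(df, catalog)


@pytest.fixture(scope="session")
def make_log(catalog):
    return lambda rows: build_log(rows, catalog)


@pytest.fixture(scope="session")
def sim_default() -> sg.SimResult:
    """One default simulation (200 users x 60 days), reused across tests."""
    return sg.simulate(sg.default_config(), seed=1)


@pytest.fixture(scope="session")
def frequent_dyads(sim_default) -> pd.DataFrame:
    return dy.filter_frequent_pairs(dy.extract_dyads(sim_default.log))
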