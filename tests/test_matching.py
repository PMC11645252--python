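"""Popularity index, caliper matching vs an optimal-matching oracle, and balance."""

import datetime

import numpy as np
import pandas as pd
import pytest

from qmim import dyads as dy
from qmim import matching as mt
from qmim import transactions as tx

D1 = datetime.date(2018, 3, 1)
D2 = datetime.date(2018, 3, 2)

_FALLBACK_CATALOG = tx.ItemCatalog(
    category={"MEAL_M": "meal", "MEAL_V": "meal", "FRUIT": "fruit"},
    vegetarian={"MEAL_V": "yes"},
)


def make_dyad(
    index,
    partner="P",
    focal="F",
    shop="s1",
    period=tx.MealPeriod.lunch,
    date=D1,
    partner_items=("MEAL_M",),
    focal_items=("MEAL_M",),
    lag=15.0,
    ts="2018-03-01T12:00:00",
    catalog=None,
):
    cats = (catalog or _FALLBACK_CATALOG).categories_of
    veg = {"MEAL_V"}
    row = {
        "partner_txn": f"pt{index}",
        "focal_txn": f"ft{index}",
        "partner_user": partner,
        "focal_user": focal,
        "shop_id": shop,
        "register_id": "r1",
        "date": date,
        "period": period,
        "lag_seconds": lag,
        "partner_anchor": "meal" if period == tx.MealPeriod.lunch else "coffee",
        "focal_anchor": "meal" if period == tx.MealPeriod.lunch else "coffee",
        "partner_items": frozenset(partner_items),
        "focal_items": frozenset(focal_items),
        "partner_categories": cats(frozenset(partner_items)),
        "focal_categories": cats(frozenset(focal_items)),
        "partner_has_veg_meal": bool(set(partner_items) & veg),
        "focal_has_veg_meal": bool(set(focal_items) & veg),
        "partner_timestamp": pd.Timestamp(ts),
        "focal_timestamp": pd.Timestamp(ts) + pd.Timedelta(seconds=lag),
    }
    return row


def dyad_frame(rows):
    return pd.DataFrame(rows)


def index_of(pop_by_stratum: dict, label="fruit"):
    """PopularityIndex from {(shop, date): (count, n)} for one lunch label."""
    counts, sizes = {}, {}
    for (shop, date), (k, n) in pop_by_stratum.items():
        sizes[(shop, date, "lunch")] = n
        if k:
            counts[(shop, date, "lunch", label)] = k
    return mt.PopularityIndex(counts, sizes)


class TestPopularityIndex:
    def test_direct_fraction(self, make_log):
        rows = [
            (f"t{i}", f"u{i}", "s1", "r1", "2018-03-01T12:00:00", ["MEAL_M", "FRUIT"])
            for i in range(3)
        ] + [
            (f"t{i}", f"u{i}", "s1", "r1", "2018-03-01T12:01:00", ["MEAL_M"])
            for i in range(3, 10)
        ]
        pop = mt.build_popularity_index(make_log(rows))
        assert pop.get("s1", D1, "lunch", "fruit") == pytest.approx(0.30)

    def test_never_sold_means_unavailable(self, make_log):
        rows = [("t1", "u1", "s1", "r1", "2018-03-01T12:00:00", ["MEAL_M"])]
        pop = mt.build_popularity_index(make_log(rows))
        assert pop.get("s1", D1, "lunch", "fruit") == 0.0

    def test_matches_brute_force_recount(self, make_log):
        rng = np.random.default_rng(3)
        pool = [["MEAL_M"], ["MEAL_M", "FRUIT"], ["MEAL_V", "SALAD"], ["COFFEE"], ["MEAL_M", "FRUIT", "SALAD"]]
        rows = [
            (
                f"t{i:02d}",
                f"u{rng.integers(8)}",
                f"s{rng.integers(2)}",
                "r1",
                pd.Timestamp("2018-03-01T12:00:00")
                + pd.Timedelta(days=int(rng.integers(2)), seconds=int(rng.integers(3600))),
                pool[rng.integers(len(pool))],
            )
            for i in range(50)
        ]
        log = make_log(rows)
        pop = mt.build_popularity_index(log)
        for label in ("fruit", "salad"):
            for (shop, date), grp in log.groupby(["shop_id", "date"]):
                lunch = grp[grp["period"] == tx.MealPeriod.lunch]
                if lunch.empty:
                    continue
                frac = np.mean([label in c for c in lunch["categories"]])
                assert pop.get(shop, date, "lunch", label) == pytest.approx(frac)

    def test_leave_two_out_lookup(self):
        pop = index_of({("s1", D1): (3, 10)})
        d = dyad_frame([make_dyad(0)])
        d["shop_id"], d["date"] = "s1", [D1]
        raw, avail_raw = pop.lookup(d, "fruit")
        loo, avail = pop.lookup(d, "fruit", np.array([True]), np.array([False]))
        assert raw[0] == pytest.approx(0.3) and avail_raw[0]
        assert loo[0] == pytest.approx(2 / 8) and avail[0]
        loo2, avail2 = pop.lookup(
            dyad_frame([make_dyad(0)]).assign(shop_id="s1", date=[D1]),
            "fruit",
            np.array([True]),
            np.array([True]),
        )
        assert loo2[0] == pytest.approx(1 / 8)


@pytest.fixture()
def fruit_item():
    return mt.focus_item("fruit", tx.MealPeriod.lunch)


class TestMatchPairs:
    def test_minimal_match_within_caliper(self, catalog, fruit_item):
        rows = [
            make_dyad(0, date=D1, partner_items=("MEAL_M", "FRUIT"), catalog=catalog),
            make_dyad(1, date=D2, partner_items=("MEAL_M",), catalog=catalog),
        ]
        pop = index_of({("s1", D1): (20, 100), ("s1", D2): (21, 100)})
        pairs = mt.match_pairs(dyad_frame(rows), fruit_item, pop, popularity_loo=False, seed=0)
        assert len(pairs) == 1
        assert pairs.loc[0, "pop_treated"] == pytest.approx(0.20)
        assert pairs.loc[0, "pop_control"] == pytest.approx(0.21)

    def test_caliper_excludes_distant_popularity(self, catalog, fruit_item):
        rows = [
            make_dyad(0, date=D1, partner_items=("MEAL_M", "FRUIT"), catalog=catalog),
            make_dyad(1, date=D2, partner_items=("MEAL_M",), catalog=catalog),
        ]
        pop = index_of({("s1", D1): (20, 100), ("s1", D2): (25, 100)})
        pairs = mt.match_pairs(dyad_frame(rows), fruit_item, pop, popularity_loo=False, seed=0)
        assert len(pairs) == 0  # 0.20 vs 0.25 is 25% apart

    def test_unavailable_stratum_excluded(self, catalog, fruit_item):
        rows = [
            make_dyad(0, date=D1, partner_items=("MEAL_M", "FRUIT"), catalog=catalog),
            make_dyad(1, date=D2, partner_items=("MEAL_M",), catalog=catalog),
        ]
        pop = index_of({("s1", D1): (20, 100), ("s1", D2): (0, 100)})
        pairs = mt.match_pairs(dyad_frame(rows), fruit_item, pop, popularity_loo=False, seed=0)
        assert len(pairs) == 0

    def test_different_partner_never_matched(self, catalog, fruit_item):
        rows = [
            make_dyad(0, partner="P1", date=D1, partner_items=("MEAL_M", "FRUIT"), catalog=catalog),
            make_dyad(1, partner="P2", date=D2, partner_items=("MEAL_M",), catalog=catalog),
        ]
        pop = index_of({("s1", D1): (20, 100), ("s1", D2): (20, 100)})
        assert len(mt.match_pairs(dyad_frame(rows), fruit_item, pop, popularity_loo=False)) == 0

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_caliper_domain(self, catalog, fruit_item, bad):
        with pytest.raises(ValueError, match="caliper"):
            mt.match_pairs(dyad_frame([make_dyad(0, catalog=catalog)]), fruit_item, index_of({}), caliper=bad)

    def _random_instance(self, catalog, rng, n_treated, n_control):
        rows = []
        strata = {}
        i = 0
        for k in range(n_treated + n_control):
            treated = k < n_treated
            date = datetime.date(2018, 3, 1 + k)
            items = ("MEAL_M", "FRUIT") if treated else ("MEAL_M",)
            rows.append(make_dyad(i, date=date, partner_items=items, catalog=catalog))
            strata[("s1", date)] = (int(rng.integers(1, 30)), 100)
            i += 1
        return dyad_frame(rows), index_of(strata)

    @staticmethod
    def _optimal_size(d, pop, item):
        """Independent oracle: maximum bipartite matching under the caliper
        admissibility graph, via exhaustive Hopcroft-Karp."""
        import networkx as nx

        sub = mt.eligible_dyads(d, item)
        popv, avail = pop.lookup(sub, item.label)
        g = nx.Graph()
        top = []
        for i in range(len(sub)):
            if not sub["exposed"].iloc[i]:
                continue
            for j in range(len(sub)):
                if sub["exposed"].iloc[j]:
                    continue
                if avail[i] and avail[j] and mt.caliper_ok(popv[i], popv[j], 0.10):
                    g.add_edge(f"t{i}", f"c{j}")
                    top.append(f"t{i}")
        if not g.number_of_edges():
            return 0
        return len(nx.algorithms.bipartite.maximum_matching(g, top_nodes=set(top))) // 2

    def test_greedy_equals_optimal_on_separable_fixture(self, catalog, fruit_item):
        """6 treated vs 9 controls in well-separated popularity clusters: the
        greedy matched-set size equals the exhaustive maximum matching."""
        rows, strata = [], {}
        pops = [10, 11, 20, 21, 30, 31]  # treated strata counts (out of 100)
        cpops = [10, 10, 11, 20, 22, 30, 30, 33, 60]
        for k, p in enumerate(pops + cpops):
            date = datetime.date(2018, 3, 1 + k)
            treated = k < len(pops)
            items = ("MEAL_M", "FRUIT") if treated else ("MEAL_M",)
            rows.append(make_dyad(k, date=date, partner_items=items, catalog=catalog))
            strata[("s1", date)] = (p, 100)
        d, pop = dyad_frame(rows), index_of(strata)
        pairs = mt.match_pairs(d, fruit_item, pop, popularity_loo=False, seed=0)
        assert len(pairs) == self._optimal_size(d, pop, fruit_item) == 6

    def test_greedy_near_optimal_on_random_small_instances(self, catalog, fruit_item):
        """Aggregate greedy matched-set size stays within 10% of the optimal
        bipartite matching over random <=15-dyad instances."""
        rng = np.random.default_rng(7)
        greedy_total = opt_total = 0
        for trial in range(30):
            d, pop = self._random_instance(catalog, rng, 6, 9)
            pairs = mt.match_pairs(d, fruit_item, pop, popularity_loo=False, seed=trial)
            opt = self._optimal_size(d, pop, fruit_item)
            assert len(pairs) <= opt
            greedy_total += len(pairs)
            opt_total += opt
        assert greedy_total >= 0.9 * opt_total

    def test_emitted_pairs_pass_independent_predicate(self, sim_default, frequent_dyads):
        pop = mt.build_popularity_index(sim_default.log)
        for item in [mt.focus_item("condiment"), mt.focus_item("fruit", tx.MealPeriod.breakfast)]:
            pairs = mt.match_pairs(frequent_dyads, item, pop, seed=3)
            assert len(pairs) > 0
            sub = mt.eligible_dyads(frequent_dyads, item)
            exposed = pd.Series(sub["exposed"].to_numpy(), index=sub.index)
            for r in pairs.itertuples():
                t = frequent_dyads.loc[r.treated_index]
                c = frequent_dyads.loc[r.control_index]
                assert t["partner_user"] == c["partner_user"] == r.partner_user
                assert t["shop_id"] == c["shop_id"]
                assert str(t["period"]) == str(c["period"])
                assert bool(exposed.loc[r.treated_index]) and not bool(exposed.loc[r.control_index])
                assert mt.caliper_ok(r.pop_treated, r.pop_control, 0.10)
                assert t["partner_anchor"] is not None and c["focal_anchor"] is not None

    def test_matching_is_injective(self, sim_default, frequent_dyads):
        pop = mt.build_popularity_index(sim_default.log)
        pairs = mt.match_pairs(frequent_dyads, mt.focus_item("condiment"), pop, seed=0)
        used = pairs["treated_index"].tolist() + pairs["control_index"].tolist()
        assert len(used) == len(set(used))

    def test_shrinking_caliper_never_adds_pairs(self, sim_default, frequent_dyads):
        pop = mt.build_popularity_index(sim_default.log)
        item = mt.focus_item("dessert", tx.MealPeriod.lunch)
        sizes = [
            len(mt.match_pairs(frequent_dyads, item, pop, caliper=c, seed=0))
            for c in (0.02, 0.05, 0.10, 0.5)
        ]
        assert sizes == sorted(sizes)

    def test_exact_anchor_restricts_to_identical_anchors(self, sim_default, frequent_dyads):
        pop = mt.build_popularity_index(sim_default.log)
        item = mt.focus_item("pastry", tx.MealPeriod.breakfast)
        pairs = mt.match_pairs(frequent_dyads, item, pop, exact_anchor=True, seed=0)
        loose = mt.match_pairs(frequent_dyads, item, pop, exact_anchor=False, seed=0)
        assert len(pairs) <= len(loose)
        for r in pairs.itertuples():
            t = frequent_dyads.loc[r.treated_index]
            c = frequent_dyads.loc[r.control_index]
            assert t["partner_anchor"] == c["partner_anchor"]
            assert t["focal_anchor"] == c["focal_anchor"]

    def test_deterministic_given_seed(self, sim_default, frequent_dyads):
        pop = mt.build_popularity_index(sim_default.log)
        item = mt.focus_item("salad")
        a = mt.match_pairs(frequent_dyads, item, pop, seed=11)
        b = mt.match_pairs(frequent_dyads, item, pop, seed=11)
        pd.testing.assert_frame_equal(a, b)


class TestBalance:
    def test_identical_popularity_gives_zero_smd(self):
        pairs = pd.DataFrame(
            {"pop_treated": [0.2, 0.3, 0.1], "pop_control": [0.2, 0.3, 0.1],
             "treated_focal_bought": [True, False, True],
             "control_focal_bought": [False, False, True]}
        )
        rep = mt.balance(pairs)
        assert rep.smd_after["popularity"] == 0.0 and rep.passed

    def test_hand_computed_four_pair_fixture(self):
        t = np.array([0.10, 0.20, 0.30, 0.40])
        c = np.array([0.12, 0.18, 0.33, 0.37])
        pairs = pd.DataFrame({"pop_treated": t, "pop_control": c})
        rep = mt.balance(pairs)
        pooled_sd = np.sqrt((np.var(t, ddof=1) + np.var(c, ddof=1)) / 2)
        assert rep.smd_after["popularity"] == pytest.approx(abs(t.mean() - c.mean()) / pooled_sd)

    def test_synthetic_run_is_balanced_after_matching(self, sim_default, frequent_dyads):
        pop = mt.build_popularity_index(sim_default.log)
        item = mt.focus_item("condiment")
        pairs = mt.match_pairs(frequent_dyads, item, pop, seed=0)
        rep = mt.balance(pairs, frequent_dyads, item, pop)
        assert rep.smd_after["popularity"] < 0.2
        assert rep.passed

    def test_needs_two_pairs(self):
        with pytest.raises(ValueError):
            mt.balance(pd.DataFrame({"pop_treated": [0.1], "pop_control": [0.1]}))


def test_focus_item_registry_has_thirteen_addition_analyses():
    assert len(mt.ADDITION_FOCUS_ITEMS) == 13
    by_period = {}
    for it in mt.ADDITION_FOCUS_ITEMS:
        by_period.setdefault(it.period[0].value, []).append(it.label)
    assert sorted(by_period["lunch"]) == sorted(
        ["condiment", "salad", "pastry", "dessert", "soup", "soft_drink", "fruit"]
    )
    assert sorted(by_period["breakfast"]) == ["dessert", "fruit", "pastry"]
    assert sorted(by_period["afternoon"]) == ["dessert", "fruit", "pastry"]
    assert len(mt.ALL_FOCUS_ITEMS) == 15


def test_focus_item_rejects_invalid_combinations():
    with pytest.raises(ValueError):
        mt.FocusItem("condiment", (tx.MealPeriod.breakfast,), "addition")
    with pytest.raises(ValueError):
        mt.FocusItem("vegetarian_meal", (tx.MealPeriod.breakfast,), "anchor_type")
    with pytest.raises(ValueError):
        mt.FocusItem("tea", (tx.MealPeriod.lunch,), "anchor_type")
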