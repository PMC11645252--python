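"""Synthetic campus purchase-log generator with known ground truth.

The generator emulates the features of campus point-of-sale data that the
matched design must contend with:

* stable *eating profiles*: per-user, per-item propensity offsets on the
  log-odds scale, partly driven by a latent "health" trait;
* *homophilous co-queueing*: users form disjoint lunch-mate ties, with tie
  probability decaying in latent-trait distance, so tied users have
  correlated tastes (the classic confound for peer effects);
* *shared context*: day×shop×item popularity shocks on the log-odds scale
  that move both members of a queue at once;
* three daily meal periods with an anchor+addition purchase structure
  (meal at lunch, coffee/tea otherwise), and
* an *additive mimicry effect*: when the immediately preceding transaction
  at the register contains an item, the focal purchase probability for that
  item is raised by δ·e^(−lag/τ).

Tied pairs co-arrive at a register with exponential inter-arrival gaps
(mean ``lag_mean`` seconds); singletons interleave.  Every focal decision's
counterfactual purchase probabilities (with and without partner exposure)
are recorded, so the analytic target

    rd* = E[p(buy | exposed) − p(buy | unexposed) | exposed]

is available for parameter-recovery tests without peeking at δ itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .transactions import ItemCatalog, annotate

__all__ = ["SimConfig", "SimResult", "simulate", "default_config", "default_catalog", "rd_star"]

# label order used throughout internal arrays
LABELS = (
    "condiment",
    "salad",
    "pastry",
    "dessert",
    "soup",
    "soft_drink",
    "fruit",
    "tea",
    "vegetarian_meal",
)
ADDITION_LABELS = LABELS[:7]

# item code per label (one code per addition category keeps taxonomy simple)
_CODE = {
    "condiment": "COND",
    "salad": "SALAD",
    "pastry": "PASTRY",
    "dessert": "DESSERT",
    "soup": "SOUP",
    "soft_drink": "SOFT",
    "fruit": "FRUIT",
}

# loading of each label on the latent health trait (drives homophily confounding)
_TRAIT_LOADING = {
    "condiment": -0.3,
    "salad": 0.7,
    "pastry": -0.5,
    "dessert": -0.6,
    "soup": 0.3,
    "soft_drink": -0.6,
    "fruit": 0.7,
    "tea": 0.4,
    "vegetarian_meal": 0.8,
}

PERIOD_WINDOWS = {
    "breakfast": (6 * 3600, 11 * 3600),
    "lunch": (11 * 3600, 14 * 3600 + 1800),
    "afternoon": (14 * 3600 + 1800, 20 * 3600),
}

# which labels are decided in each period (additions + the anchor-type choice)
PERIOD_LABELS = {
    "breakfast": ("pastry", "dessert", "fruit", "tea"),
    "lunch": ("condiment", "salad", "pastry", "dessert", "soup", "soft_drink", "fruit", "vegetarian_meal"),
    "afternoon": ("pastry", "dessert", "fruit", "tea"),
}


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; the seed fully determines the output."""

    n_users: int = 200
    status_mix: dict = field(
        default_factory=lambda: {"student": 0.55, "staff": 0.35, "other": 0.10}
    )
    n_shops: int = 12
    n_registers: int = 3
    n_days: int = 60
    start_date: str = "2018-01-08"
    #: baseline purchase probability per period per addition label
    base_popularity: dict = field(
        default_factory=lambda: {
            "breakfast": {"pastry": 0.15, "dessert": 0.04, "fruit": 0.05},
            "lunch": {
                "condiment": 0.25,
                "salad": 0.12,
                "pastry": 0.08,
                "dessert": 0.15,
                "soup": 0.06,
                "soft_drink": 0.10,
                "fruit": 0.08,
            },
            "afternoon": {"pastry": 0.12, "dessert": 0.05, "fruit": 0.04},
        }
    )
    tea_share: float = 0.085  # baseline tea propensity; noise and mimicry lift the realised share to ~0.13
    veg_share: float = 0.35  # baseline probability the lunch meal is vegetarian
    attendance: dict = field(
        default_factory=lambda: {"breakfast": 0.30, "lunch": 0.80, "afternoon": 0.25}
    )
    profile_sd: float = 0.8  # per-user per-item log-odds spread
    context_sd: float = 0.1  # day×shop×item log-odds shock
    tie_density: float = 0.8  # fraction of users in a (disjoint) co-queueing tie
    homophily_strength: float = 0.0  # tie weight ∝ exp(−strength·|trait gap|)
    status_assortative: bool = True  # ties form within status groups
    delta: float = 0.15  # additive mimicry effect on the probability scale
    tau: float = math.inf  # lag-decay time constant, seconds (∞ = no decay)
    lag_mean: float = 14.0  # mean within-pair inter-arrival gap, seconds
    mimicry_window: float = 300.0  # exposure only to predecessors this recent
    subgroup_deltas: dict | None = None  # optional per-focal-status δ override
    seed: int = 0

    def validate(self) -> None:
        if self.n_users < 2:
            raise ValueError("need at least 2 users")
        if not 0 <= self.tie_density <= 1:
            raise ValueError("tie_density must be in [0, 1]")
        if self.lag_mean <= 0:
            raise ValueError("lag_mean must be positive")
        if not 0 <= self.delta <= 1:
            raise ValueError("delta must be in [0, 1]")
        if abs(sum(self.status_mix.values()) - 1) > 1e-9:
            raise ValueError("status_mix must sum to 1")


def default_config(**overrides) -> SimConfig:
    """The shipped study conditions; keyword overrides replace fields."""
    return replace(SimConfig(), **overrides) if overrides else SimConfig()


def default_catalog() -> ItemCatalog:
    """Catalog matching the generator's item codes."""
    category = {
        "MEAL_V": "meal",
        "MEAL_M": "meal",
        "COFFEE": "coffee",
        "TEA": "tea",
        **{_CODE[label]: label for label in ADDITION_LABELS},
    }
    vegetarian = {"MEAL_V": "yes", "MEAL_M": "no"}
    return ItemCatalog(category=category, vegetarian=vegetarian)


@dataclass
class SimResult:
    """A simulated log plus everything needed to audit it."""

    log: pd.DataFrame  # annotated canonical transaction frame
    truth: pd.DataFrame  # one row per focal decision with a predecessor
    demographics: pd.DataFrame  # user_id-indexed status/gender/birth_year
    catalog: ItemCatalog
    clip_fraction: float  # share of decisions whose probability was clipped
    config: SimConfig


def rd_star(truth: pd.DataFrame, additions_only: bool = True) -> float:
    """Ground-truth analytic target: mean realised effect among exposed decisions."""
    t = truth[truth["is_addition"]] if additions_only else truth
    exposed = t[t["exposed"]]
    if exposed.empty:
        return float("nan")
    return float((exposed["p_with"] - exposed["p_without"]).mean())


def _make_users(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    statuses = list(cfg.status_mix)
    probs = np.array([cfg.status_mix[s] for s in statuses])
    status = rng.choice(statuses, size=cfg.n_users, p=probs)
    gender = rng.choice(["female", "male"], size=cfg.n_users)
    year0 = int(cfg.start_date[:4])
    birth = np.empty(cfg.n_users, dtype=int)
    for i, s in enumerate(status):
        if s == "student":
            birth[i] = year0 - int(rng.integers(18, 26))  # mostly youngest tercile
        elif s == "staff":
            birth[i] = year0 - int(rng.integers(28, 61))
        else:
            birth[i] = year0 - int(rng.integers(22, 50))
    return pd.DataFrame(
        {
            "user_id": [f"u{i:05d}" for i in range(cfg.n_users)],
            "status": status,
            "gender": gender,
            "birth_year": birth,
        }
    )


def _make_ties(
    cfg: SimConfig, users: pd.DataFrame, trait: np.ndarray, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Disjoint co-queueing pairs, optionally homophilous and status-assortative."""
    n_pairs = int(cfg.tie_density * cfg.n_users / 2)
    if n_pairs * 2 > cfg.n_users:
        raise ValueError("tie_density requires more tied users than exist")
    free = list(rng.permutation(cfg.n_users))
    ties: list[tuple[int, int]] = []
    status = users["status"].to_numpy()
    while len(ties) < n_pairs and len(free) >= 2:
        a = free.pop(0)
        pool = np.array(free)
        if cfg.status_assortative:
            same = pool[status[pool] == status[a]]
            if len(same) > 0:
                pool = same
        w = np.exp(-cfg.homophily_strength * np.abs(trait[pool] - trait[a]))
        w = w / w.sum()
        b = int(rng.choice(pool, p=w))
        free.remove(b)
        ties.append((a, b))
    return ties


def simulate(config: SimConfig | None = None, seed: int | None = None) -> SimResult:
    """Generate a transaction log and its ground truth from *config*.

    The full procedure: draw users, traits, profiles and ties; for each day,
    shop and period, tied pairs co-arrive at a random register in random
    internal order with an exponential gap, singletons arrive alone; walk
    each register stream in time order and draw every purchase decision,
    adding δ·e^(−lag/τ) to the purchase probability of items present in the
    immediately preceding transaction (within ``mimicry_window`` seconds and
    the same period).
    """
    cfg = config or default_config()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_labels = len(LABELS)
    lab_ix = {lab: i for i, lab in enumerate(LABELS)}

    users = _make_users(cfg, rng)
    trait = rng.standard_normal(cfg.n_users)
    loading = np.array([_TRAIT_LOADING[lab] for lab in LABELS])
    noise = rng.standard_normal((cfg.n_users, n_labels))
    profile = cfg.profile_sd * (
        trait[:, None] * loading[None, :]
        + np.sqrt(1.0 - loading[None, :] ** 2) * noise
    )

    ties = _make_ties(cfg, users, trait, rng)
    tied = {u for ab in ties for u in ab}
    singles = [u for u in range(cfg.n_users) if u not in tied]
    # units: (members, home shop); pairs share a home shop
    units = [(list(ab), int(rng.integers(cfg.n_shops))) for ab in ties]
    units += [([u], int(rng.integers(cfg.n_shops))) for u in singles]

    # base log-odds per (period, label); untracked combinations are impossible
    base = np.full((3, n_labels), -np.inf)
    periods = ("breakfast", "lunch", "afternoon")
    for pi, per in enumerate(periods):
        for lab, p in cfg.base_popularity[per].items():
            base[pi, lab_ix[lab]] = _logit(p)
        if per == "lunch":
            base[pi, lab_ix["vegetarian_meal"]] = _logit(cfg.veg_share)
        else:
            base[pi, lab_ix["tea"]] = _logit(cfg.tea_share)

    context = rng.normal(0.0, cfg.context_sd, size=(cfg.n_days, cfg.n_shops, n_labels))

    # --- arrivals ---------------------------------------------------------
    day_l, shop_l, reg_l, per_l, time_l, user_l = [], [], [], [], [], []
    for day in range(cfg.n_days):
        for members, shop in units:
            for pi, per in enumerate(periods):
                if rng.random() >= cfg.attendance[per]:
                    continue
                reg = int(rng.integers(cfg.n_registers))
                w0, w1 = PERIOD_WINDOWS[per]
                start = w0 + rng.random() * (w1 - w0 - 600)
                order = rng.permutation(len(members))
                t = start
                for k, m in enumerate(order):
                    if k > 0:
                        t = t + rng.exponential(cfg.lag_mean)
                    day_l.append(day)
                    shop_l.append(shop)
                    reg_l.append(reg)
                    per_l.append(pi)
                    time_l.append(t)
                    user_l.append(members[m])

    day_a = np.array(day_l)
    shop_a = np.array(shop_l)
    reg_a = np.array(reg_l)
    per_a = np.array(per_l)
    time_a = np.array(time_l)
    user_a = np.array(user_l)
    n_txn = len(day_a)

    # register-stream order
    order = np.lexsort((time_a, reg_a, day_a, shop_a))
    day_a, shop_a, reg_a, per_a, time_a, user_a = (
        a[order] for a in (day_a, shop_a, reg_a, per_a, time_a, user_a)
    )

    # baseline probabilities for every transaction × label (vectorised)
    logits = base[per_a] + profile[user_a] + context[day_a, shop_a]
    p0 = 1.0 / (1.0 + np.exp(-logits))

    # per-focal mimicry effect size
    deltas = np.full(n_txn, cfg.delta)
    if cfg.subgroup_deltas:
        status_by_user = users["status"].to_numpy()
        for s, d in cfg.subgroup_deltas.items():
            deltas[status_by_user[user_a] == s] = d

    # predecessor in the same register stream, same period, within the window
    same_stream = np.zeros(n_txn, dtype=bool)
    same_stream[1:] = (
        (shop_a[1:] == shop_a[:-1])
        & (day_a[1:] == day_a[:-1])
        & (reg_a[1:] == reg_a[:-1])
        & (per_a[1:] == per_a[:-1])
    )
    lag_prev = np.full(n_txn, np.nan)
    lag_prev[1:] = time_a[1:] - time_a[:-1]
    has_pred = same_stream & (lag_prev <= cfg.mimicry_window)
    decay = np.zeros(n_txn)
    decay[has_pred] = (
        np.exp(-lag_prev[has_pred] / cfg.tau) if np.isfinite(cfg.tau) else 1.0
    )

    # which labels are live in each period
    live = np.zeros((3, n_labels), dtype=bool)
    for pi, per in enumerate(periods):
        for lab in PERIOD_LABELS[per]:
            live[pi, lab_ix[lab]] = True

    # --- sequential purchase draws ---------------------------------------
    U = rng.random((n_txn, n_labels))
    bought = np.zeros((n_txn, n_labels), dtype=bool)
    n_clipped = 0
    n_decisions = 0
    for i in range(n_txn):
        mask = live[per_a[i]]
        p = p0[i].copy()
        if has_pred[i]:
            add = deltas[i] * decay[i]
            exposed = bought[i - 1] & mask
            p[exposed] = p[exposed] + add
        over = (p > 1.0) & mask
        n_clipped += int(np.count_nonzero(over))
        n_decisions += int(np.count_nonzero(mask))
        np.clip(p, 0.0, 1.0, out=p)
        bought[i] = (U[i] < p) & mask

    # --- ground truth (vectorised over decisions with a predecessor) -----
    pred_ix = np.arange(n_txn) - 1
    gi = np.flatnonzero(has_pred)
    g_rows = []
    for pi in range(3):
        sel = gi[per_a[gi] == pi]
        if len(sel) == 0:
            continue
        labs = np.flatnonzero(live[pi])
        for L in labs:
            p_wo = p0[sel, L]
            p_w = np.clip(p_wo + deltas[sel] * decay[sel], 0.0, 1.0)
            g_rows.append(
                pd.DataFrame(
                    {
                        "txn_index": sel,
                        "focal_user_index": user_a[sel],
                        "label": LABELS[L],
                        "is_addition": LABELS[L] in ADDITION_LABELS,
                        "lag_seconds": lag_prev[sel],
                        "exposed": bought[pred_ix[sel], L],
                        "bought": bought[sel, L],
                        "p_without": p_wo,
                        "p_with": p_w,
                    }
                )
            )
    truth = (
        pd.concat(g_rows, ignore_index=True)
        if g_rows
        else pd.DataFrame(
            columns=[
                "txn_index", "focal_user_index", "label", "is_addition",
                "lag_seconds", "exposed", "bought", "p_without", "p_with",
            ]
        )
    )

    # --- assemble the log in the canonical dialect ------------------------
    start = pd.Timestamp(cfg.start_date)
    timestamps = (
        start
        + pd.to_timedelta(day_a, unit="D")
        + pd.to_timedelta(np.floor(time_a).astype(int), unit="s")
    )
    anchor_codes = np.where(
        per_a == 1,
        np.where(bought[:, lab_ix["vegetarian_meal"]], "MEAL_V", "MEAL_M"),
        np.where(bought[:, lab_ix["tea"]], "TEA", "COFFEE"),
    )
    addition_codes = [_CODE[lab] for lab in ADDITION_LABELS]
    items = [
        frozenset(
            [anchor_codes[i]]
            + [addition_codes[j] for j in range(7) if bought[i, j]]
        )
        for i in range(n_txn)
    ]
    uid = users["user_id"].to_numpy()
    log = pd.DataFrame(
        {
            "txn_id": [f"t{i:07d}" for i in range(n_txn)],
            "user_id": uid[user_a],
            "shop_id": [f"s{j:02d}" for j in shop_a],
            "register_id": [f"r{j}" for j in reg_a],
            "timestamp": timestamps,
            "items": items,
        }
    )
    log = log.sort_values(
        ["shop_id", "register_id", "timestamp", "txn_id"], kind="mergesort"
    ).reset_index(drop=True)
    catalog = default_catalog()
    log = annotate(log, catalog)
    truth["focal_user"] = uid[truth["focal_user_index"].to_numpy(dtype=int)] if len(truth) else []

    return SimResult(
        log=log,
        truth=truth,
        demographics=users.set_index("user_id"),
        catalog=catalog,
        clip_fraction=n_clipped / max(n_decisions, 1),
        config=cfg,
    )
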