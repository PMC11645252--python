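"""Paired contingency analysis and effect estimation.

For a focus item, each matched pair contributes one of four outcomes
depending on whether the treated-dyad focal and the control-dyad focal
bought the item.  With counts ``n11`` (both bought), ``n10`` (treated focal
only), ``n01`` (control focal only), ``n00`` (neither) and
``n = n11+n10+n01+n00``, the headline estimands are

    RD = p(buy | partner bought) − p(buy | partner did not)
       = (n10 − n01) / n
    RR = p(buy | partner bought) / p(buy | partner did not)
       = (n11 + n10) / (n11 + n01)

with 95% confidence intervals from a percentile bootstrap over matched pairs
(resampling the n pairs with replacement).  The hypothesis of no treatment
effect is tested with McNemar's paired χ² on the discordant counts, with an
exact binomial variant for small samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyCounts",
    "EffectEstimate",
    "tabulate",
    "estimate",
    "paired_chi2",
    "subgroup_estimates",
    "unmatched_contrast",
    "age_tercile",
    "AGE_TERCILE_EDGES",
]


@dataclass(frozen=True)
class ContingencyCounts:
    """Paired 2×2 table of focal purchases across matched dyad pairs."""

    n11: int  # both focals purchased
    n10: int  # treated focal purchased, control focal did not
    n01: int  # control focal purchased, treated focal did not
    n00: int  # neither purchased

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    @property
    def treated_purchases(self) -> int:
        return self.n11 + self.n10

    @property
    def control_purchases(self) -> int:
        return self.n11 + self.n01

    @property
    def treated_rate(self) -> float:
        return self.treated_purchases / self.n

    @property
    def control_rate(self) -> float:
        return self.control_purchases / self.n

    @property
    def discordant_ratio(self) -> float:
        """How much more often the focal mirrors than opposes the partner."""
        return self.n10 / self.n01 if self.n01 else math.inf

    def shares(self) -> dict:
        """Each cell as a share of all matched pairs."""
        n = self.n
        return {k: getattr(self, k) / n for k in ("n11", "n10", "n01", "n00")}

    def __add__(self, other: "ContingencyCounts") -> "ContingencyCounts":
        return ContingencyCounts(
            self.n11 + other.n11,
            self.n10 + other.n10,
            self.n01 + other.n01,
            self.n00 + other.n00,
        )


def tabulate(pairs: pd.DataFrame) -> ContingencyCounts:
    """Count the four focal-outcome combinations over matched pairs."""
    if pairs.empty:
        return ContingencyCounts(0, 0, 0, 0)
    t = pairs["treated_focal_bought"].to_numpy(dtype=bool)
    c = pairs["control_focal_bought"].to_numpy(dtype=bool)
    return ContingencyCounts(
        n11=int(np.sum(t & c)),
        n10=int(np.sum(t & ~c)),
        n01=int(np.sum(~t & c)),
        n00=int(np.sum(~t & ~c)),
    )


@dataclass(frozen=True)
class EffectEstimate:
    """Point estimates and bootstrap CIs for one analysis stratum."""

    rd: float
    rr: float | None
    ci_rd: tuple[float, float] | None
    ci_rr: tuple[float, float] | None
    n_pairs: int
    item: str = ""
    subgroup: str = ""
    low_n: bool = False

    @property
    def relative_effect(self) -> float | None:
        """RR − 1: the relative increase in the focal purchase probability."""
        return None if self.rr is None else self.rr - 1.0


def _point(counts: ContingencyCounts) -> tuple[float, float | None]:
    rd = (counts.n10 - counts.n01) / counts.n
    rr = (
        counts.treated_purchases / counts.control_purchases
        if counts.control_purchases > 0
        else None
    )
    return rd, rr


def estimate(
    counts: ContingencyCounts,
    boot_reps: int = 1000,
    seed: int = 0,
    item: str = "",
    subgroup: str = "",
) -> EffectEstimate:
    """RD and RR with percentile-bootstrap 95% CIs.

    The bootstrap resamples the n matched pairs with replacement, which for
    a 2×2 paired table is a multinomial resample of the four cells.  When no
    control focal ever purchased, RR is undefined (``None``) but RD is still
    returned.
    """
    if counts.n == 0:
        raise ValueError("cannot estimate from an empty table")
    rd, rr = _point(counts)
    ci_rd = ci_rr = None
    if boot_reps > 0:
        rng = np.random.default_rng(seed)
        p = np.array([counts.n11, counts.n10, counts.n01, counts.n00]) / counts.n
        draws = rng.multinomial(counts.n, p, size=boot_reps).astype(float)
        n11, n10, n01 = draws[:, 0], draws[:, 1], draws[:, 2]
        rd_b = (n10 - n01) / counts.n
        ci_rd = (float(np.percentile(rd_b, 2.5)), float(np.percentile(rd_b, 97.5)))
        denom = n11 + n01
        if rr is not None and np.all(denom > 0):
            rr_b = (n11 + n10) / denom
            ci_rr = (float(np.percentile(rr_b, 2.5)), float(np.percentile(rr_b, 97.5)))
    return EffectEstimate(
        rd=rd, rr=rr, ci_rd=ci_rd, ci_rr=ci_rr, n_pairs=counts.n,
        item=item, subgroup=subgroup,
    )


def paired_chi2(counts: ContingencyCounts, exact: bool = False) -> tuple[float | None, float]:
    """McNemar test of no treatment effect on the discordant counts.

    Returns ``(statistic, p_value)``.  The χ² form is
    ``(n10 − n01)² / (n10 + n01)`` with a 1-df χ² p-value; with
    ``exact=True`` the statistic is ``None`` and the p-value is the
    two-sided exact binomial probability of the observed discordant split.
    """
    d = counts.n10 + counts.n01
    if d == 0:
        return None, float("nan")
    if exact:
        p = stats.binomtest(counts.n10, d, 0.5).pvalue
        return None, float(p)
    stat = (counts.n10 - counts.n01) ** 2 / d
    return float(stat), float(stats.chi2.sf(stat, df=1))


def unmatched_contrast(dyads: pd.DataFrame, items) -> float:
    """Naive (unmatched, unadjusted) exposure contrast pooled over focus items.

    p(focal bought | partner bought) − p(focal bought | partner did not),
    computed over all eligible dyads without any matching.  Used as the
    biased comparator that the matched design is meant to beat.
    """
    from .matching import FocusItem, eligible_dyads

    if isinstance(items, FocusItem):
        items = [items]
    exp_buy = exp_n = une_buy = une_n = 0
    for item in items:
        sub = eligible_dyads(dyads, item)
        if sub.empty:
            continue
        e = sub["exposed"].to_numpy(dtype=bool)
        o = sub["outcome"].to_numpy(dtype=bool)
        exp_buy += int(np.sum(o[e]))
        exp_n += int(np.sum(e))
        une_buy += int(np.sum(o[~e]))
        une_n += int(np.sum(~e))
    if exp_n == 0 or une_n == 0:
        return float("nan")
    return exp_buy / exp_n - une_buy / une_n


# ---------------------------------------------------------------------------
# subgroup analyses

AGE_TERCILE_EDGES = (22, 32)  # ≤22 | 23–32 | >32, at transaction time
SUBGROUP_AXES = (
    "partner_status",
    "focal_status",
    "dyad_status_combo",
    "partner_gender",
    "focal_gender",
    "partner_age_tercile",
    "focal_age_tercile",
)

LOW_N_THRESHOLD = 30


def age_tercile(birth_year: int, txn_date) -> str:
    """Age bin at transaction time: 'le22', '23-32', or 'gt32'.

    Age is years elapsed since January 1 of the birth year, floored — i.e.
    transaction year minus birth year.
    """
    age = pd.Timestamp(txn_date).year - int(birth_year)
    if age <= AGE_TERCILE_EDGES[0]:
        return "le22"
    if age <= AGE_TERCILE_EDGES[1]:
        return "23-32"
    return "gt32"


def _user_attr(demographics: pd.DataFrame, user, col: str):
    try:
        return demographics.at[user, col]
    except KeyError:
        return None


def _axis_values(pairs: pd.DataFrame, demographics: pd.DataFrame, axis: str):
    """Per-pair subgroup level, or None (unknown / discordant focal attribute)."""

    def status(u):
        return _user_attr(demographics, u, "status")

    def gender(u):
        return _user_attr(demographics, u, "gender")

    def tercile(u, date):
        by = _user_attr(demographics, u, "birth_year")
        return None if by is None else age_tercile(by, date)

    vals = []
    n_discordant = 0
    for row in pairs.itertuples():
        if axis == "partner_status":
            vals.append(status(row.partner_user))
        elif axis == "partner_gender":
            vals.append(gender(row.partner_user))
        elif axis == "partner_age_tercile":
            # partner identity is shared, but ages may straddle a birthday
            a = tercile(row.partner_user, row.treated_date)
            b = tercile(row.partner_user, row.control_date)
            if a != b:
                n_discordant += 1
                vals.append(None)
            else:
                vals.append(a)
        elif axis == "focal_status":
            a, b = status(row.treated_focal_user), status(row.control_focal_user)
            if a is None or b is None or a != b:
                n_discordant += a is not None and b is not None and a != b
                vals.append(None)
            else:
                vals.append(a)
        elif axis == "focal_gender":
            a, b = gender(row.treated_focal_user), gender(row.control_focal_user)
            if a is None or b is None or a != b:
                n_discordant += a is not None and b is not None and a != b
                vals.append(None)
            else:
                vals.append(a)
        elif axis == "focal_age_tercile":
            a = tercile(row.treated_focal_user, row.treated_date)
            b = tercile(row.control_focal_user, row.control_date)
            if a is None or b is None or a != b:
                n_discordant += a is not None and b is not None and a != b
                vals.append(None)
            else:
                vals.append(a)
        elif axis == "dyad_status_combo":
            ps = status(row.partner_user)
            fa, fb = status(row.treated_focal_user), status(row.control_focal_user)
            if ps is None or fa is None or fb is None or fa != fb:
                n_discordant += fa is not None and fb is not None and fa != fb
                vals.append(None)
            else:
                vals.append(f"{ps}-{fa}")
        else:
            raise ValueError(f"unknown subgroup axis: {axis}")
    return vals, int(n_discordant)


@dataclass
class SubgroupResult:
    axis: str
    estimates: list[EffectEstimate] = field(default_factory=list)
    n_dropped_discordant: int = 0
    n_unknown: int = 0


def subgroup_estimates(
    pairs: pd.DataFrame,
    demographics: pd.DataFrame,
    axis: str,
    boot_reps: int = 1000,
    seed: int = 0,
) -> SubgroupResult:
    """Effect estimates within levels of a demographic axis.

    Partner attributes are constant within a pair by construction; for focal
    axes, pairs whose treated and control focals disagree on the attribute
    are dropped and counted.  Levels with fewer than 30 pairs are flagged
    ``low_n``.
    """
    vals, n_disc = _axis_values(pairs, demographics, axis)
    result = SubgroupResult(axis=axis, n_dropped_discordant=n_disc)
    ser = pd.Series(vals, index=pairs.index, dtype=object)
    result.n_unknown = int(ser.isna().sum()) - n_disc
    for k, level in enumerate(sorted(ser.dropna().unique())):
        sub = pairs[ser == level]
        counts = tabulate(sub)
        est = estimate(counts, boot_reps=boot_reps, seed=seed + k, subgroup=str(level))
        if counts.n < LOW_N_THRESHOLD:
            est = EffectEstimate(
                rd=est.rd, rr=est.rr, ci_rd=est.ci_rd, ci_rr=est.ci_rr,
                n_pairs=est.n_pairs, item=est.item, subgroup=est.subgroup, low_n=True,
            )
        result.estimates.append(est)
    return result
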