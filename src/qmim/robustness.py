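"""Robustness analyses: randomized-partner baseline, dose–response over queue
lag, and Rosenbaum sensitivity with amplification.

*Randomized baseline.*  Each dyad's partner transaction is replaced by a
uniformly sampled transaction from the same (shop, date, period) stratum,
excluding the focal user's own transactions; matching and estimation are then
re-run unchanged.  Whatever effect survives reflects shared context rather
than queue adjacency, so on mimicry-only data the baseline should vanish.

*Dose–response.*  If mimicry is causal it should fade with the time lag
between the two purchases.  Matched pairs are binned by the treated dyad's
lag (10-s bins over 0–120 s), RD and RR are estimated per bin, and a weighted
least-squares line (weights = pair counts) is fitted over bin midpoints.

*Sensitivity.*  Rosenbaum's Γ bounds the p-value of the paired sign test
under a hidden bias that multiplies the within-pair treatment odds by up to
Γ: pbound(Γ) = P[Binomial(n10+n01, Γ/(1+Γ)) ≥ n10].  ``gamma_star`` is the
smallest Γ at which that upper bound crosses α.  Amplification re-expresses a
given Γ as a curve of two-parameter confounders (Λ, Δ) with
Γ = (ΛΔ + 1)/(Λ + Δ), where Λ multiplies the odds of treatment and Δ the
odds of a positive outcome difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .effects import ContingencyCounts, estimate, tabulate

__all__ = [
    "randomize_partners",
    "dose_response",
    "DoseResponseFit",
    "rosenbaum_gamma",
    "SensitivityResult",
    "amplify",
    "gamma_from_lambda_delta",
    "AmplificationCurve",
]


def randomize_partners(
    dyads: pd.DataFrame,
    log: pd.DataFrame,
    seed: int = 0,
    exclude_true_partner: bool = False,
) -> tuple[pd.DataFrame, int]:
    """Replace each dyad's partner with a random same-stratum transactor.

    The replacement transaction is drawn uniformly from the dyad's
    (shop, date, period) stratum of the annotated *log*, excluding the focal
    user's own transactions (and, optionally, the true partner's).  Returns
    the randomized dyad frame and the number of dyads dropped because their
    stratum held no eligible replacement.
    """
    rng = np.random.default_rng(seed)
    in_period = log["period"].notna()
    sub = log[in_period]
    strata = {
        key: grp
        for key, grp in sub.groupby(
            [sub["shop_id"], sub["date"], sub["period"].astype(str)], sort=False
        )
    }
    out = dyads.copy().reset_index(drop=True)
    partner_cols = [
        "partner_txn",
        "partner_user",
        "partner_anchor",
        "partner_items",
        "partner_categories",
        "partner_has_veg_meal",
        "partner_timestamp",
    ]
    log_cols = ["txn_id", "user_id", "anchor", "items", "categories", "has_veg_meal", "timestamp"]
    dropped = 0
    keep = np.ones(len(out), dtype=bool)
    new_vals = {c: out[c].tolist() for c in partner_cols}
    for i, row in enumerate(out.itertuples()):
        grp = strata.get((row.shop_id, row.date, str(row.period)))
        if grp is None:
            keep[i] = False
            dropped += 1
            continue
        ok = grp["user_id"].to_numpy() != row.focal_user
        if exclude_true_partner:
            ok &= grp["user_id"].to_numpy() != row.partner_user
        idxs = np.flatnonzero(ok)
        if len(idxs) == 0:
            keep[i] = False
            dropped += 1
            continue
        j = idxs[rng.integers(len(idxs))] if len(idxs) > 1 else idxs[0]
        pick = grp.iloc[j]
        for pc, lc in zip(partner_cols, log_cols):
            new_vals[pc][i] = pick[lc]
    for c in partner_cols:
        out[c] = new_vals[c]
    out = out[keep].reset_index(drop=True)
    return out, dropped


@dataclass
class DoseResponseFit:
    """Binned RD/RR by queue lag, with weighted least-squares slopes."""

    bin_edges: np.ndarray
    bin_mid: np.ndarray
    rd: np.ndarray
    rr: np.ndarray
    n_pairs: np.ndarray
    slope_rd: float
    p_rd: float
    slope_rr: float
    p_rr: float
    intercept_rd: float = float("nan")
    intercept_rr: float = float("nan")


def _wls_slope(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float, float]:
    """Weighted least squares y ~ x; returns (slope, intercept, two-sided p)."""
    import statsmodels.api as sm

    X = sm.add_constant(x)
    fit = sm.WLS(y, X, weights=w).fit()
    return float(fit.params[1]), float(fit.params[0]), float(fit.pvalues[1])


def dose_response(
    pairs: pd.DataFrame,
    bin_width: float = 10.0,
    max_lag: float = 120.0,
    lag_mode: str = "treated",
    boot_reps: int = 0,
    seed: int = 0,
) -> DoseResponseFit:
    """Estimate RD/RR per lag bin and the linear trend across bins.

    Each matched pair's lag is the treated dyad's inter-arrival time
    (``lag_mode="mean"`` averages treated and control lags).  Pairs with lag
    ≥ *max_lag* are excluded from the fit.  Bins with no pairs, or with an
    undefined RR, carry NaN and zero weight.
    """
    if lag_mode == "treated":
        lag = pairs["treated_lag"].to_numpy(dtype=float)
    elif lag_mode == "mean":
        lag = (
            pairs["treated_lag"].to_numpy(dtype=float)
            + pairs["control_lag"].to_numpy(dtype=float)
        ) / 2.0
    else:
        raise ValueError("lag_mode must be 'treated' or 'mean'")
    edges = np.arange(0.0, max_lag + bin_width, bin_width)
    mids = (edges[:-1] + edges[1:]) / 2.0
    nbins = len(mids)
    rd = np.full(nbins, np.nan)
    rr = np.full(nbins, np.nan)
    npair = np.zeros(nbins, dtype=int)
    for b in range(nbins):
        mask = (lag >= edges[b]) & (lag < edges[b + 1])
        if not mask.any():
            continue
        counts = tabulate(pairs[mask])
        npair[b] = counts.n
        est = estimate(counts, boot_reps=boot_reps, seed=seed + b)
        rd[b] = est.rd
        rr[b] = est.rr if est.rr is not None else np.nan
    ok_rd = ~np.isnan(rd)
    if ok_rd.sum() < 3:
        raise ValueError("dose-response fit needs at least 3 non-empty lag bins")
    s_rd, i_rd, p_rd = _wls_slope(mids[ok_rd], rd[ok_rd], npair[ok_rd])
    ok_rr = ~np.isnan(rr)
    if ok_rr.sum() >= 3:
        s_rr, i_rr, p_rr = _wls_slope(mids[ok_rr], rr[ok_rr], npair[ok_rr])
    else:
        s_rr = i_rr = p_rr = float("nan")
    return DoseResponseFit(
        bin_edges=edges, bin_mid=mids, rd=rd, rr=rr, n_pairs=npair,
        slope_rd=s_rd, p_rd=p_rd, slope_rr=s_rr, p_rr=p_rr,
        intercept_rd=i_rd, intercept_rr=i_rr,
    )


@dataclass
class SensitivityResult:
    """Rosenbaum bound: smallest Γ at which significance would be lost."""

    gamma_star: float
    alpha: float
    p_at_1: float
    counts: ContingencyCounts = field(repr=False, default=None)

    def pbound(self, gamma: float) -> float:
        return _pbound(self.counts, gamma)


def _pbound(counts: ContingencyCounts, gamma: float) -> float:
    """Upper bound on the one-sided sign-test p-value under bias Γ."""
    if gamma < 1:
        raise ValueError("gamma must be >= 1")
    d = counts.n10 + counts.n01
    return float(stats.binom.sf(counts.n10 - 1, d, gamma / (1.0 + gamma)))


def rosenbaum_gamma(
    counts: ContingencyCounts, alpha: float = 0.05, tol: float = 1e-3, gamma_max: float = 1e3
) -> SensitivityResult:
    """Sensitivity of the paired sign test to hidden treatment-assignment bias.

    Finds, by bisection to *tol*, the smallest Γ ≥ 1 at which the worst-case
    one-sided p-value ``pbound(Γ)`` exceeds *alpha*.  When the observed
    discordant split already favours the null (n10 ≤ n01) or is not
    significant at Γ = 1, there is no effect to explain away and Γ* = 1.
    """
    if counts.n10 + counts.n01 == 0:
        raise ValueError("no discordant pairs: sensitivity undefined")
    p1 = _pbound(counts, 1.0)
    if counts.n10 <= counts.n01 or p1 > alpha:
        return SensitivityResult(gamma_star=1.0, alpha=alpha, p_at_1=p1, counts=counts)
    lo, hi = 1.0, 2.0
    while _pbound(counts, hi) <= alpha:
        lo, hi = hi, hi * 2.0
        if hi > gamma_max:
            return SensitivityResult(
                gamma_star=float("inf"), alpha=alpha, p_at_1=p1, counts=counts
            )
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if _pbound(counts, mid) > alpha:
            hi = mid
        else:
            lo = mid
    return SensitivityResult(gamma_star=hi, alpha=alpha, p_at_1=p1, counts=counts)


@dataclass
class AmplificationCurve:
    """(Λ, Δ) pairs on the curve Γ = (ΛΔ + 1)/(Λ + Δ) for a fixed Γ."""

    gamma: float
    lambdas: np.ndarray
    deltas: np.ndarray
    skipped: int = 0


def gamma_from_lambda_delta(lam: float, delta: float) -> float:
    """Collapse a two-parameter confounder (Λ, Δ) to its single-Γ equivalent."""
    return (lam * delta + 1.0) / (lam + delta)


def amplify(gamma: float, lambdas) -> AmplificationCurve:
    """Solve Δ for each Λ on the amplification curve of *gamma*.

    Δ = (ΛΓ − 1)/(Λ − Γ), defined only for Λ > Γ; grid points at or below Γ
    are skipped and counted.
    """
    if gamma <= 1:
        raise ValueError("amplification needs gamma > 1")
    lambdas = np.asarray(lambdas, dtype=float)
    ok = lambdas > gamma
    lam = lambdas[ok]
    deltas = (lam * gamma - 1.0) / (lam - gamma)
    return AmplificationCurve(
        gamma=gamma, lambdas=lam, deltas=deltas, skipped=int(np.sum(~ok))
    )
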