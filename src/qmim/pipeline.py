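"""End-to-end study orchestration.

``run`` drives the full design from one configuration: simulate (or read) a
transaction log, extract and filter dyads, build the popularity index, match
treated to control dyads per focus item, estimate per-item and pooled
effects, and run the robustness battery (randomized-partner baseline,
dose–response over queue lag, Rosenbaum sensitivity with amplification).
The result is a single JSON-serialisable report that echoes every stage's
parameters and records the filter funnel (transactions → dyads → frequent
dyads → dyads used in matched pairs).

All randomness is funnelled through one seeded generator per stage, with
stage seeds derived from the master seed by hashing the stage name, so two
runs with the same configuration produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dyads as dy
from . import effects as ef
from . import matching as mt
from . import robustness as rb
from . import synthgen as sg
from . import transactions as tx

__all__ = ["RunConfig", "run", "stage_seed", "SCHEMA_VERSION"]

logger = logging.getLogger("qmim")

SCHEMA_VERSION = "1.0"


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the master seed by hashing the stage name."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).hexdigest()
    return int(h[:8], 16) % (2**31)


@dataclass
class RunConfig:
    """One study run: input mode, analysis list, and stage parameters."""

    mode: str = "simulate"  # "simulate" | "files"
    sim: dict = field(default_factory=dict)  # SimConfig field overrides
    log_path: str | None = None
    catalog_path: str | None = None
    demographics_path: str | None = None
    items: list | None = None  # None → all 13 additions + 2 anchor analyses
    window_seconds: float = 300.0
    min_joint: int = 10
    pair_count_ordering: str = "pooled"
    caliper: float = 0.10
    caliper_mode: str = "relative"
    exact_anchor: bool = False
    popularity_loo: bool = True
    boot_reps: int = 1000
    subgroup_axes: list = field(default_factory=list)
    randomized_baseline: bool = True
    exclude_true_partner: bool = False
    dose_response: bool = True
    dose_bin_width: float = 10.0
    dose_max_lag: float = 120.0
    dose_lag_mode: str = "treated"
    sensitivity: bool = True
    sensitivity_alpha: float = 0.05
    seed: int = 0
    out_dir: str | None = None

    _KNOWN = None  # filled below

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown RunConfig keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def focus_items(self) -> tuple[mt.FocusItem, ...]:
        if self.items is None:
            return mt.ALL_FOCUS_ITEMS
        out = []
        for entry in self.items:
            if isinstance(entry, str):
                out.append(mt.focus_item(entry))
            else:
                per = entry.get("period")
                if per is not None:
                    per = tx.MealPeriod(per) if isinstance(per, str) else per
                out.append(mt.focus_item(entry["label"], per))
        return tuple(out)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else f
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def _counts_dict(c: ef.ContingencyCounts) -> dict:
    return {
        "n11": c.n11, "n10": c.n10, "n01": c.n01, "n00": c.n00, "n": c.n,
        "shares": c.shares(),
        "treated_rate": c.treated_rate if c.n else None,
        "control_rate": c.control_rate if c.n else None,
    }


def _est_dict(e: ef.EffectEstimate) -> dict:
    return {
        "rd": e.rd, "rr": e.rr, "ci_rd": e.ci_rd, "ci_rr": e.ci_rr,
        "relative_effect": e.relative_effect, "n_pairs": e.n_pairs,
        "low_n": e.low_n,
    }


def _match_all(
    dyad_frame: pd.DataFrame,
    items,
    pop: mt.PopularityIndex,
    cfg: RunConfig,
    seed_stage: str,
) -> dict[str, pd.DataFrame]:
    out = {}
    for item in items:
        pairs = mt.match_pairs(
            dyad_frame,
            item,
            pop,
            caliper=cfg.caliper,
            caliper_mode=cfg.caliper_mode,
            exact_anchor=cfg.exact_anchor,
            popularity_loo=cfg.popularity_loo,
            seed=stage_seed(cfg.seed, f"{seed_stage}:{item.name}"),
        )
        out[item.name] = pairs
    return out


def run(config: RunConfig) -> dict:
    """Execute the full study and return the report dictionary."""
    cfg = config
    report: dict = {"schema_version": SCHEMA_VERSION, "config": _jsonify(dataclasses.asdict(cfg))}

    # --- input ------------------------------------------------------------
    if cfg.mode == "simulate":
        sim_cfg = sg.default_config(**cfg.sim)
        if "seed" not in cfg.sim:
            sim_cfg = dataclasses.replace(sim_cfg, seed=stage_seed(cfg.seed, "simulate"))
        sim = sg.simulate(sim_cfg)
        log, catalog, demographics = sim.log, sim.catalog, sim.demographics
        report["simulation"] = {
            "clip_fraction": sim.clip_fraction,
            "rd_star": sg.rd_star(sim.truth),
            "seed": sim_cfg.seed,
        }
    elif cfg.mode == "files":
        if not (cfg.log_path and cfg.catalog_path):
            raise ValueError("files mode needs log_path and catalog_path")
        catalog = tx.read_catalog(cfg.catalog_path)
        log = tx.annotate(tx.read_transactions(cfg.log_path, catalog), catalog)
        demographics = (
            tx.read_demographics(cfg.demographics_path)
            if cfg.demographics_path
            else None
        )
    else:
        raise ValueError(f"unknown mode: {cfg.mode}")
    logger.info("transactions: %d", len(log))

    # --- dyads ------------------------------------------------------------
    all_dyads = dy.extract_dyads(log, window_seconds=cfg.window_seconds)
    frequent = dy.filter_frequent_pairs(
        all_dyads, min_joint=cfg.min_joint, pair_count_ordering=cfg.pair_count_ordering
    )
    logger.info("dyads: %d, after >=%d filter: %d", len(all_dyads), cfg.min_joint, len(frequent))
    summ = dy.dyad_summary(frequent)
    report["dyads"] = {
        "n_dyads": len(all_dyads),
        "n_frequent": len(frequent),
        "mean_lag": summ.mean_lag,
        "sd_lag": summ.sd_lag,
        "frac_lag_under_60s": summ.frac_lag_under_60s,
        "anchor_shares": summ.anchor_shares,
    }

    items = cfg.focus_items()
    pop = mt.build_popularity_index(log)

    # --- matching + per-item estimation -----------------------------------
    pairs_by_item = _match_all(frequent, items, pop, cfg, "match")
    per_item = {}
    pooled_counts = ef.ContingencyCounts(0, 0, 0, 0)
    addition_frames = []
    used_dyads: set = set()
    for item in items:
        pairs = pairs_by_item[item.name]
        entry: dict = {"n_pairs": len(pairs)}
        if len(pairs) >= 2:
            counts = ef.tabulate(pairs)
            est = ef.estimate(
                counts,
                boot_reps=cfg.boot_reps,
                seed=stage_seed(cfg.seed, f"estimate:{item.name}"),
                item=item.name,
            )
            bal = mt.balance(pairs, frequent, item, pop, popularity_loo=cfg.popularity_loo)
            entry.update(
                counts=_counts_dict(counts),
                estimate=_est_dict(est),
                balance={
                    "smd_before": bal.smd_before,
                    "smd_after": bal.smd_after,
                    "passed": bal.passed,
                },
            )
            if item.kind == "addition":
                pooled_counts = pooled_counts + counts
                addition_frames.append(pairs)
        per_item[item.name] = entry
        used_dyads.update(pairs["treated_index"].tolist())
        used_dyads.update(pairs["control_index"].tolist())
    report["per_item"] = per_item

    pooled_pairs = (
        pd.concat(addition_frames, ignore_index=True)
        if addition_frames
        else pd.DataFrame(columns=mt.PAIR_COLUMNS)
    )

    report["funnel"] = {
        "n_transactions": len(log),
        "n_dyads": len(all_dyads),
        "n_frequent_dyads": len(frequent),
        "n_dyads_in_matched_pairs": len(used_dyads),
    }

    # --- pooled analysis ---------------------------------------------------
    pooled: dict = {"n_pairs": int(pooled_counts.n)}
    if pooled_counts.n > 0:
        est = ef.estimate(
            pooled_counts, boot_reps=cfg.boot_reps, seed=stage_seed(cfg.seed, "estimate:pooled")
        )
        stat, pval = ef.paired_chi2(pooled_counts)
        pooled.update(
            counts=_counts_dict(pooled_counts),
            estimate=_est_dict(est),
            mcnemar={"chi2": stat, "p_value": pval},
        )
        if cfg.sensitivity and pooled_counts.n10 + pooled_counts.n01 > 0:
            sens = rb.rosenbaum_gamma(pooled_counts, alpha=cfg.sensitivity_alpha)
            pooled["sensitivity"] = {
                "gamma_star": sens.gamma_star,
                "alpha": sens.alpha,
                "p_at_gamma_1": sens.p_at_1,
            }
            if np.isfinite(sens.gamma_star) and sens.gamma_star > 1:
                curve = rb.amplify(
                    sens.gamma_star, np.linspace(sens.gamma_star * 1.05, sens.gamma_star * 5, 9)
                )
                pooled["amplification"] = {
                    "lambdas": curve.lambdas, "deltas": curve.deltas,
                }
    report["pooled"] = pooled
    report["naive_contrast"] = ef.unmatched_contrast(
        frequent, [i for i in items if i.kind == "addition"]
    )

    # --- subgroups ---------------------------------------------------------
    if cfg.subgroup_axes and demographics is not None and len(pooled_pairs):
        sub_report = {}
        for axis in cfg.subgroup_axes:
            res = ef.subgroup_estimates(
                pooled_pairs,
                demographics,
                axis,
                boot_reps=cfg.boot_reps,
                seed=stage_seed(cfg.seed, f"subgroup:{axis}"),
            )
            sub_report[axis] = {
                "levels": {e.subgroup: _est_dict(e) for e in res.estimates},
                "n_dropped_discordant": res.n_dropped_discordant,
                "n_unknown": res.n_unknown,
            }
        report["subgroups"] = sub_report

    # --- robustness --------------------------------------------------------
    if cfg.randomized_baseline:
        rnd, dropped = rb.randomize_partners(
            frequent,
            log,
            seed=stage_seed(cfg.seed, "randomize"),
            exclude_true_partner=cfg.exclude_true_partner,
        )
        rnd_pairs_by_item = _match_all(rnd, items, pop, cfg, "match-randomized")
        rnd_counts = ef.ContingencyCounts(0, 0, 0, 0)
        for item in items:
            if item.kind == "addition":
                rnd_counts = rnd_counts + ef.tabulate(rnd_pairs_by_item[item.name])
        entry = {"n_dropped": dropped, "n_pairs": int(rnd_counts.n)}
        if rnd_counts.n > 0:
            est = ef.estimate(
                rnd_counts, boot_reps=cfg.boot_reps, seed=stage_seed(cfg.seed, "estimate:randomized")
            )
            entry["counts"] = _counts_dict(rnd_counts)
            entry["estimate"] = _est_dict(est)
        report["randomized_baseline"] = entry

    if cfg.dose_response and len(pooled_pairs) > 0:
        try:
            fit = rb.dose_response(
                pooled_pairs,
                bin_width=cfg.dose_bin_width,
                max_lag=cfg.dose_max_lag,
                lag_mode=cfg.dose_lag_mode,
            )
            report["dose_response"] = {
                "bin_mid": fit.bin_mid, "rd": fit.rd, "rr": fit.rr,
                "n_pairs": fit.n_pairs,
                "slope_rd": fit.slope_rd, "p_rd": fit.p_rd,
                "slope_rr": fit.slope_rr, "p_rr": fit.p_rr,
            }
        except ValueError as exc:
            report["dose_response"] = {"error": str(exc)}

    report = _jsonify(report)

    # --- outputs -----------------------------------------------------------
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        rows = []
        for name, entry in per_item.items():
            if "estimate" in entry:
                e = entry["estimate"]
                rows.append(
                    {
                        "item": name, "n_pairs": entry["n_pairs"],
                        "rd": e["rd"], "rr": e["rr"],
                        "ci_rd_lo": e["ci_rd"][0] if e["ci_rd"] else None,
                        "ci_rd_hi": e["ci_rd"][1] if e["ci_rd"] else None,
                    }
                )
        pd.DataFrame(rows).to_csv(out / "effects.csv", index=False)
        pairs_dir = out / "pairs"
        pairs_dir.mkdir(exist_ok=True)
        for name, pairs in pairs_by_item.items():
            if len(pairs):
                pairs.to_csv(pairs_dir / f"{name.replace('@', '_')}.csv", index=False)
    return report
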