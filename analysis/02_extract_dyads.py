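#!/usr/bin/env python
"""Extract adjacent-purchase dyads from the simulated log and describe them.

A dyad is two consecutive anchored transactions at the same register within
5 minutes by different people; only user pairs seen adjacent at least 10
times are kept, so each partner can later serve as their own control.
Reads scratch/transactions.csv (written by 01_simulate.py), writes the dyad
table to scratch/ and the descriptive summary to results/.
"""

import json
from pathlib import Path

from qmim import dyads as dy
from qmim import transactions as tx

SCRATCH = Path(__file__).resolve().parents[1] / "scratch"
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    catalog = tx.read_catalog(SCRATCH / "catalog.csv")
    log = tx.annotate(tx.read_transactions(SCRATCH / "transactions.csv", catalog), catalog)
    all_dyads = dy.extract_dyads(log)
    frequent = dy.filter_frequent_pairs(all_dyads, min_joint=10)
    dy.write_dyads_csv(frequent, SCRATCH / "dyads.csv")

    s = dy.dyad_summary(frequent)
    summary = {
        "n_transactions": len(log),
        "n_dyads": len(all_dyads),
        "n_frequent_dyads": len(frequent),
        "mean_lag_seconds": s.mean_lag,
        "sd_lag_seconds": s.sd_lag,
        "frac_lag_under_60s": s.frac_lag_under_60s,
        "anchor_shares": s.anchor_shares,
    }
    (RESULTS / "dyad_summary.json").write_text(json.dumps(summary, indent=2))
    print(
        f"{len(all_dyads)} dyads, {len(frequent)} after the >=10 filter; "
        f"mean lag {s.mean_lag:.1f}s (SD {s.sd_lag:.1f}), "
        f"{s.frac_lag_under_60s:.1%} under a minute"
    )
    print("breakfast anchors:", s.anchor_shares.get("breakfast"))


if __name__ == "__main__":
    main()
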