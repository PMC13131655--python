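#!/usr/bin/env python
"""Per-branch genome gain/loss and TE-insertion attribution.

Accumulates insertion/deletion bp per branch of the dated species tree,
merges lifted insertion fragments (< 100 bp, same ancestral event),
attributes merged insertions to TE copies at 75% reciprocal overlap, and
extracts the per-MY insertion-rate curve along the focal terminal lineage.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from notokit.branch_dynamics import (
    attribute_te_insertions,
    merge_lifted_insertions,
    net_gain_rates,
    rate_curve,
)
from notokit.io import read_branch_mutations, read_dated_tree, read_repeat_table


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--focal-leaf", default="HarAnt")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    tree = read_dated_tree(args.data / "species_tree.nwk")
    muts = read_branch_mutations(args.data / "branch_mutations.tsv")
    repeats = read_repeat_table(args.data / "branch_repeats.tsv")
    truth = json.loads((args.data / "truth_branches.json").read_text())

    rates = net_gain_rates(muts, tree)
    merged = merge_lifted_insertions(muts, max_gap=100)
    attributed = attribute_te_insertions(merged, repeats, tree)

    rows = []
    for bid in sorted(tree.durations):
        r, a, t = rates[bid], attributed[bid], truth["per_branch"][bid]
        rows.append(
            {
                "branch_id": bid,
                "ins_bp": r.ins_bp,
                "del_bp": r.del_bp,
                "net_bp": r.net_bp,
                "duration_my": r.duration_my,
                "net_rate_mb_per_my": r.net_rate_mb_per_my,
                "te_insertions": a.te_insertions,
                "te_per_my": a.te_per_my,
                "planted_te_events": t["n_te_events"],
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(args.out / "branch_rates.tsv", sep="\t", index=False)
    curve = rate_curve(attributed, tree, args.focal_leaf)
    curve.to_csv(args.out / f"rate_curve_{args.focal_leaf}.tsv", sep="\t", index=False)

    exact = int((df.te_insertions == df.planted_te_events).sum())
    print(df.to_string(index=False))
    print(
        f"TE attribution exact on {exact}/{len(df)} branches; "
        f"focal-path curve -> rate_curve_{args.focal_leaf}.tsv "
        f"(integral {float((curve.rate_per_my * curve.duration_my).sum()):.1f} "
        f"= {int(curve.te_insertions.sum())} insertions)"
    )


if __name__ == "__main__":
    main()
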