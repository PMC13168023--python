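#!/usr/bin/env python
"""Classify cross-stage edge conservation versus heterogeneity.

Matches edges across the three stage networks, runs the fixed-effect
Fisher-z meta-analysis per shared edge (Cochran's Q, I2), labels edges
stable (p_Q > 0.05) or heterogeneous (I2 > 75% and BH-adjusted p_Q <
0.05), categorises heterogeneous D25-vs-D120 pairs as reversed /
strengthened / weakened, and writes the summary proportions.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from coabnet import edgedyn, io

ROOT = Path(__file__).resolve().parents[1]
STAGES = ["D25", "D120", "D240"]


def main():
    netdir = ROOT / "results" / "networks"
    if not (netdir / "network_D25.graphml").exists():
        sys.exit("run analysis/02_infer_networks.py first")
    nets = [io.read_graphml(netdir / f"network_{s}.graphml") for s in STAGES]
    table = edgedyn.match_edges(nets)
    shared_all = table[[f"present_{s}" for s in STAGES]].all(axis=1).sum()
    print(f"{len(table)} distinct edges; {shared_all} present in all three stages")

    classified = edgedyn.classify_conservation(table, stages=STAGES)
    cats = []
    for _, row in classified.iterrows():
        if row["label"] != "heterogeneous":
            cats.append("")
            continue
        cat, _ = edgedyn.classify_pairwise_change(
            row["r_D25"], row["r_D120"],
            row.get("q_D25", 1.0) < 0.05, row.get("q_D120", 1.0) < 0.05,
        )
        cats.append(cat)
    classified["pairwise_category"] = cats

    outdir = ROOT / "results"
    classified.to_csv(outdir / "edge_dynamics.tsv", sep="\t", index=False)
    summary = edgedyn.summarize_conservation(classified["label"])
    summary.to_csv(outdir / "conservation_summary.tsv", sep="\t", index=False)

    for _, row in summary[summary.stratum == "overall"].iterrows():
        print(f"  {row['label']}: {row['count']}/{row['total']} ({row['percent']}%)")
    het = classified[classified.label == "heterogeneous"]
    if len(het):
        print("  heterogeneous D25-vs-D120 categories:",
              dict(het.pairwise_category.value_counts()))


if __name__ == "__main__":
    main()
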