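#!/usr/bin/env python
"""Phenotype association scan and two-guild detection at the growth stage.

Regresses log-TSS abundance of every D120 taxon on the continuous
growth phenotype (BH FDR < 0.2), builds the signed co-abundance graph
among significant features from the D120 network, two-colours it into
antagonistic guilds, and compares guild summed abundance between the
extreme phenotype quartiles with a Wilcoxon rank-sum test.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from coabnet import guilds, io

ROOT = Path(__file__).resolve().parents[1]


def main():
    data = ROOT / "results" / "data"
    netdir = ROOT / "results" / "networks"
    if not (netdir / "network_D120.graphml").exists():
        sys.exit("run analysis/02_infer_networks.py first")
    counts = io.read_abundance(data / "abundance_D120.tsv")
    meta = io.read_metadata(data / "metadata.tsv")
    phenotype = meta.loc[meta.stage == "D120", "phenotype"].reindex(counts.columns)

    assoc = guilds.associate_features(counts, phenotype)
    assoc.to_csv(ROOT / "results" / "associations.tsv", sep="\t", index=False)
    n_pos = ((assoc.significant) & (assoc.direction == "positive")).sum()
    n_neg = ((assoc.significant) & (assoc.direction == "negative")).sum()
    print(f"{assoc.significant.sum()} of {len(assoc)} taxa associated with the "
          f"phenotype at FDR<0.2 ({n_pos} positive, {n_neg} negative)")

    sig = set(assoc.loc[assoc.significant, "feature"])
    direction = dict(zip(assoc.feature, assoc.direction))
    net = io.read_graphml(netdir / "network_D120.graphml")
    g = nx.Graph()
    g.add_nodes_from(sorted(sig))
    for a, b, d in net.edges(data=True):
        if a in sig and b in sig:
            g.add_edge(a, b, r=d["r"])
    part = guilds.detect_guilds(g, phenotype_direction=direction)
    pd.DataFrame(
        sorted([(m, "guild1") for m in part.guild1]
               + [(m, "guild2") for m in part.guild2]
               + [(m, "unassigned") for m in part.unassigned]),
        columns=["feature", "guild"],
    ).to_csv(ROOT / "results" / "guild_membership.tsv", sep="\t", index=False)
    print(f"guilds: {len(part.guild1)} + {len(part.guild2)} members, "
          f"{len(part.unassigned)} unassigned, "
          f"{len(part.frustrated_edges)} frustrated edges")

    gab = guilds.guild_abundance(counts, part)
    gab.to_csv(ROOT / "results" / "guild_abundance.tsv", sep="\t")
    q1, q3 = phenotype.quantile([0.25, 0.75])
    extreme = phenotype[(phenotype <= q1) | (phenotype >= q3)]
    labels = np.where(extreme >= q3, "high", "low")
    for guild in ("guild1", "guild2"):
        stat, p = guilds.compare_groups(gab.loc[extreme.index, guild], labels)
        hi = gab.loc[extreme.index[labels == "high"], guild].median()
        lo = gab.loc[extreme.index[labels == "low"], guild].median()
        print(f"  {guild}: median abundance high={hi:.4f} vs low={lo:.4f} "
              f"(Wilcoxon p={p:.3g})")


if __name__ == "__main__":
    main()
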