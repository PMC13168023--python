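#!/usr/bin/env python
"""Metabolic competition/complementarity scoring of guild members.

Reads the precomputed pairwise MRO (resource overlap, competition) and
MIP (interaction potential, complementarity) fixtures, derives the
combined metabolic distance D = 1 - (MRO - MIP) and the composite
competition intensity C = Z(MRO) - Z(MIP) over between-guild pairs,
flags the upper quartile as competitive, finds MIP outliers relative to
phylogenetic distance (Z > 2.698), classifies per-guild core/shell/cloud
pathways, and ranks the metabolites competitive pairs jointly demand.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from coabnet import metanet

ROOT = Path(__file__).resolve().parents[1]


def main():
    mdir = ROOT / "results" / "data" / "metabolic"
    if not (mdir / "mro.tsv").exists():
        sys.exit("run analysis/01_simulate.py first")
    mro = pd.read_csv(mdir / "mro.tsv", sep="\t", index_col=0)
    mip = pd.read_csv(mdir / "mip.tsv", sep="\t", index_col=0)
    dist = pd.read_csv(mdir / "phylo_distance.tsv", sep="\t", index_col=0)
    pathways = pd.read_csv(mdir / "pathway_presence.tsv", sep="\t", index_col=0)
    labels = pd.read_csv(mdir / "guild_labels.tsv", sep="\t", index_col=0)["guild"]
    exchange = pd.read_csv(mdir / "exchange.tsv", sep="\t")

    pairs = metanet.pair_table(mro, mip, labels, dist)
    pairs["distance"] = metanet.metabolic_distance(pairs["mro"], pairs["mip"])
    within = pairs.pair_class.str.startswith("within")
    print(f"{len(pairs)} strain pairs; mean metabolic distance within guilds "
          f"{pairs.loc[within, 'distance'].mean():.3f} vs between "
          f"{pairs.loc[~within, 'distance'].mean():.3f}")

    between = pairs.pair_class == "between"
    pairs["competition_intensity"] = np.nan
    pairs.loc[between, "competition_intensity"] = metanet.competition_intensity(
        pairs.loc[between, "mro"], pairs.loc[between, "mip"]
    )
    ids = (pairs.loc[between, "strain_a"] + "|" + pairs.loc[between, "strain_b"]).to_numpy()
    pairs["competitive"] = False
    pairs.loc[between, "competitive"] = metanet.classify_competitive(
        pairs.loc[between, "competition_intensity"].to_numpy(), pair_ids=ids
    )
    pairs["phylo_outlier"] = metanet.phylo_outliers(pairs["mip"], pairs["phylo_distance"])
    pairs.sort_values(["strain_a", "strain_b"]).to_csv(
        ROOT / "results" / "metabolic_pairs.tsv", sep="\t", index=False
    )
    print(f"{int(pairs.competitive.sum())} of {int(between.sum())} between-guild "
          f"pairs flagged competitive (upper quartile); "
          f"{int(pairs.phylo_outlier.sum())} phylogeny-adjusted MIP outliers")

    classes = metanet.core_cloud_pathways(pathways, labels)
    classes.to_csv(ROOT / "results" / "pathway_classes.tsv", sep="\t", index=False)
    for guild, block in classes.groupby("guild"):
        frac = (block["class"].value_counts(normalize=True) * 100).round(1)
        print(f"  {guild}: {frac.to_dict()} % of carried pathways")

    uptake = {
        s: set(grp.metabolite)
        for s, grp in exchange[exchange.direction == "uptake"].groupby("strain")
    }
    for s in mro.index:
        uptake.setdefault(s, set())
    comp_pairs = list(
        pairs.loc[pairs.competitive, ["strain_a", "strain_b"]].itertuples(index=False, name=None)
    )
    ranking = metanet.shared_demand_ranking(uptake, comp_pairs, top_k=30)
    ranking.to_csv(ROOT / "results" / "shared_demand.tsv", sep="\t", index=False)
    print("top shared demands:", list(ranking.metabolite.head(5)))


if __name__ == "__main__":
    main()
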