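"""Metabolic competition/complementarity scoring between guild members.

Consumes precomputed pairwise indices from genome-scale metabolic
models: the metabolic resource overlap MRO (competition index) and the
metabolic interaction potential MIP (complementarity index), both in
[0, 1].  Derives the combined metabolic distance D = 1 - (MRO - MIP),
the composite competition intensity C = Z(MRO) - Z(MIP), an
upper-quartile competitive-pair classification, phylogeny-adjusted MIP
outliers, per-guild core/shell/cloud pathway classes, and a ranking of
metabolites most commonly demanded by competitive pairs.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "pair_table",
    "metabolic_distance",
    "competition_intensity",
    "classify_competitive",
    "phylo_outliers",
    "core_cloud_pathways",
    "shared_demand_ranking",
]


def pair_table(
    mro: pd.DataFrame,
    mip: pd.DataFrame,
    guild_labels: pd.Series | None = None,
    phylo_distance: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Long-format table of unordered strain pairs with MRO/MIP (and
    optionally pair class and phylogenetic distance)."""
    strains = list(mro.index)
    if list(mip.index) != strains or list(mip.columns) != strains:
        raise ValueError("MRO and MIP must share strain labels")
    rows = []
    for i in range(len(strains)):
        for j in range(i + 1, len(strains)):
            a, b = strains[i], strains[j]
            row = {
                "strain_a": a,
                "strain_b": b,
                "mro": float(mro.iloc[i, j]),
                "mip": float(mip.iloc[i, j]),
            }
            if guild_labels is not None:
                ga, gb = guild_labels[a], guild_labels[b]
                row["pair_class"] = (
                    f"within_{ga}" if ga == gb else "between"
                )
            if phylo_distance is not None:
                row["phylo_distance"] = float(phylo_distance.iloc[i, j])
            rows.append(row)
    return pd.DataFrame(rows)


def metabolic_distance(mro, mip):
    """Combined metabolic distance D = 1 - (MRO - MIP), in [0, 2]."""
    mro = np.asarray(mro, dtype=float)
    mip = np.asarray(mip, dtype=float)
    if ((mro < 0) | (mro > 1)).any() or ((mip < 0) | (mip > 1)).any():
        raise ValueError("indices must lie in [0, 1]")
    return 1.0 - (mro - mip)


def competition_intensity(mro_values, mip_values, ddof: int = 1):
    """Composite competition intensity C = Z(MRO) - Z(MIP).

    Z-scores are taken over the pair set under analysis (sample SD, as in
    R's ``scale()``); both indices must vary across the set.
    """
    mro = np.asarray(mro_values, dtype=float)
    mip = np.asarray(mip_values, dtype=float)
    if mro.size < 3:
        raise ValueError("need at least 3 pairs to standardise")
    s_mro, s_mip = mro.std(ddof=ddof), mip.std(ddof=ddof)
    if s_mro == 0 or s_mip == 0:
        raise ValueError("zero variance in MRO or MIP; Z-scores undefined")
    return (mro - mro.mean()) / s_mro - (mip - mip.mean()) / s_mip


def classify_competitive(c_values, pair_ids=None) -> np.ndarray:
    """Flag the upper quartile (top ceil(N/4) ranks by C) as competitive.

    Ties are broken by pair id (ascending) so exactly ceil(N/4) pairs are
    flagged regardless of ties.
    """
    c = np.asarray(c_values, dtype=float)
    n = c.size
    if n == 0:
        return np.zeros(0, dtype=bool)
    ids = np.asarray(pair_ids) if pair_ids is not None else np.arange(n)
    k = math.ceil(n / 4)
    order = np.lexsort((ids, -c))  # descending C, then id ascending
    flags = np.zeros(n, dtype=bool)
    flags[order[:k]] = True
    return flags


def phylo_outliers(
    mip_values, phylo_distances, z_cutoff: float = 2.698
) -> np.ndarray:
    """Pairs whose MIP is elevated relative to phylogenetic distance.

    OLS of MIP on distance; residuals standardised by their SD; flag
    standardised residual > z_cutoff.
    """
    if z_cutoff <= 0:
        raise ValueError("z_cutoff must be positive")
    mip = np.asarray(mip_values, dtype=float)
    dist = np.asarray(phylo_distances, dtype=float)
    if mip.size != dist.size:
        raise ValueError("MIP and distance vectors must align")
    if mip.size < 10:
        raise ValueError("need at least 10 pairs for a stable regression")
    fit = sm.OLS(mip, sm.add_constant(dist)).fit()
    resid = fit.resid
    sd = resid.std(ddof=0)
    if sd == 0:
        return np.zeros(mip.size, dtype=bool)
    return resid / sd > z_cutoff


def core_cloud_pathways(
    pathway_presence: pd.DataFrame,
    guild_labels: pd.Series,
    core_cut: float = 0.90,
    cloud_cut: float = 0.10,
) -> pd.DataFrame:
    """Per-guild pathway prevalence classes.

    Core: carried by >= core_cut of the guild's genomes; cloud: carried
    by exactly one genome or <= cloud_cut of them; shell otherwise.
    Pathways absent from a guild are omitted for that guild.
    """
    labels = guild_labels.reindex(pathway_presence.index)
    if labels.dropna().empty:
        raise ValueError("no genomes carry a guild label")
    rows = []
    for guild in sorted(labels.dropna().unique()):
        block = pathway_presence.loc[labels == guild]
        n = len(block)
        if n == 0:
            raise ValueError(f"guild {guild!r} has no genomes")
        carried = block.sum(axis=0)
        for pwy, count in carried.items():
            if count == 0:
                continue
            prev = count / n
            if prev >= core_cut:
                cls = "core"
            elif count == 1 or prev <= cloud_cut:
                cls = "cloud"
            else:
                cls = "shell"
            rows.append(
                {
                    "pathway": pwy,
                    "guild": guild,
                    "prevalence": float(prev),
                    "n_genomes": int(count),
                    "class": cls,
                }
            )
    return pd.DataFrame(rows)


def shared_demand_ranking(
    uptake_sets: dict[str, set[str]],
    competitive_pairs: list[tuple[str, str]],
    top_k: int = 30,
) -> pd.DataFrame:
    """Metabolites most commonly demanded by both members of competitive
    pairs; score = number of competitive pairs whose uptake sets both
    contain the metabolite.  Ties rank alphabetically."""
    scores: dict[str, int] = {}
    for a, b in competitive_pairs:
        for met in uptake_sets[a] & uptake_sets[b]:
            scores[met] = scores.get(met, 0) + 1
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
    return pd.DataFrame(ranked, columns=["metabolite", "n_competitive_pairs"])
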