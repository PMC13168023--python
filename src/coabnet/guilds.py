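"""Phenotype-associated features and antagonistic guild structure.

The association scan regresses log-transformed total-sum-scaled
abundance of each feature on a continuous phenotype (plus optional
covariates) and splits BH-significant features by coefficient sign — a
fixed-effects analogue of the MaAsLin2 LOG/TSS pipeline.  Significant
features are then organised into guilds from their signed co-abundance
graph: connected components of the positive-edge subgraph are contracted
to supernodes and the negative-edge supernode graph is two-coloured;
edges breaking the two-guild sign pattern are reported as frustrated
rather than fatal.  Utility tests (Wilcoxon rank-sum, KO Shannon
diversity, per-feature GLM enrichment, Fisher's exact proportions)
support the downstream guild comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
import statsmodels.api as sm
from scipy import stats

from .netinfer import bh_adjust

__all__ = [
    "AssociationResult",
    "GuildPartition",
    "associate_features",
    "detect_guilds",
    "guild_abundance",
    "compare_groups",
    "ko_shannon",
    "enrichment_scan",
    "proportion_test",
]


@dataclass(frozen=True)
class AssociationResult:
    feature: str
    coefficient: float
    stderr: float
    p: float
    q: float

    @property
    def direction(self) -> str:
        return "positive" if self.coefficient >= 0 else "negative"


@dataclass
class GuildPartition:
    guild1: set[str]
    guild2: set[str]
    frustrated_edges: list[tuple[str, str]] = field(default_factory=list)
    unassigned: set[str] = field(default_factory=set)

    def label_of(self, feature: str) -> str | None:
        if feature in self.guild1:
            return "guild1"
        if feature in self.guild2:
            return "guild2"
        return None


def _log_tss(abundances: pd.DataFrame) -> pd.DataFrame:
    """log2 of total-sum-scaled abundance with half-minimum replacement of
    zeros (per feature)."""
    rel = abundances.div(abundances.sum(axis=0), axis=1)
    out = rel.copy()
    for feat in out.index:
        row = out.loc[feat]
        nz = row[row > 0]
        if nz.empty:
            continue
        out.loc[feat] = row.replace(0.0, nz.min() / 2.0)
    return np.log2(out)


def associate_features(
    abundances: pd.DataFrame,
    phenotype: pd.Series,
    covariates: pd.DataFrame | None = None,
    q_cutoff: float = 0.2,
) -> pd.DataFrame:
    """Per-feature linear-model scan of log-TSS abundance on phenotype.

    Returns a DataFrame (feature, coefficient, stderr, p, q, direction,
    significant) sorted by q; constant features are skipped.
    """
    samples = abundances.columns
    if len(samples) < 20:
        raise ValueError("need at least 20 samples")
    y_all = _log_tss(abundances)
    x = pd.DataFrame({"phenotype": phenotype.reindex(samples)})
    if covariates is not None:
        x = pd.concat([x, covariates.reindex(samples)], axis=1)
    x = sm.add_constant(x)
    rows = []
    for feat in abundances.index:
        y = y_all.loc[feat]
        if np.ptp(y.to_numpy()) == 0:
            continue
        fit = sm.OLS(y.to_numpy(), x.to_numpy()).fit()
        idx = list(x.columns).index("phenotype")
        rows.append(
            {
                "feature": feat,
                "coefficient": fit.params[idx],
                "stderr": fit.bse[idx],
                "p": fit.pvalues[idx],
            }
        )
    res = pd.DataFrame(rows)
    if res.empty:
        raise ValueError("no non-constant features to test")
    res["q"] = bh_adjust(res["p"].to_numpy())
    res["direction"] = np.where(res["coefficient"] >= 0, "positive", "negative")
    res["significant"] = res["q"] < q_cutoff
    return res.sort_values("q").reset_index(drop=True)


def detect_guilds(
    network: nx.Graph,
    phenotype_direction: dict[str, str] | None = None,
) -> GuildPartition:
    """Two-guild bipartition of a signed co-abundance graph.

    Positive-edge connected components become supernodes; the negative
    edges between supernodes are two-coloured breadth-first.  Odd-cycle
    conflicts are reported as frustrated edges (the offending negative
    edge, or a positive edge joining the two colours).  Supernodes
    untouched by negative edges stay unassigned unless the graph has no
    negative edge at all, in which case everything is one guild.
    Guild 1 is the side holding more positively phenotype-associated
    members (when directions are supplied).
    """
    pos = nx.Graph()
    pos.add_nodes_from(network.nodes)
    neg_edges = []
    for a, b, d in network.edges(data=True):
        if d["r"] > 0:
            pos.add_edge(a, b)
        elif d["r"] < 0:
            neg_edges.append((a, b))
    comp_of: dict[str, int] = {}
    comps: list[set[str]] = []
    for comp in nx.connected_components(pos):
        for n in comp:
            comp_of[n] = len(comps)
        comps.append(set(comp))
    if not neg_edges:
        members = set(network.nodes)
        return GuildPartition(guild1=members, guild2=set(), unassigned=set())
    meta = nx.Graph()
    meta.add_nodes_from(range(len(comps)))
    frustrated: list[tuple[str, str]] = []
    for a, b in neg_edges:
        ca, cb = comp_of[a], comp_of[b]
        if ca == cb:
            # negative edge inside a positively-connected component
            frustrated.append((a, b) if a <= b else (b, a))
        else:
            meta.add_edge(ca, cb, example=(a, b))
    color: dict[int, int] = {}
    for start in sorted(meta.nodes):
        if start in color or meta.degree(start) == 0:
            continue
        color[start] = 0
        queue = [start]
        while queue:
            u = queue.pop(0)
            for v in meta.neighbors(u):
                if v not in color:
                    color[v] = 1 - color[u]
                    queue.append(v)
                elif color[v] == color[u]:
                    a, b = meta[u][v]["example"]
                    frustrated.append((a, b) if a <= b else (b, a))
    side = [set(), set()]
    unassigned: set[str] = set()
    for ci, members in enumerate(comps):
        if ci in color:
            side[color[ci]].update(members)
        else:
            unassigned.update(members)
    g1, g2 = side
    if phenotype_direction:
        pos_share = [
            sum(1 for n in s if phenotype_direction.get(n) == "positive") for s in side
        ]
        if pos_share[1] > pos_share[0]:
            g1, g2 = g2, g1
    # machine-check the sign invariant: any unlisted violation is a bug
    reported = set(frustrated)
    for a, b, d in network.edges(data=True):
        key = (a, b) if a <= b else (b, a)
        if key in reported or d["r"] == 0:
            continue
        same = (a in g1 and b in g1) or (a in g2 and b in g2)
        crossing = (a in g1 and b in g2) or (a in g2 and b in g1)
        assert not (same and d["r"] < 0), f"unreported frustrated edge {key}"
        assert not (crossing and d["r"] > 0), f"unreported frustrated edge {key}"
    return GuildPartition(
        guild1=g1, guild2=g2, frustrated_edges=sorted(set(frustrated)), unassigned=unassigned
    )


def guild_abundance(abundances: pd.DataFrame, partition: GuildPartition) -> pd.DataFrame:
    """Per-sample summed relative abundance of each guild."""
    rel = abundances.div(abundances.sum(axis=0), axis=1)
    missing = (partition.guild1 | partition.guild2) - set(abundances.index)
    if missing:
        raise ValueError(f"guild members absent from table: {sorted(missing)[:5]}")
    return pd.DataFrame(
        {
            "guild1": rel.loc[sorted(partition.guild1)].sum(axis=0)
            if partition.guild1
            else 0.0,
            "guild2": rel.loc[sorted(partition.guild2)].sum(axis=0)
            if partition.guild2
            else 0.0,
        }
    )


def compare_groups(values, group_labels) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U): exact when the
    combined sample is small (<= 25), tie-corrected normal approximation
    otherwise."""
    v = np.asarray(list(values), dtype=float)
    g = np.asarray(list(group_labels))
    levels = sorted(pd.unique(g))
    if len(levels) != 2:
        raise ValueError("need exactly two groups")
    a, b = v[g == levels[0]], v[g == levels[1]]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 observations")
    has_ties = len(np.unique(v)) < len(v)
    method = "exact" if (len(v) <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def ko_shannon(ko_counts: pd.DataFrame) -> pd.Series:
    """Shannon diversity H = -sum p ln p of KO counts per genome (rows)."""
    out = {}
    for genome, row in ko_counts.iterrows():
        c = row.to_numpy(dtype=float)
        c = c[c > 0]
        if c.size == 0:
            raise ValueError(f"genome {genome!r} has zero KOs")
        p = c / c.sum()
        out[genome] = float(-(p * np.log(p)).sum())
    return pd.Series(out, name="shannon")


def enrichment_scan(
    feature_matrix: pd.DataFrame,
    guild_labels: pd.Series,
    fdr_cut: float = 0.05,
) -> pd.DataFrame:
    """Per-feature two-group GLM of feature on guild membership.

    Binary features use a binomial GLM (Fisher's exact fallback under
    complete separation); count features use a Poisson GLM with Pearson
    dispersion scaling (quasi-Poisson-robust inference).  Returns
    feature, effect direction ('guild1'/'guild2'), p, q, significant.
    """
    labels = guild_labels.reindex(feature_matrix.index)
    ind = (labels == "guild1").astype(float).to_numpy()
    x = sm.add_constant(ind)
    rows = []
    for feat in feature_matrix.columns:
        y = feature_matrix[feat].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            continue
        binary = set(np.unique(y)) <= {0.0, 1.0}
        if binary:
            sep = (y[ind == 1].mean() in (0.0, 1.0)) or (y[ind == 0].mean() in (0.0, 1.0))
            if sep:
                a = int(y[ind == 1].sum())
                b = int((ind == 1).sum()) - a
                c = int(y[ind == 0].sum())
                d = int((ind == 0).sum()) - c
                p = stats.fisher_exact([[a, b], [c, d]])[1]
                coef = y[ind == 1].mean() - y[ind == 0].mean()
            else:
                fit = sm.GLM(y, x, family=sm.families.Binomial()).fit()
                coef, p = fit.params[1], fit.pvalues[1]
        else:
            fit = sm.GLM(y, x, family=sm.families.Poisson()).fit(scale="X2")
            coef, p = fit.params[1], fit.pvalues[1]
        rows.append(
            {
                "feature": feat,
                "enriched_in": "guild1" if coef > 0 else "guild2",
                "p": float(p),
            }
        )
    res = pd.DataFrame(rows)
    if res.empty:
        return pd.DataFrame(columns=["feature", "enriched_in", "p", "q", "significant"])
    res["q"] = bh_adjust(res["p"].to_numpy())
    res["significant"] = res["q"] < fdr_cut
    return res.sort_values("q").reset_index(drop=True)


def proportion_test(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test on the 2x2 table [[a, b], [c, d]]."""
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("cell counts must be nonnegative integers")
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(p)
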