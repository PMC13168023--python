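"""Cross-stage edge dynamics: conservation versus heterogeneity.

Edges shared between stage networks are compared with a fixed-effect
meta-analysis on the Fisher-z scale: z_k = atanh(r_k) with weight
w_k = n_k - 3, pooled z = sum(w z)/sum(w), Cochran's Q = sum w (z - zbar)^2
on K-1 degrees of freedom, and I^2 = max(0, (Q - df)/Q) * 100.  An edge is
*stable* when Q is non-significant (p_Q > alpha), *heterogeneous* when
I^2 exceeds a cutoff and the BH-adjusted p_Q clears an FDR threshold, and
*intermediate* otherwise.  Heterogeneous two-stage pairs are further
categorised as sign-reversed or as strengthened/weakened at the first
stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats

from .netinfer import bh_adjust

__all__ = [
    "MetaResult",
    "match_edges",
    "meta_heterogeneity",
    "classify_conservation",
    "classify_pairwise_change",
    "summarize_conservation",
    "module_jaccard",
]


@dataclass(frozen=True)
class MetaResult:
    pooled_z: float
    Q: float
    df: int
    p_Q: float
    I2: float  # percentage in [0, 100]


def _edge_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def match_edges(networks: list[nx.Graph], n_samples: dict[str, int] | None = None) -> pd.DataFrame:
    """Union of edges across stage networks with per-stage r/p/q/presence.

    ``n_samples`` maps stage label to sample count (needed downstream for
    the meta-analysis weights); defaults to the graph attribute
    ``n_samples`` when present.
    """
    if len(networks) < 2:
        raise ValueError("need at least 2 networks")
    stages = [g.graph.get("stage", str(i)) for i, g in enumerate(networks)]
    if len(stages) != len(set(stages)):
        raise ValueError("duplicate stage labels")
    rows: dict[tuple[str, str], dict] = {}
    for stage, g in zip(stages, networks):
        n = (n_samples or {}).get(stage, g.graph.get("n_samples", np.nan))
        for a, b, d in g.edges(data=True):
            key = _edge_key(a, b)
            row = rows.setdefault(key, {"taxon_a": key[0], "taxon_b": key[1]})
            row[f"r_{stage}"] = d.get("r", np.nan)
            row[f"p_{stage}"] = d.get("p", np.nan)
            row[f"q_{stage}"] = d.get("q", np.nan)
            row[f"n_{stage}"] = n
            row[f"present_{stage}"] = True
    if not rows:
        cols = ["taxon_a", "taxon_b"] + [
            f"{f}_{s}" for s in stages for f in ("r", "p", "q", "n", "present")
        ]
        table = pd.DataFrame(columns=cols)
        table.attrs["stages"] = stages
        return table
    table = pd.DataFrame(list(rows.values()))
    for stage in stages:
        col = f"present_{stage}"
        if col not in table:
            table[col] = False
        table[col] = table[col].map(lambda v: bool(v) if v is True else False)
    table.attrs["stages"] = stages
    return table.sort_values(["taxon_a", "taxon_b"]).reset_index(drop=True)


def meta_heterogeneity(r_list, n_list) -> MetaResult:
    """Fixed-effect Fisher-z meta-analysis of one edge across stages."""
    r = np.asarray(r_list, dtype=float)
    n = np.asarray(n_list, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("|r| must be < 1 (Fisher z undefined at |r| = 1)")
    if np.any(n <= 3):
        raise ValueError("each stage needs n > 3")
    z = np.arctanh(r)
    w = n - 3.0
    pooled = float(np.sum(w * z) / np.sum(w))
    q = float(np.sum(w * (z - pooled) ** 2))
    df = len(r) - 1
    p_q = float(stats.chi2.sf(q, df)) if df > 0 else 1.0
    i2 = float(max(0.0, (q - df) / q) * 100.0) if q > 0 else 0.0
    return MetaResult(pooled_z=pooled, Q=q, df=df, p_Q=p_q, I2=i2)


def classify_conservation(
    table: pd.DataFrame,
    stages: list[str] | None = None,
    alpha_stable: float = 0.05,
    i2_cut: float = 75.0,
    fdr_cut: float = 0.05,
) -> pd.DataFrame:
    """Classify every edge present in all compared stages.

    Returns the per-edge table (sorted pair, per-stage r/n, Q, df, p_Q,
    BH-adjusted q_Q over the compared set, I2, label).  Edges missing in
    any compared stage are excluded.
    """
    stages = stages or table.attrs.get("stages")
    if not stages:
        raise ValueError("stage labels required")
    mask = np.logical_and.reduce([table[f"present_{s}"].to_numpy() for s in stages])
    shared = table.loc[mask].copy()
    if shared.empty:
        shared["label"] = []
        return shared
    metas = [
        meta_heterogeneity(
            [row[f"r_{s}"] for s in stages], [row[f"n_{s}"] for s in stages]
        )
        for _, row in shared.iterrows()
    ]
    shared["Q"] = [m.Q for m in metas]
    shared["df"] = [m.df for m in metas]
    shared["p_Q"] = [m.p_Q for m in metas]
    shared["I2"] = [m.I2 for m in metas]
    shared["q_Q"] = bh_adjust(shared["p_Q"].to_numpy())
    def label(row):
        if row["p_Q"] > alpha_stable:
            return "stable"
        if row["I2"] > i2_cut and row["q_Q"] < fdr_cut:
            return "heterogeneous"
        return "intermediate"
    shared["label"] = shared.apply(label, axis=1)
    return shared.reset_index(drop=True)


def classify_pairwise_change(rA: float, rB: float, sigA: bool = True, sigB: bool = True):
    """Categorise a heterogeneous two-stage edge.

    Returns (category, significance annotation); category is ``reversed``
    when the signs differ, else ``increased_at_A`` / ``decreased_at_A`` by
    magnitude, or ``indeterminate`` when either r is exactly zero.
    """
    sA, sB = np.sign(rA), np.sign(rB)
    if sA == 0 or sB == 0:
        category = "indeterminate"
    elif sA != sB:
        category = "reversed"
    elif abs(rA) > abs(rB):
        category = "increased_at_A"
    else:
        category = "decreased_at_A"
    sig = {
        (True, True): "significant_both",
        (True, False): "significant_only_A",
        (False, True): "significant_only_B",
        (False, False): "significant_neither",
    }[(bool(sigA), bool(sigB))]
    return category, sig


def _pct(numer: int, denom: int) -> float:
    """Percentage rounded half-up to 2 decimals (matches printed tables)."""
    if denom == 0:
        return 0.0
    val = Decimal(numer) / Decimal(denom) * 100
    return float(val.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def summarize_conservation(
    labels: pd.Series | list,
    strata: pd.Series | list | None = None,
) -> pd.DataFrame:
    """Counts and half-up-rounded percentages per label, overall and per
    stratum."""
    labels = pd.Series(list(labels), name="label")
    if labels.empty:
        raise ValueError("labels must be nonempty")
    frames = []
    def block(sub: pd.Series, stratum: str):
        total = len(sub)
        counts = sub.value_counts()
        return pd.DataFrame(
            {
                "stratum": stratum,
                "label": counts.index,
                "count": counts.to_numpy(),
                "total": total,
                "percent": [_pct(int(c), total) for c in counts],
            }
        )
    frames.append(block(labels, "overall"))
    if strata is not None:
        strata = pd.Series(list(strata))
        for s in sorted(strata.unique()):
            frames.append(block(labels[strata == s], str(s)))
    return pd.concat(frames, ignore_index=True)


def module_jaccard(
    partitionA: list[set], partitionB: list[set]
) -> tuple[np.ndarray, float]:
    """Pairwise Jaccard similarity between module memberships.

    Returns the |A| x |B| matrix J(M1, M2) = |M1 & M2| / |M1 | M2| and the
    network-level similarity: the mean, over modules of A, of each
    module's best match in B (symmetrised with the B-side mean).
    """
    if any(len(m) == 0 for m in partitionA + partitionB):
        raise ValueError("empty module")
    sim = np.zeros((len(partitionA), len(partitionB)))
    for i, ma in enumerate(partitionA):
        for j, mb in enumerate(partitionB):
            sim[i, j] = len(ma & mb) / len(ma | mb)
    mean_sim = float((sim.max(axis=1).mean() + sim.max(axis=0).mean()) / 2.0)
    return sim, mean_sim
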