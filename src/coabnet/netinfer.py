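"""Compositionality-corrected co-abundance network inference.

Implements the SparCC estimator (the algorithm behind FastSpar):
log-ratio variances t_ij = Var[log(f_i/f_j)] are converted to basis
variances by solving ((p-2)I + 11^T) w = rowsums(t), correlations follow
as r_ij = (w_i + w_j - t_ij) / (2 sqrt(w_i w_j)), and strongly correlated
pairs are iteratively excluded from the linear system to protect the
sparsity assumption.  Significance comes from a permutation null that
shuffles each taxon independently across samples; edges are retained at a
Benjamini-Hochberg FDR cutoff.

Networks are plain :class:`networkx.Graph` objects with per-edge ``r``,
``p``, ``q`` attributes, a graph-level ``stage`` label, and per-node
``mean_abundance`` / ``beneficial`` attributes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx
from statsmodels.stats.multitest import multipletests

__all__ = [
    "prevalence_filter",
    "estimate_fractions",
    "sparcc",
    "permutation_pvalues",
    "bh_adjust",
    "build_network",
    "extract_beneficial_subnetwork",
    "infer_network",
]


def prevalence_filter(counts: pd.DataFrame, min_prevalence: float = 0.10) -> pd.DataFrame:
    """Keep taxa with nonzero counts in >= ceil(min_prevalence * n) samples."""
    if not 0 < min_prevalence <= 1:
        raise ValueError("min_prevalence must be in (0, 1]")
    n = counts.shape[1]
    need = int(np.ceil(min_prevalence * n))
    keep = (counts > 0).sum(axis=1) >= need
    if not keep.any():
        raise ValueError("prevalence filter removed every taxon")
    return counts.loc[keep]


def estimate_fractions(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Dirichlet-posterior-mean fractions, samples x taxa.

    With a uniform (+1) prior the posterior mean for sample s is
    (c_is + 1) / (depth_s + p).  Input is taxa x samples (table
    convention); output is samples x taxa for the estimator.
    """
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be nonnegative")
    c = c.T  # samples x taxa
    totals = c.sum(axis=1)
    if (totals == 0).any():
        bad = np.where(totals == 0)[0]
        names = (
            list(np.asarray(counts.columns)[bad])
            if isinstance(counts, pd.DataFrame)
            else bad.tolist()
        )
        raise ValueError(f"sample(s) with all-zero counts: {names}")
    p = c.shape[1]
    return (c + 1.0) / (totals + p)[:, None]


def _variation_matrix(fractions: np.ndarray) -> np.ndarray:
    """t_ij = Var[log(f_i / f_j)] across samples (unbiased)."""
    logf = np.log(fractions)
    v = logf.var(axis=0, ddof=1)
    cov = np.cov(logf, rowvar=False, ddof=1)
    t = v[:, None] + v[None, :] - 2.0 * cov
    np.fill_diagonal(t, 0.0)
    return np.maximum(t, 0.0)


def _solve_basis(t: np.ndarray, excluded: set[tuple[int, int]]) -> np.ndarray:
    """Solve the SparCC basis-variance system with excluded pairs removed."""
    p = t.shape[0]
    m = np.ones((p, p)) + (p - 2) * np.eye(p)
    t_eff = t.copy()
    for i, j in excluded:
        m[i, j] -= 1.0
        m[j, i] -= 1.0
        m[i, i] -= 1.0
        m[j, j] -= 1.0
        t_eff[i, j] = 0.0
        t_eff[j, i] = 0.0
    omega2 = np.linalg.solve(m, t_eff.sum(axis=1))
    return np.maximum(omega2, 1e-12)


def _correlation_from_basis(t: np.ndarray, omega2: np.ndarray) -> np.ndarray:
    om = np.sqrt(omega2)
    r = (omega2[:, None] + omega2[None, :] - t) / (2.0 * np.outer(om, om))
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def _sparcc_once(
    fractions: np.ndarray,
    exclusion_threshold: float,
    max_exclusions: int,
) -> tuple[np.ndarray, np.ndarray]:
    t = _variation_matrix(fractions)
    p = t.shape[0]
    if p < 4:
        raise ValueError("SparCC requires at least 4 taxa")
    excluded: set[tuple[int, int]] = set()
    excl_count = np.zeros(p, dtype=int)
    omega2 = _solve_basis(t, excluded)
    r = _correlation_from_basis(t, omega2)
    for _ in range(max_exclusions):
        cand = np.abs(r.copy())
        np.fill_diagonal(cand, 0.0)
        for i, j in excluded:
            cand[i, j] = cand[j, i] = 0.0
        i, j = np.unravel_index(int(np.argmax(cand)), cand.shape)
        if cand[i, j] <= exclusion_threshold:
            break
        # stop rather than degrade the system below 4 effectively-coupled taxa
        if min(p - excl_count[i], p - excl_count[j]) - 1 < 4:
            break
        excluded.add((min(i, j), max(i, j)))
        excl_count[i] += 1
        excl_count[j] += 1
        omega2 = _solve_basis(t, excluded)
        r = _correlation_from_basis(t, omega2)
    return r, omega2


def sparcc(
    counts_or_fractions,
    exclusion_threshold: float = 0.1,
    max_exclusions: int = 10,
    n_inner: int = 20,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """SparCC correlation matrix and basis variances.

    Accepts a taxa x samples count table (fractions are then estimated)
    or a precomputed samples x taxa fraction matrix (rows summing to 1).
    With ``n_inner > 1`` the estimate is the mean over ``n_inner``
    Dirichlet resamplings of the fractions; with ``n_inner = 1`` the
    posterior-mean fractions are used directly (deterministic).
    """
    x = np.asarray(
        counts_or_fractions.to_numpy()
        if isinstance(counts_or_fractions, pd.DataFrame)
        else counts_or_fractions,
        dtype=float,
    )
    if np.allclose(x.sum(axis=1), 1.0, atol=1e-6) and (x > 0).all():
        fractions, counts = x, None
    else:
        counts = x
        fractions = estimate_fractions(counts_or_fractions)
    if n_inner <= 1 or counts is None:
        return _sparcc_once(fractions, exclusion_threshold, max_exclusions)
    rng = np.random.default_rng(seed)
    r_sum = np.zeros((counts.shape[0], counts.shape[0]))
    w_sum = np.zeros(counts.shape[0])
    for _ in range(n_inner):
        fr = np.stack([rng.dirichlet(col + 1.0) for col in counts.T])
        r, w = _sparcc_once(fr, exclusion_threshold, max_exclusions)
        r_sum += r
        w_sum += w
    r = np.clip(r_sum / n_inner, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r, w_sum / n_inner


def permutation_pvalues(
    counts: pd.DataFrame | np.ndarray,
    observed_r: np.ndarray,
    n_permutations: int = 1000,
    seed: int = 0,
    exclusion_threshold: float = 0.1,
    max_exclusions: int = 10,
    null_scheme: str = "permute",
) -> np.ndarray:
    """Permutation pseudo p-values for every taxon pair.

    Each permutation shuffles every taxon's counts independently across
    samples (destroying correlations, preserving marginals), recomputes
    the SparCC matrix, and p = (1 + #{|r_perm| >= |r_obs|}) / (1 + B).
    ``null_scheme="bootstrap"`` resamples samples with replacement per
    taxon instead (FastSpar's bootstrap flavour).
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    if null_scheme not in ("permute", "bootstrap"):
        raise ValueError("null_scheme must be 'permute' or 'bootstrap'")
    c = np.asarray(
        counts.to_numpy() if isinstance(counts, pd.DataFrame) else counts, dtype=float
    )
    p, n = c.shape
    rng = np.random.default_rng(seed)
    abs_obs = np.abs(observed_r)
    exceed = np.zeros((p, p), dtype=int)
    for _ in range(n_permutations):
        if null_scheme == "permute":
            perm = np.stack([rng.permutation(row) for row in c])
        else:
            perm = np.stack([row[rng.integers(0, n, size=n)] for row in c])
        fr = estimate_fractions(perm)
        r_perm, _ = _sparcc_once(fr, exclusion_threshold, max_exclusions)
        exceed += np.abs(r_perm) >= abs_obs
    pvals = (1.0 + exceed) / (1.0 + n_permutations)
    np.fill_diagonal(pvals, 1.0)
    return np.minimum(pvals, 1.0)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up with monotonicity enforcement.

    1-D input: adjusted across the vector.  Square symmetric input:
    adjusted over the upper triangle only, mirrored back.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim == 2:
        if p.shape[0] != p.shape[1]:
            raise ValueError("2-D p-value input must be square")
        iu = np.triu_indices(p.shape[0], k=1)
        q_flat = multipletests(p[iu], method="fdr_bh")[1]
        q = np.ones_like(p)
        q[iu] = q_flat
        q[(iu[1], iu[0])] = q_flat
        return q
    if p.size == 0:
        return p.copy()
    return multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)


def build_network(
    r: np.ndarray,
    q: np.ndarray,
    q_cutoff: float = 0.05,
    p: np.ndarray | None = None,
    taxa: list[str] | None = None,
    stage: str = "",
    mean_abundance: np.ndarray | None = None,
    beneficial: np.ndarray | None = None,
) -> nx.Graph:
    """Edge-filtered correlation network: keep pairs with q < q_cutoff."""
    m = r.shape[0]
    taxa = taxa if taxa is not None else [f"taxon_{i:03d}" for i in range(m)]
    g = nx.Graph(stage=stage)
    for i, t in enumerate(taxa):
        g.add_node(
            t,
            mean_abundance=float(mean_abundance[i]) if mean_abundance is not None else 0.0,
            beneficial=bool(beneficial[i]) if beneficial is not None else False,
        )
    for i in range(m):
        for j in range(i + 1, m):
            if q[i, j] < q_cutoff:
                g.add_edge(
                    taxa[i],
                    taxa[j],
                    r=float(r[i, j]),
                    p=float(p[i, j]) if p is not None else float("nan"),
                    q=float(q[i, j]),
                )
    return g


def extract_beneficial_subnetwork(network: nx.Graph, beneficial_flags: dict | None = None) -> nx.Graph:
    """Induced subgraph on beneficial taxa plus their first neighbours."""
    if beneficial_flags is None:
        beneficial_flags = {n: bool(d.get("beneficial", False)) for n, d in network.nodes(data=True)}
    missing = [n for n in network.nodes if n not in beneficial_flags]
    if missing:
        raise ValueError(f"beneficial flags missing for nodes: {missing[:5]}")
    seeds = {n for n in network.nodes if beneficial_flags[n]}
    if not seeds:
        raise ValueError("no beneficial taxa flagged")
    keep = set(seeds)
    for n in seeds:
        keep.update(network.neighbors(n))
    sub = network.subgraph(keep).copy()
    sub.graph.update(network.graph)
    return sub


def infer_network(
    counts: pd.DataFrame,
    stage: str = "",
    min_prevalence: float = 0.10,
    q_cutoff: float = 0.05,
    n_permutations: int = 1000,
    n_inner: int = 20,
    exclusion_threshold: float = 0.1,
    max_exclusions: int = 10,
    seed: int = 0,
    beneficial: pd.Series | None = None,
    null_scheme: str = "permute",
) -> nx.Graph:
    """Full single-stage inference: prevalence filter -> SparCC ->
    permutation p-values -> BH -> FDR-filtered network."""
    filtered = prevalence_filter(counts, min_prevalence)
    r, _ = sparcc(
        filtered,
        exclusion_threshold=exclusion_threshold,
        max_exclusions=max_exclusions,
        n_inner=n_inner,
        seed=seed,
    )
    pvals = permutation_pvalues(
        filtered,
        r,
        n_permutations=n_permutations,
        seed=seed + 1,
        exclusion_threshold=exclusion_threshold,
        max_exclusions=max_exclusions,
        null_scheme=null_scheme,
    )
    q = bh_adjust(pvals)
    rel = filtered.to_numpy(dtype=float)
    rel = rel / rel.sum(axis=0, keepdims=True)
    flags = (
        beneficial.reindex(filtered.index).fillna(False).to_numpy(dtype=bool)
        if beneficial is not None
        else None
    )
    return build_network(
        r,
        q,
        q_cutoff=q_cutoff,
        p=pvals,
        taxa=list(filtered.index),
        stage=stage,
        mean_abundance=rel.mean(axis=1),
        beneficial=flags,
    )
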