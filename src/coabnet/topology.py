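"""Topology of strength-filtered co-abundance networks.

Global metrics (nodes, edges, signed edge counts, average degree, average
clustering, Freeman degree centralization, modularity of a greedy
partition), Guimera-Amaral Zi/Pi node roles, power-law degree-
distribution fits with a bootstrap plausibility verdict, and two-sample
degree-distribution comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import networkx as nx
from networkx.algorithms import community as nx_comm
from scipy import stats

__all__ = [
    "TopologyReport",
    "NodeRole",
    "PowerLawFit",
    "filter_by_strength",
    "topology_metrics",
    "detect_modules",
    "zi_pi",
    "powerlaw_alpha",
    "fit_degree_distribution",
    "compare_degree_distributions",
]


@dataclass(frozen=True)
class TopologyReport:
    n_nodes: int
    n_edges: int
    n_positive_edges: int
    n_negative_edges: int
    average_degree: float
    clustering_coefficient: float
    modularity: float
    centralization: float
    hub_node_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class NodeRole:
    Zi: float
    Pi: float
    role: str  # peripheral | connector | module_hub | network_hub

    @property
    def is_hub(self) -> bool:
        return self.role != "peripheral"


@dataclass(frozen=True)
class PowerLawFit:
    alpha: float
    xmin: float
    ks: float
    plausible: bool
    bootstrap_p: float


def filter_by_strength(network: nx.Graph, r_cut: float = 0.2, signed: bool = False) -> nx.Graph:
    """Keep edges with |r| > r_cut (or r > r_cut in signed mode); drop
    nodes left isolated."""
    if not 0 <= r_cut < 1:
        raise ValueError("r_cut must lie in [0, 1)")
    g = network.copy()
    drop = [
        (a, b)
        for a, b, d in g.edges(data=True)
        if (d["r"] <= r_cut if signed else abs(d["r"]) <= r_cut)
    ]
    g.remove_edges_from(drop)
    g.remove_nodes_from([n for n in list(g.nodes) if g.degree(n) == 0])
    return g


def detect_modules(network: nx.Graph, seed: int = 0) -> tuple[list[set], float]:
    """Greedy modularity maximisation on the |r|-weighted graph.

    Deterministic: communities are found per connected component with
    CNM greedy agglomeration; the seed only matters for tie-breaking in
    degenerate graphs and is accepted for interface stability.
    """
    if network.number_of_edges() == 0:
        parts = [{n} for n in sorted(network.nodes)]
        return parts, 0.0
    w = nx.Graph()
    w.add_nodes_from(network.nodes)
    for a, b, d in network.edges(data=True):
        w.add_edge(a, b, weight=abs(d.get("r", 1.0)))
    comms = [set(c) for c in nx_comm.greedy_modularity_communities(w, weight="weight")]
    mod = nx_comm.modularity(w, comms, weight="weight")
    return comms, float(mod)


def topology_metrics(
    network: nx.Graph,
    partition: list[set] | None = None,
    seed: int = 0,
    hub_ids: tuple[str, ...] = (),
) -> TopologyReport:
    """Global topology report; modularity from the supplied partition or a
    fresh greedy one."""
    n = network.number_of_nodes()
    if n < 3:
        raise ValueError("need at least 3 nodes")
    e = network.number_of_edges()
    signs = [d.get("r", 1.0) for _, _, d in network.edges(data=True)]
    pos = sum(1 for r in signs if r > 0)
    neg = sum(1 for r in signs if r < 0)
    degrees = np.array([d for _, d in network.degree()], dtype=float)
    kmax = degrees.max() if n else 0.0
    denom = (n - 1) * (n - 2)
    centralization = float((kmax - degrees).sum() / denom) if denom > 0 else 0.0
    if partition is None:
        partition, modularity = detect_modules(network, seed=seed)
    else:
        modularity = (
            nx_comm.modularity(network, partition) if e > 0 else 0.0
        )
    return TopologyReport(
        n_nodes=n,
        n_edges=e,
        n_positive_edges=pos,
        n_negative_edges=neg,
        average_degree=2.0 * e / n,
        clustering_coefficient=float(nx.average_clustering(network)),
        modularity=float(modularity),
        centralization=centralization,
        hub_node_ids=tuple(hub_ids),
    )


def zi_pi(
    network: nx.Graph,
    partition: list[set],
    zi_cut: float = 2.5,
    pi_cut: float = 0.62,
) -> dict[str, NodeRole]:
    """Within-module degree z-score and participation coefficient per node.

    Zi = (k_i,own - mean_own) / sd_own over the node's module (0 when the
    module's within-degrees have zero variance); Pi = 1 - sum_s
    (k_is / k_i)^2.  Roles follow the Guimera-Amaral quadrants; every
    non-peripheral role counts as a hub.
    """
    module_of: dict[str, int] = {}
    for m, members in enumerate(partition):
        for node in members:
            module_of[node] = m
    missing = [n for n in network.nodes if n not in module_of]
    if missing:
        raise ValueError(f"nodes absent from partition: {missing[:5]}")
    within = {
        n: sum(1 for nb in network.neighbors(n) if module_of[nb] == module_of[n])
        for n in network.nodes
    }
    stats_by_mod: dict[int, tuple[float, float]] = {}
    for m, members in enumerate(partition):
        ks = np.array([within[n] for n in members if n in network], dtype=float)
        if ks.size:
            stats_by_mod[m] = (float(ks.mean()), float(ks.std(ddof=0)))
    roles: dict[str, NodeRole] = {}
    for n in network.nodes:
        k = network.degree(n)
        if k == 0:
            roles[n] = NodeRole(0.0, 0.0, "peripheral")
            continue
        mean, sd = stats_by_mod[module_of[n]]
        zi = (within[n] - mean) / sd if sd > 0 else 0.0
        per_mod: dict[int, int] = {}
        for nb in network.neighbors(n):
            per_mod[module_of[nb]] = per_mod.get(module_of[nb], 0) + 1
        pi = 1.0 - sum((c / k) ** 2 for c in per_mod.values())
        if zi > zi_cut and pi > pi_cut:
            role = "network_hub"
        elif zi > zi_cut:
            role = "module_hub"
        elif pi > pi_cut:
            role = "connector"
        else:
            role = "peripheral"
        roles[n] = NodeRole(float(zi), float(pi), role)
    return roles


def powerlaw_alpha(degrees, xmin: float = 1.0) -> float:
    """Continuous MLE exponent at a fixed xmin: 1 + n / sum ln(x/xmin)."""
    x = np.asarray([d for d in degrees if d >= xmin], dtype=float)
    s = np.log(x / xmin).sum()
    if s <= 0:
        raise ValueError("degenerate tail (all values at xmin)")
    return float(1.0 + x.size / s)


def fit_degree_distribution(
    degrees,
    n_bootstrap: int = 100,
    seed: int = 0,
    plausibility_alpha: float = 0.1,
) -> PowerLawFit:
    """Continuous-approximation power-law MLE with KS-minimised xmin.

    alpha = 1 + n / sum(ln(x_i / xmin)) over x_i >= xmin; xmin scans the
    distinct degree values and minimises the KS distance to the fitted
    tail.  The plausibility verdict is a parametric bootstrap
    (``n_bootstrap`` resamples from the fitted law): plausible when the
    observed KS is not extreme (bootstrap p >= ``plausibility_alpha``).
    """
    x = np.asarray([d for d in degrees if d >= 1], dtype=float)
    if x.size < 20:
        raise ValueError("need >= 20 nodes with degree >= 1")
    if np.unique(x).size == 1:
        raise ValueError("degenerate degree sequence (all degrees equal)")

    def fit_tail(data: np.ndarray, xmin: float) -> tuple[float, float]:
        tail = data[data >= xmin]
        logs = np.log(tail / xmin)
        s = logs.sum()
        if s <= 0:
            return np.inf, np.inf
        alpha = 1.0 + tail.size / s
        xs = np.sort(tail)
        emp = np.arange(1, xs.size + 1) / xs.size
        model = 1.0 - (xs / xmin) ** (1.0 - alpha)
        ks = float(np.max(np.abs(emp - model)))
        return alpha, ks

    candidates = np.unique(x)[:-1] if np.unique(x).size > 1 else np.unique(x)
    best = None
    for xm in candidates:
        if (x >= xm).sum() < 10:
            continue
        alpha, ks = fit_tail(x, xm)
        if np.isfinite(ks) and (best is None or ks < best[2]):
            best = (alpha, float(xm), ks)
    if best is None:
        alpha, ks = fit_tail(x, candidates[0])
        best = (alpha, float(candidates[0]), ks)
    alpha, xmin, ks_obs = best

    rng = np.random.default_rng(seed)
    ntail = int((x >= xmin).sum())
    worse = 0
    for _ in range(n_bootstrap):
        u = rng.random(ntail)
        synth = xmin * (1.0 - u) ** (-1.0 / (alpha - 1.0))
        _, ks_b = fit_tail(synth, xmin)
        if ks_b >= ks_obs:
            worse += 1
    boot_p = (1.0 + worse) / (1.0 + n_bootstrap)
    return PowerLawFit(
        alpha=float(alpha),
        xmin=float(xmin),
        ks=ks_obs,
        plausible=boot_p >= plausibility_alpha,
        bootstrap_p=float(boot_p),
    )


def compare_degree_distributions(degreesA, degreesB):
    """Two-sample Kolmogorov-Smirnov test on degree sequences."""
    a = np.asarray(list(degreesA), dtype=float)
    b = np.asarray(list(degreesB), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("degree sequences must be nonempty")
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)
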