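"""Network stability, vulnerability, and robustness to node removal.

Node influence is the abundance-weighted mean interaction strength
(wMIS): the abundance-weighted mean of signed edge correlations over a
node's neighbours.  Stability combines the core-node fraction (taxa
present in every stage network) with the share of total |wMIS| those
core nodes carry.  Vulnerability is the relative loss of unweighted
global efficiency when a node is deleted; the network's vulnerability is
the worst case over nodes.  Robustness contrasts targeted removal (TR)
of hub nodes against random attack (RA) on non-hubs, tracking the
retained fraction of total |wMIS| over replicates and comparing the two
ratio distributions with a two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import networkx as nx
from scipy import stats

__all__ = [
    "ResilienceReport",
    "wmis",
    "core_nodes",
    "stability_index",
    "global_efficiency",
    "vulnerability",
    "robustness_simulation",
]


@dataclass
class ResilienceReport:
    wmis: dict[str, float]
    core: set[str]
    stability: float
    efficiency: float
    node_vulnerability: dict[str, float]
    network_vulnerability: float
    tr_ratios: list[float]
    ra_ratios: list[float]
    tr_vs_ra_p: float


def wmis(network: nx.Graph, mean_abundances: dict[str, float]) -> dict[str, float]:
    """wMIS_i = sum_j a_j r_ij / sum_j a_j over neighbours j; 0 for
    isolated nodes or all-zero neighbour abundance (warned)."""
    out: dict[str, float] = {}
    for node in network.nodes:
        nbrs = list(network.neighbors(node))
        if not nbrs:
            out[node] = 0.0
            continue
        a = np.array([mean_abundances[j] for j in nbrs], dtype=float)
        if (a < 0).any():
            raise ValueError("abundances must be nonnegative")
        r = np.array([network[node][j]["r"] for j in nbrs], dtype=float)
        denom = a.sum()
        if denom == 0:
            warnings.warn(f"node {node!r}: neighbour abundances all zero; wMIS set to 0")
            out[node] = 0.0
        else:
            out[node] = float((a * r).sum() / denom)
    return out


def core_nodes(networks: list[nx.Graph]) -> set[str]:
    """Nodes present in every stage network."""
    if len(networks) < 2:
        raise ValueError("need at least 2 networks")
    core = set(networks[0].nodes)
    for g in networks[1:]:
        core &= set(g.nodes)
    return core


def stability_index(network: nx.Graph, abundances: dict[str, float], core: set[str]) -> float:
    """S = (|core|/|nodes|) * (sum_core |wMIS| / sum_all |wMIS|)."""
    nodes = set(network.nodes)
    if not core <= nodes:
        raise ValueError("core must be a subset of the network's nodes")
    if not nodes:
        return 0.0
    w = wmis(network, abundances)
    total = sum(abs(v) for v in w.values())
    if total == 0:
        return 0.0
    core_share = sum(abs(w[n]) for n in core) / total
    return float(len(core) / len(nodes) * core_share)


def global_efficiency(network: nx.Graph) -> float:
    """Mean inverse shortest-path length over ordered node pairs
    (unweighted; disconnected pairs contribute 0)."""
    if network.number_of_nodes() < 2:
        raise ValueError("need at least 2 nodes")
    return float(nx.global_efficiency(network))


def vulnerability(network: nx.Graph) -> tuple[dict[str, float], float]:
    """Per-node V_i = (E - E_{-i}) / E and the network maximum."""
    if network.number_of_nodes() < 3:
        raise ValueError("need at least 3 nodes")
    e0 = global_efficiency(network)
    if e0 == 0:
        raise ValueError("efficiency is zero; vulnerability undefined")
    out: dict[str, float] = {}
    for node in network.nodes:
        g = network.copy()
        g.remove_node(node)
        e = global_efficiency(g) if g.number_of_nodes() >= 2 else 0.0
        out[node] = float((e0 - e) / e0)
    return out, float(max(out.values()))


def robustness_simulation(
    network: nx.Graph,
    abundances: dict[str, float],
    hub_ids,
    n_reps: int = 10,
    seed: int = 0,
) -> tuple[list[float], list[float], float]:
    """TR/RA wMIS-retention ratios and their rank-sum comparison.

    Per replicate, TR removes floor(|hubs|/2) (minimum 1) hubs uniformly
    at random; RA removes the same number of non-hubs; the ratio is the
    total |wMIS| of the reduced network (recomputed) over the original
    total.
    """
    hubs = sorted(set(hub_ids) & set(network.nodes))
    if len(hubs) < 2:
        raise ValueError("need at least 2 hubs")
    non_hubs = sorted(set(network.nodes) - set(hubs))
    n_remove = max(1, len(hubs) // 2)
    if len(non_hubs) < n_remove:
        raise ValueError("not enough non-hub nodes to match the removal count")
    if n_remove >= network.number_of_nodes():
        raise ValueError("removal would empty the network")
    base = sum(abs(v) for v in wmis(network, abundances).values())
    if base == 0:
        raise ValueError("total |wMIS| is zero; ratios undefined")
    rng = np.random.default_rng(seed)
    tr, ra = [], []
    for _ in range(n_reps):
        for pool, sink in ((hubs, tr), (non_hubs, ra)):
            drop = rng.choice(pool, size=n_remove, replace=False)
            g = network.copy()
            g.remove_nodes_from(drop)
            total = sum(abs(v) for v in wmis(g, abundances).values())
            sink.append(float(total / base))
    if np.allclose(tr, ra):
        p = 1.0
    else:
        p = float(stats.mannwhitneyu(tr, ra, alternative="two-sided").pvalue)
    return tr, ra, p
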