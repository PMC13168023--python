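"""End-to-end pipeline: synthetic data (optional) -> per-stage SparCC
networks -> beneficial subnetworks -> cross-stage edge dynamics ->
topology -> resilience -> guild detection -> metabolic scoring.

Every stage writes deterministic, id-sorted tabular artifacts plus a
manifest recording the configuration, seed, package versions, and which
stages completed.  ``run_pipeline(config)`` is the single entry point;
the CLI and the analysis scripts are thin wrappers over it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx

from . import edgedyn, guilds, io, metanet, netinfer, resilience, synthdata, topology
from .config import PipelineConfig

__all__ = ["default_scenario", "run_pipeline"]


def default_scenario(config: PipelineConfig):
    """The default synthetic study: 150 taxa, 3 stages, two antagonistic
    10-member guilds driving the phenotype, 12 conserved strong pairs,
    8 sign-flipping variable pairs, conserved 30-taxon co-abundance
    modules (within-module rho 0.4) filling the remaining taxa, and 15
    beneficial taxa.  The modules make the planted network realistically
    dense — empirical co-abundance networks carry thousands of
    correlated pairs, and a sparse truth would leave the
    Benjamini-Hochberg step-up with too few genuine discoveries to clear
    the permutation p-value floor.

    Returns (counts per stage, phenotype, truth, guild_spec, network
    spec, metabolic fixtures).
    """
    p = config.n_taxa
    stages = tuple(config.stages)
    guild_spec = synthdata.PlantedGuildSpec(
        guild1_members=tuple(range(0, 10)),
        guild2_members=tuple(range(10, 20)),
        within_rho=0.6,
        between_rho=-0.5,
        effect_size=5.0,
        noise_sd=1.0,
    )
    flags = [i < 30 and i % 2 == 0 for i in range(p)]  # 15 beneficial taxa
    conserved = []
    base = synthdata.guild_correlation_spec(
        guild_spec, p, stages, beneficial_flags=flags
    )
    conserved.extend(base.conserved_edges)
    # strong conserved edges on disjoint pairs outside the guilds; the
    # planted-edge budget shrinks gracefully on small test tables
    i = 20
    n_cons = 0
    while n_cons < 12 and i + 1 < p:
        conserved.append(((i, i + 1), 0.7))
        i += 2
        n_cons += 1
    # sign-flipping variable edges, disjoint from everything above
    variable = []
    flips = tuple(0.7 if s % 2 == 0 else -0.7 for s in range(len(stages)))
    n_var = 0
    while n_var < 8 and i + 1 < p:
        variable.append(((i, i + 1), flips))
        i += 2
        n_var += 1
    # conserved community modules over the remaining taxa
    while p - i >= 10:
        size = min(30, p - i)
        members = list(range(i, i + size))
        for a in range(size):
            for b in range(a + 1, size):
                conserved.append(((members[a], members[b]), 0.4))
        i += size
    spec = synthdata.PlantedNetworkSpec(
        n_taxa=p,
        stages=stages,
        conserved_edges=tuple(conserved),
        variable_edges=tuple(variable),
        beneficial_flags=tuple(flags),
    )
    mats, truth = synthdata.generate_stage_correlations(spec, seed=config.seed)
    counts = synthdata.generate_counts(
        mats, n_samples=config.n_samples, depth=config.depth, seed=config.seed
    )
    growth_stage = config.stages[min(1, len(config.stages) - 1)]
    phenotype = synthdata.generate_phenotype(counts[growth_stage], guild_spec, seed=config.seed)
    truth.guild1 = list(guild_spec.guild1_members)
    truth.guild2 = list(guild_spec.guild2_members)
    truth.effect_size = guild_spec.effect_size
    truth.noise_sd = guild_spec.noise_sd
    fixtures = synthdata.generate_metabolic_fixtures(guild_spec, seed=config.seed)
    return counts, phenotype, truth, guild_spec, spec, fixtures


def _report_to_dict(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _report_to_dict(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (set, tuple)):
        return sorted(obj) if isinstance(obj, set) else list(obj)
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _report_to_dict(v) for k, v in obj.items()}
    return obj


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Execute every stage and write artifacts + manifest under outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    completed: list[str] = []
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "networkx": nx.__version__,
        },
        "stages_completed": completed,
    }

    def _fail(stage: str, exc: Exception):
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # ---- stage 1: data -------------------------------------------------
    try:
        if config.simulate:
            counts, phenotype, truth, guild_spec, _, fixtures = default_scenario(config)
            beneficial = pd.Series(
                {t: bool(f) for t, f in zip(next(iter(counts.values())).index,
                                            _spec_flags(config))}
            )
            synthdata.write_fixture_tables(
                outdir / "data", counts, phenotype, truth,
                beneficial_flags=beneficial.to_numpy(),
            )
        else:
            counts = {
                stage: io.read_abundance(path)
                for stage, path in config.abundance_paths.items()
            }
            meta = io.read_metadata(config.metadata_path) if config.metadata_path else None
            phenotype = meta["phenotype"] if meta is not None and "phenotype" in meta else None
            tax = io.read_taxonomy(config.taxonomy_path) if config.taxonomy_path else None
            beneficial = tax["beneficial"] if tax is not None else pd.Series(dtype=bool)
            truth = fixtures = guild_spec = None
        completed.append("data")
    except Exception as exc:  # noqa: BLE001 - stage name must reach the user
        _fail("data", exc)

    # ---- stage 2: per-stage networks ----------------------------------
    networks: dict[str, nx.Graph] = {}
    n_samples: dict[str, int] = {}
    try:
        for k, stage in enumerate(config.stages):
            table = counts[stage]
            net = netinfer.infer_network(
                table,
                stage=stage,
                min_prevalence=config.min_prevalence,
                q_cutoff=config.network_fdr,
                n_permutations=config.n_permutations,
                n_inner=config.n_inner,
                seed=config.seed + 10 * (k + 1),
                beneficial=beneficial if len(beneficial) else None,
            )
            net.graph["n_samples"] = table.shape[1]
            networks[stage] = net
            n_samples[stage] = table.shape[1]
            io.write_edge_list(net, outdir / f"network_{stage}.tsv")
            io.write_graphml(net, outdir / f"network_{stage}.graphml")
        completed.append("networks")
    except Exception as exc:
        _fail("networks", exc)

    # ---- stage 3: beneficial subnetworks ------------------------------
    try:
        subnets = {}
        if len(beneficial) and beneficial.any():
            for stage, net in networks.items():
                sub = netinfer.extract_beneficial_subnetwork(net)
                subnets[stage] = sub
                io.write_edge_list(sub, outdir / f"subnetwork_{stage}.tsv")
        completed.append("subnetworks")
    except Exception as exc:
        _fail("subnetworks", exc)

    # ---- stage 4: cross-stage edge dynamics ---------------------------
    try:
        table = edgedyn.match_edges(list(networks.values()), n_samples=n_samples)
        classified = edgedyn.classify_conservation(
            table,
            stages=list(config.stages),
            alpha_stable=config.alpha_stable,
            i2_cut=config.i2_cut,
            fdr_cut=config.heterogeneity_fdr,
        )
        if not classified.empty:
            s0, s1 = config.stages[0], config.stages[1]
            cats = [
                edgedyn.classify_pairwise_change(
                    row[f"r_{s0}"], row[f"r_{s1}"],
                    row.get(f"q_{s0}", 1.0) < config.network_fdr,
                    row.get(f"q_{s1}", 1.0) < config.network_fdr,
                )[0]
                if row["label"] == "heterogeneous"
                else ""
                for _, row in classified.iterrows()
            ]
            classified["pairwise_category"] = cats
            summary = edgedyn.summarize_conservation(classified["label"])
            summary.to_csv(outdir / "conservation_summary.tsv", sep="\t", index=False)
        classified.to_csv(outdir / "edge_dynamics.tsv", sep="\t", index=False)
        completed.append("edge_dynamics")
    except Exception as exc:
        _fail("edge_dynamics", exc)

    # ---- stage 5: topology --------------------------------------------
    partitions: dict[str, list[set]] = {}
    roles_by_stage: dict[str, dict] = {}
    filtered: dict[str, nx.Graph] = {}
    try:
        reports = {}
        for stage, net in networks.items():
            strong = topology.filter_by_strength(net, config.strength_cut)
            filtered[stage] = strong
            if strong.number_of_nodes() < 3:
                continue
            parts, _ = topology.detect_modules(strong, seed=config.seed)
            partitions[stage] = parts
            roles = topology.zi_pi(strong, parts, zi_cut=config.zi_cut, pi_cut=config.pi_cut)
            roles_by_stage[stage] = roles
            hubs = tuple(sorted(n for n, r in roles.items() if r.is_hub))
            rep = topology.topology_metrics(strong, partition=parts, hub_ids=hubs)
            reports[stage] = _report_to_dict(rep)
            pd.DataFrame(
                [
                    {
                        "node": n,
                        "degree": strong.degree(n),
                        "module": next(i for i, m in enumerate(parts) if n in m),
                        "Zi": roles[n].Zi,
                        "Pi": roles[n].Pi,
                        "role": roles[n].role,
                    }
                    for n in sorted(strong.nodes)
                ]
            ).to_csv(outdir / f"node_roles_{stage}.tsv", sep="\t", index=False)
        stage_list = [s for s in config.stages if s in partitions]
        jaccard = {}
        for a, b in zip(stage_list, stage_list[1:]):
            _, mean_sim = edgedyn.module_jaccard(partitions[a], partitions[b])
            jaccard[f"{a}|{b}"] = mean_sim
        (outdir / "topology_report.json").write_text(
            json.dumps({"stages": reports, "module_jaccard": jaccard}, indent=2, sort_keys=True)
        )
        completed.append("topology")
    except Exception as exc:
        _fail("topology", exc)

    # ---- stage 6: resilience ------------------------------------------
    try:
        core = resilience.core_nodes(list(filtered.values())) if len(filtered) >= 2 else set()
        res_reports = {}
        rob_rows = []
        for stage, strong in filtered.items():
            if strong.number_of_nodes() < 3:
                continue
            ab = {n: d.get("mean_abundance", 1.0) for n, d in strong.nodes(data=True)}
            w = resilience.wmis(strong, ab)
            stability = resilience.stability_index(strong, ab, core & set(strong.nodes))
            eff = resilience.global_efficiency(strong)
            vuln, net_vuln = resilience.vulnerability(strong)
            roles = roles_by_stage.get(stage, {})
            hubs = sorted(n for n, r in roles.items() if r.is_hub)
            if len(hubs) < 2:  # degenerate role table: fall back to top-degree nodes
                degs = sorted(strong.degree, key=lambda kv: (-kv[1], kv[0]))
                hubs = [n for n, _ in degs[: max(2, strong.number_of_nodes() // 10)]]
            tr, ra, pval = resilience.robustness_simulation(
                strong, ab, hubs, n_reps=config.robustness_reps, seed=config.seed + 7
            )
            for rep_i, (t, r_) in enumerate(zip(tr, ra)):
                rob_rows.append({"stage": stage, "replicate": rep_i, "mode": "TR", "ratio": t})
                rob_rows.append({"stage": stage, "replicate": rep_i, "mode": "RA", "ratio": r_})
            res_reports[stage] = {
                "stability": stability,
                "efficiency": eff,
                "network_vulnerability": net_vuln,
                "n_core": len(core & set(strong.nodes)),
                "tr_median": float(np.median(tr)),
                "ra_median": float(np.median(ra)),
                "tr_vs_ra_p": pval,
            }
        pd.DataFrame(rob_rows).to_csv(outdir / "robustness_replicates.tsv", sep="\t", index=False)
        (outdir / "resilience_report.json").write_text(
            json.dumps(res_reports, indent=2, sort_keys=True)
        )
        completed.append("resilience")
    except Exception as exc:
        _fail("resilience", exc)

    # ---- stage 7: guilds ----------------------------------------------
    partition = None
    try:
        if phenotype is not None:
            growth_stage = config.stages[min(1, len(config.stages) - 1)]
            gtable = counts[growth_stage]
            assoc = guilds.associate_features(
                gtable, phenotype, q_cutoff=config.association_fdr
            )
            assoc.to_csv(outdir / "associations.tsv", sep="\t", index=False)
            sig = set(assoc.loc[assoc["significant"], "feature"])
            direction = dict(zip(assoc["feature"], assoc["direction"]))
            # signed co-abundance graph among significant features; the
            # stage network already restricts edges to FDR < 0.05
            net = networks[growth_stage]
            sig_graph = nx.Graph()
            sig_graph.add_nodes_from(sorted(sig))
            for a, b, d in net.edges(data=True):
                if a in sig and b in sig:
                    sig_graph.add_edge(a, b, **d)
            partition = guilds.detect_guilds(sig_graph, phenotype_direction=direction)
            pd.DataFrame(
                sorted(
                    [(m, "guild1") for m in partition.guild1]
                    + [(m, "guild2") for m in partition.guild2]
                    + [(m, "unassigned") for m in partition.unassigned]
                ),
                columns=["feature", "guild"],
            ).to_csv(outdir / "guild_membership.tsv", sep="\t", index=False)
            if partition.guild1 and partition.guild2:
                gab = guilds.guild_abundance(gtable, partition)
                gab.to_csv(outdir / "guild_abundance.tsv", sep="\t")
        completed.append("guilds")
    except Exception as exc:
        _fail("guilds", exc)

    # ---- stage 8: metabolic scoring -----------------------------------
    try:
        if config.simulate and fixtures is not None:
            pairs = metanet.pair_table(
                fixtures.mro, fixtures.mip, fixtures.guild_labels, fixtures.phylo_distance
            )
            pairs["distance"] = metanet.metabolic_distance(pairs["mro"], pairs["mip"])
            between = pairs["pair_class"] == "between"
            pairs["competition_intensity"] = np.nan
            pairs.loc[between, "competition_intensity"] = metanet.competition_intensity(
                pairs.loc[between, "mro"], pairs.loc[between, "mip"]
            )
            pairs["competitive"] = False
            pairs.loc[between, "competitive"] = metanet.classify_competitive(
                pairs.loc[between, "competition_intensity"].to_numpy(),
                pair_ids=(
                    pairs.loc[between, "strain_a"] + "|" + pairs.loc[between, "strain_b"]
                ).to_numpy(),
            )
            pairs["phylo_outlier"] = metanet.phylo_outliers(
                pairs["mip"], pairs["phylo_distance"], z_cutoff=config.outlier_z
            )
            pairs.sort_values(["strain_a", "strain_b"]).to_csv(
                outdir / "metabolic_pairs.tsv", sep="\t", index=False
            )
            metanet.core_cloud_pathways(
                fixtures.pathway_presence,
                fixtures.guild_labels,
                core_cut=config.core_prevalence,
                cloud_cut=config.cloud_prevalence,
            ).to_csv(outdir / "pathway_classes.tsv", sep="\t", index=False)
            comp_pairs = list(
                pairs.loc[pairs["competitive"], ["strain_a", "strain_b"]].itertuples(
                    index=False, name=None
                )
            )
            metanet.shared_demand_ranking(fixtures.uptake_sets, comp_pairs).to_csv(
                outdir / "shared_demand.tsv", sep="\t", index=False
            )
        completed.append("metabolic")
    except Exception as exc:
        _fail("metabolic", exc)

    manifest["inputs_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir


def _spec_flags(config: PipelineConfig) -> list[bool]:
    return [i < 30 and i % 2 == 0 for i in range(config.n_taxa)]
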