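# coabnet

Longitudinal gut-microbiome co-abundance network analysis: how microbial
taxa co-vary across host developmental stages, which of those
relationships persist or rewire with age, and how co-abundance structure
relates to a continuous host phenotype such as growth rate.

The package is aimed at microbiome researchers who have stage-structured
taxon/MAG abundance tables (metagenomic relative abundances or counts)
plus per-sample phenotype metadata, and who want a reproducible pipeline
from compositionality-aware correlation inference to guild-level
phenotype association and metabolic interaction scoring — together with
a synthetic-data generator that plants ground truth so every stage of
the pipeline can be validated end to end without any sequencing data.

## What it computes

1. **Compositionality-corrected networks (SparCC).** Counts are mapped
   to Dirichlet-posterior fractions; pairwise log-ratio variances
   t_ij = Var[log(f_i/f_j)] are converted to basis variances ω² by
   solving ((p−2)I + 11ᵀ)ω² = Σ_j t_ij, giving
   r_ij = (ω_i² + ω_j² − t_ij)/(2ω_iω_j), with iterative exclusion of
   strongly correlated pairs and averaging over Dirichlet resamplings.
   Significance comes from per-taxon permutation nulls,
   p = (1 + #{|r_perm| ≥ |r_obs|})/(1 + B), with Benjamini–Hochberg FDR
   filtering (default q < 0.05) and a ≥10 % prevalence filter.
2. **Cross-stage edge dynamics.** Each edge shared across stages enters
   a fixed-effect Fisher-z meta-analysis: z_k = atanh(r_k), w_k = n_k−3,
   Cochran's Q = Σw_k(z_k − z̄)², I² = max(0, (Q−df)/Q)·100.  Edges are
   *stable* (p_Q > 0.05), *heterogeneous* (I² > 75 % and BH-adjusted
   p_Q < 0.05; further split into reversed / strengthened / weakened),
   or intermediate.
3. **Topology.** On the |r| > 0.2 strength-filtered networks: node and
   edge counts by sign, average degree, clustering, Freeman degree
   centralization, greedy-modularity modules, Guimerà–Amaral node roles
   (within-module degree z-score Zi vs participation coefficient Pi at
   2.5 / 0.62), power-law degree fits with a bootstrap plausibility
   verdict, and cross-stage module Jaccard similarity.
4. **Resilience.** Abundance-weighted mean interaction strength
   wMIS_i = Σ_j a_j r_ij / Σ_j a_j over neighbours; a core-node
   stability index; global efficiency and per-node vulnerability
   V_i = (E − E_−i)/E; and targeted-hub-removal (TR) versus random
   non-hub-attack (RA) robustness simulations compared by Wilcoxon
   rank-sum.
5. **Guilds.** A per-feature linear-model scan of log-TSS abundance on
   the phenotype (BH FDR < 0.2) followed by a signed-graph bipartition:
   positive-edge components are contracted and two-coloured along
   negative edges, producing two antagonistic guilds (within-guild edges
   positive, between-guild negative; violations reported as frustrated
   edges).
6. **Metabolic interactions.** From precomputed pairwise competition
   (MRO) and complementarity (MIP) indices: metabolic distance
   D = 1 − (MRO − MIP), composite competition intensity
   C = Z(MRO) − Z(MIP) with an upper-quartile competitive-pair rule,
   phylogeny-adjusted MIP outliers (residual Z > 2.698), per-guild
   core/shell/cloud pathway classes (≥90 % / ≤10 % prevalence), and a
   ranking of metabolites jointly demanded by competitive pairs.

## Worked example

The analysis scripts run the whole study on synthetic data with planted
truth (150 taxa, three stages × 300 samples, two 10-member antagonistic
guilds driving the phenotype, 12 strong conserved pairs, 8
sign-flipping pairs, three 30-taxon co-abundance modules):

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_infer_networks.py --seed 1
python analysis/03_edge_dynamics.py
python analysis/04_topology.py
python analysis/05_resilience.py
python analysis/06_guilds.py
python analysis/07_metabolic.py
```

Output of the chain (abridged):

```
D120: 150 nodes, 2430 edges (FDR<0.05; 984 negative); beneficial subnetwork 51 nodes / 300 edges
3653 distinct edges; 1587 present in all three stages
  stable: 1531/1587 (96.47%)
  heterogeneous: 8/1587 (0.5%)
  heterogeneous D25-vs-D120 categories: {'reversed': 8}
D120: 150 nodes / 1680 strong edges, 0 hubs, clustering 0.621, modularity 0.609
module similarity: {'D25|D120': 0.797, 'D120|D240': 0.879}
30 of 150 taxa associated with the phenotype at FDR<0.2 (19 positive, 11 negative)
guilds: 17 + 11 members, 2 unassigned, 0 frustrated edges
  guild1: median abundance high=0.0937 vs low=0.0500 (Wilcoxon p=1.03e-09)
  guild2: median abundance high=0.0685 vs low=0.1519 (Wilcoxon p=5.16e-12)
190 strain pairs; mean metabolic distance within guilds 0.769 vs between 1.339
25 of 100 between-guild pairs flagged competitive (upper quartile)
```

Reading the numbers: all 8 planted sign-flipping edges are the only
edges called heterogeneous, and every one is categorised *reversed*; the
two detected guilds contain exactly the 20 planted guild members (plus
a handful of false-positive associations expected at FDR 0.2, attached
by their inferred edges); guild 1 is enriched in high-phenotype samples
and guild 2 in low-phenotype samples, as planted; and within-guild
metabolic distance is lower than between-guild distance, the signature
of niche-sharing guilds.

The same pipeline runs on real tables through the configuration object
(`coabnet.config.PipelineConfig` pointing at abundance/metadata/taxonomy
TSVs) or the CLI (`coabnet run-all --config my.yaml --out outdir`).

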