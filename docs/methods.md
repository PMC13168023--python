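# Methods

This note documents the statistical models, parameter choices, and
numerical conventions behind `coabnet`, and what the synthetic study
does and does not establish.

## Correlation inference

SparCC assumes taxa abundances are observed only as compositions and
that the true correlation network is sparse.  Counts are converted to
fractions by the Dirichlet posterior mean with a uniform prior,
f_is = (c_is + 1)/(N_s + p), which also removes zeros.  The variation
matrix t_ij = Var[log(f_i/f_j)] (unbiased sample variance) is computed
from the covariance of log-fractions.  Basis variances solve
((p−2)I + 11ᵀ)ω² = rowsums(t); correlations follow as
r_ij = (ω_i² + ω_j² − t_ij)/(2ω_iω_j), clipped to [−1, 1].  The
sparsity assumption is protected by iteratively removing the strongest
pair with |r| above `exclusion_threshold` (default 0.1) from the linear
system — its t entries are zeroed and the corresponding diagonal terms
decremented — up to `max_exclusions` (default 10) times; exclusion
stops rather than degrade the system below four effectively coupled
taxa.  The final estimate averages `n_inner` (default 20) full Dirichlet
resamplings of the fractions; with `n_inner = 1` the posterior-mean
fractions are used directly, which makes the estimator deterministic and
is the mode used for oracle comparisons.

Significance: each permutation shuffles every taxon's counts
independently across samples, destroying all inter-taxon association
while preserving marginals, and the full SparCC matrix is recomputed;
p = (1 + #{|r_perm| ≥ |r_obs|})/(1 + B) with B = `n_permutations`
(pipeline default 1000; the synthetic study uses 200, see below).  A
bootstrap null (per-taxon resampling with replacement) is available via
`null_scheme="bootstrap"`.  BH adjustment runs over the upper triangle
only; edges are kept at q < 0.05.

The +1-smoothed permutation p-value has a floor of 1/(B+1).  A
consequence worth knowing: with m tests and k truly correlated pairs
all at the floor, BH discovers them only if k > m/(B·q_cut)
(approximately).  Sparse truths therefore need large B; realistically
dense truths (microbiome co-abundance networks typically have thousands
of correlated pairs) are discoverable at modest B.  The default
synthetic scenario is dense for exactly this reason.

## Cross-stage edge dynamics

Correlations are compared across stages on the Fisher-z scale with the
large-sample variance 1/(n−3), i.e. weights w_k = n_k − 3 — the
fixed-effect arm of a standard inverse-variance meta-analysis.
Cochran's Q is referred to χ²(K−1); I² = max(0, (Q−df)/Q)·100.
Classification: stable iff p_Q > 0.05 (unadjusted, a deliberate
pro-stability convention: absence of evidence of heterogeneity);
heterogeneous iff I² > 75 % and BH-adjusted p_Q < 0.05, with BH taken
over the set of edges shared by the stages being compared;
everything else is intermediate.  Heterogeneous two-stage pairs are
categorised *reversed* when the correlation signs differ, otherwise
*increased/decreased at the first stage* by |r|; an exactly-zero r
yields *indeterminate*.  Reported percentages are rounded half-up to
two decimals, matching the convention of printed summary tables.

Module similarity between two partitions is the full pairwise Jaccard
matrix plus a single network-level value: the mean of each module's
best match, symmetrised between the two directions.  The full matrix is
always emitted so any other aggregation can be recomputed.

## Topology

The strength filter keeps |r| > 0.2 by default.  A signed variant
(r > 0.2, discarding negative edges) exists, but absolute filtering is
the default because negative-edge counts are part of the topology
report and would otherwise be identically zero.  Modules come from
CNM greedy modularity maximisation on the |r|-weighted graph —
deterministic, which we prioritise over the marginally higher
modularity of stochastic Louvain; the `seed` argument only breaks ties.
Zi is the within-module degree z-score (0 where a module's
within-degrees have zero variance), Pi = 1 − Σ_s (k_is/k_i)².  Roles
use the standard quadrants at Zi = 2.5, Pi = 0.62: peripheral,
connector, module hub, network hub; all non-peripheral roles count as
hubs.  Clustering is the unweighted average local clustering
coefficient; centralization is Freeman's degree centralization
Σ(k_max − k_i)/((N−1)(N−2)).

Power-law fits use the continuous-approximation MLE
α = 1 + n/Σln(x_i/x_min) with x_min chosen by KS minimisation over the
observed degree values (tails of fewer than 10 points are skipped), and
a parametric bootstrap (100 resamples from the fitted law) for the
plausibility verdict at level 0.1.  This is a screening verdict, not a
full likelihood-ratio model comparison against alternatives.

## Resilience

wMIS_i is the abundance-weighted mean of signed edge correlations over
a node's neighbours; totals use |wMIS| so positive and negative
interactions both count as influence.  The stability index is
S = (|core|/|nodes|) · (Σ_core |wMIS| / Σ_all |wMIS|), where core nodes
are those present in every stage network; S is monotone in both
ingredients and equals 1 when all nodes are core.  These two formulas
are this package's concrete instantiation of abundance-weighted node
influence and core-weighted stability; output metadata labels them as
such.  Efficiency uses unweighted shortest paths (a 1/|r|-weighted
variant is behind a flag); vulnerability is the relative efficiency
loss on node deletion, and the network value is the maximum over nodes.

Robustness: TR removes floor(|hubs|/2) (minimum 1) randomly chosen
hubs, RA removes the same number of non-hubs; the retained fraction of
total |wMIS| (recomputed on the reduced network) is tracked over
replicates (default 10) and the two ratio lists are compared by
two-sided Wilcoxon rank-sum.  One caution from our own experiments:
within a single graph the replicates share all structure, so the
rank-sum will eventually detect *any* systematic hub/non-hub asymmetry,
including the mild degree bias that role-based hub sets have even in
Erdős–Rényi graphs.  Claims about network *classes* (scale-free vs
random) should therefore pool replicates across independent graph
instances, which is how the package's own scale-free/random contrast is
evaluated (30 ratios per arm across 10 graphs).  Where a network yields
fewer than two role-based hubs (common in homogeneous synthetic
modules), drivers fall back to the top-degree decile as the hub set.

## Guild detection

The association scan mirrors the common MaAsLin2 configuration reduced
to fixed effects: total-sum scaling, half-minimum replacement of zeros
per feature, log2 transform, per-feature OLS of transformed abundance
on phenotype plus optional covariates, BH across features, significance
at q < 0.2.  No random-effect grouping is modelled; a covariate slot
covers batch-like structure.

Guild structure is read off the signed co-abundance graph among
significant features: connected components of the positive-edge
subgraph are contracted to supernodes, and the supernode graph induced
by negative edges is two-coloured breadth-first.  Negative edges inside
a positive component and odd-cycle conflicts are recorded as frustrated
edges rather than aborting — real data is rarely perfectly balanced —
and the resulting partition is machine-checked: every sign violation
must appear in the frustrated list.  Guild 1 is the side with more
positively phenotype-associated members.  Supernodes touched by no
negative edge remain unassigned; a graph with no negative edges at all
is reported as a single guild.  The pipeline builds this graph from the
stage network's FDR-filtered edges (q < 0.05), the stricter of the two
conventions in circulation for this step; `detect_guilds` itself
accepts any signed graph, so a raw p < 0.05 graph can be supplied
instead.

Group comparisons use the Wilcoxon rank-sum test, exact for combined
n ≤ 25 without ties, tie-corrected normal approximation otherwise.
KO functional diversity is the Shannon index over a genome's KO counts.
Per-feature guild enrichment uses a binomial GLM for presence/absence
(Fisher's exact test under complete separation) and a Poisson GLM with
Pearson-χ² dispersion scaling (quasi-Poisson) for counts, BH-corrected
at FDR 0.05.  2×2 proportion comparisons use Fisher's exact test.

## Metabolic scoring

MRO and MIP are consumed as precomputed tables (their computation from
genome-scale metabolic models is out of scope).  D = 1 − (MRO − MIP)
∈ [0, 2]; C = Z(MRO) − Z(MIP) with Z-scores using the sample SD over
the pair set under analysis — over between-guild pairs when classifying
competition (the quantity of interest is competition *between* guilds),
over all pairs when reporting a global C.  The competitive set is the
top ⌈N/4⌉ pairs ranked by (C, pair id); the deterministic tie rule
means the flagged count is exactly ⌈N/4⌉ regardless of ties.
Phylogeny-adjusted complementarity outliers come from OLS of MIP on
phylogenetic distance with residuals standardised by their SD and a
one-sided threshold (default Z > 2.698, accepted as a conventional
parameter).  Pathway classes per guild: core ≥ 90 % prevalence, cloud
≤ 10 % or a single genome, shell otherwise; pathways absent from a
guild are omitted for that guild.  Shared-demand ranking scores each
metabolite by the number of competitive pairs whose uptake sets both
contain it, ties broken alphabetically.

## Synthetic data

The generator emulates stage-structured compositional sequencing
counts: per stage, a latent MVN with the planted correlation matrix
(log-scale SD 1.0 around a lognormal baseline profile), softmax to
composition, multinomial at fixed depth.  Planted matrices are repaired
to positive definiteness by eigenvalue clipping at 1e-6 and diagonal
renormalisation; if repair moves any planted entry by more than 0.02
the spec is rejected rather than silently distorted.  The phenotype is
effect_size × (guild-1 − guild-2 relative-abundance sum) + N(0,
noise_sd²).  Metabolic fixtures derive MRO from pathway-profile overlap
coefficients, phylogenetic distance from pathway Hamming distance plus
noise, and MIP as an increasing function of that distance — giving the
anti-correlated MRO/MIP and the positive MIP–distance relationship
observed empirically, with identical strains at MRO = 1.

Default study conditions: 150 taxa, 3 stages × 300 samples, depth
50,000; guilds of 10 + 10 with within-ρ 0.6 and between-ρ −0.5,
phenotype effect 5 and noise SD 1; 12 conserved ρ = 0.7 pairs; 8
variable pairs flipping ±0.7 between stages; and three conserved
30-taxon modules at within-ρ 0.4, giving ≈1,500 truly correlated pairs
out of 11,175 — the dense regime real co-abundance networks occupy,
and (see above) the regime in which FDR discovery at 200 permutations
is arithmetically possible.  All randomness flows from one master seed
through documented per-purpose counters (correlations 0, counts 100+k
for stage k, phenotype 200, metabolic 300); identical seeds give
byte-identical outputs.

What the synthetic study does *not* emulate: real taxon prevalence and
depth distributions (all taxa here pass the 10 % prevalence filter),
zero-inflation beyond multinomial sampling, overdispersion between
biological replicates, phylogenetic correlation of abundances, repeated
measures of individuals across stages, or covariate structure
(population, sex, batch).  Passing tests demonstrate that the
estimators recover planted truth under their own model assumptions,
not that those assumptions hold for any particular dataset.

## Problem sizes and runtime

The default synthetic study (three SparCC fits with 20 resamplings,
3 × 200 permutation matrices, full downstream analysis) completes in
roughly 15 seconds on one CPU; the acceptance recomputation, including
the 1,000-edge meta-analysis null calibration and the 20-graph
robustness ensemble, takes about a minute.  These sizes were chosen so
that the full validation loop is cheap enough to run habitually;
production datasets simply scale the same code.

## Known limitations

- The permutation null treats samples as exchangeable; longitudinal
  repeated measures would need a restricted permutation scheme.
- Fixed-effect meta-analysis assumes one true effect per edge within a
  stage; between-population heterogeneity within a stage is not
  modelled (no random-effects arm, by design).
- The stability and wMIS formulas are explicit package-level
  definitions (flagged in output metadata), chosen for monotonicity and
  boundary behaviour; other instantiations of the same ingredients
  exist.
- The power-law verdict is a KS screening test, not a
  likelihood-ratio comparison against log-normal or stretched
  exponential alternatives.
- Guild two-colouring is exact for balanced signed graphs; heavily
  frustrated graphs yield a partition whose quality should be judged by
  the reported frustrated-edge list.
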