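"""Synthetic stage-structured compositional data with planted ground truth.

Generates multi-stage microbial count tables whose latent log-abundances
carry planted pairwise correlations (conserved across stages or varying,
including sign flips), a continuous host phenotype driven by two
antagonistic guilds, and metabolic-score fixtures (resource-overlap /
complementarity matrices, phylogenetic distances, pathway presence,
uptake/secretion sets) with the qualitative structure expected of
genome-scale metabolic model outputs.

The count model is logistic-normal--multinomial: per sample a latent
vector is drawn from a multivariate normal with the stage correlation
matrix, softmax-transformed to composition, and multinomial-sampled at a
fixed sequencing depth.  This is the regime compositionality-aware
correlation estimators such as SparCC are designed for.

All randomness flows through a single integer seed expanded with a
documented per-purpose counter (see :func:`_child_rng`); no global state.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PlantedNetworkSpec",
    "PlantedGuildSpec",
    "SyntheticTruth",
    "generate_stage_correlations",
    "generate_counts",
    "generate_phenotype",
    "generate_metabolic_fixtures",
    "write_fixture_tables",
]

# Counters used when expanding the master seed into per-purpose streams.
# Stage k of the count generator uses _COUNTS + k.
_CORR = 0
_COUNTS = 100
_PHENOTYPE = 200
_METABOLIC = 300

#: maximum tolerated drift of a planted entry under nearest-PD repair
PD_REPAIR_TOL = 0.02


def _child_rng(seed: int, counter: int) -> np.random.Generator:
    """Deterministic child generator: master seed + purpose counter."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(counter,)))


@dataclass(frozen=True)
class PlantedNetworkSpec:
    """Planted correlation structure shared by all stages.

    conserved_edges: ``[((i, j), rho), ...]`` — the same rho in every stage.
    variable_edges: ``[((i, j), (rho_stage1, ..., rho_stageK)), ...]`` —
    per-stage values, sign flips allowed.
    """

    n_taxa: int
    stages: tuple[str, ...]
    conserved_edges: tuple[tuple[tuple[int, int], float], ...] = ()
    variable_edges: tuple[tuple[tuple[int, int], tuple[float, ...]], ...] = ()
    background_rho: float = 0.0
    beneficial_flags: tuple[bool, ...] = ()

    def __post_init__(self):
        if self.n_taxa < 2:
            raise ValueError("need at least 2 taxa")
        if len(self.stages) != len(set(self.stages)):
            raise ValueError("duplicate stage labels")
        if not -1.0 < self.background_rho < 1.0:
            raise ValueError("background_rho must lie in (-1, 1)")
        flags = self.beneficial_flags
        if flags and len(flags) != self.n_taxa:
            raise ValueError("beneficial_flags length must equal n_taxa")
        seen = set()
        for (i, j), rhos in self._edge_items():
            if not (0 <= i < self.n_taxa and 0 <= j < self.n_taxa) or i == j:
                raise ValueError(f"invalid taxon pair ({i}, {j})")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"pair ({i}, {j}) listed twice")
            seen.add(key)
            for r in rhos:
                if not -1.0 < r < 1.0:
                    raise ValueError(f"rho {r} out of (-1, 1) at pair ({i}, {j})")
        for (_, rhos) in self.variable_edges:
            if len(rhos) != len(self.stages):
                raise ValueError("variable edge needs one rho per stage")

    def _edge_items(self):
        for pair, rho in self.conserved_edges:
            yield pair, (rho,) * len(self.stages)
        for pair, rhos in self.variable_edges:
            yield pair, tuple(rhos)

    @property
    def flags(self) -> np.ndarray:
        if self.beneficial_flags:
            return np.asarray(self.beneficial_flags, dtype=bool)
        return np.zeros(self.n_taxa, dtype=bool)


@dataclass(frozen=True)
class PlantedGuildSpec:
    """Two antagonistic guilds driving a continuous phenotype.

    Guild-1 members correlate positively with each other (``within_rho``)
    and negatively with guild-2 members (``between_rho``); the phenotype is
    ``effect_size * (guild1 - guild2 relative-abundance sum)`` plus
    Gaussian noise.
    """

    guild1_members: tuple[int, ...]
    guild2_members: tuple[int, ...]
    within_rho: float = 0.6
    between_rho: float = -0.5
    effect_size: float = 5.0
    noise_sd: float = 1.0

    def __post_init__(self):
        g1, g2 = set(self.guild1_members), set(self.guild2_members)
        if g1 & g2:
            raise ValueError("guild member sets must be disjoint")
        if not (self.within_rho > 0 > self.between_rho):
            raise ValueError("need within_rho > 0 > between_rho")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside generated data."""

    stages: list[str]
    correlations: dict[str, np.ndarray]
    edge_labels: dict[str, str]          # "i-j" (i<j) -> "stable" | "variable"
    guild1: list[int]
    guild2: list[int]
    effect_size: float
    noise_sd: float

    def to_json(self) -> str:
        payload = {
            "stages": self.stages,
            "correlations": {k: v.tolist() for k, v in self.correlations.items()},
            "edge_labels": self.edge_labels,
            "guild1": self.guild1,
            "guild2": self.guild2,
            "effect_size": self.effect_size,
            "noise_sd": self.noise_sd,
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(
            stages=d["stages"],
            correlations={k: np.asarray(v) for k, v in d["correlations"].items()},
            edge_labels=d["edge_labels"],
            guild1=d["guild1"],
            guild2=d["guild2"],
            effect_size=d["effect_size"],
            noise_sd=d["noise_sd"],
        )

    def __eq__(self, other):
        if not isinstance(other, SyntheticTruth):
            return NotImplemented
        return self.to_json() == other.to_json()


def _nearest_pd(corr: np.ndarray, eig_floor: float = 1e-6) -> np.ndarray:
    """Nearest-PD repair: clip eigenvalues at ``eig_floor``, renormalise to
    unit diagonal."""
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() > eig_floor:
        return corr
    vals = np.clip(vals, eig_floor, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def generate_stage_correlations(
    spec: PlantedNetworkSpec, seed: int = 0
) -> tuple[dict[str, np.ndarray], SyntheticTruth]:
    """Build one latent correlation matrix per stage from the planted spec.

    Unlisted pairs get ``background_rho``.  Matrices that are not positive
    definite are repaired by eigenvalue clipping; if the repair moves any
    planted entry by more than ``PD_REPAIR_TOL`` the spec is rejected.
    """
    p, stages = spec.n_taxa, spec.stages
    mats: dict[str, np.ndarray] = {}
    labels: dict[str, str] = {}
    for k, stage in enumerate(stages):
        m = np.full((p, p), spec.background_rho, dtype=float)
        np.fill_diagonal(m, 1.0)
        for (i, j), rho in spec.conserved_edges:
            m[i, j] = m[j, i] = rho
        for (i, j), rhos in spec.variable_edges:
            m[i, j] = m[j, i] = rhos[k]
        repaired = _nearest_pd(m)
        for (i, j), rhos in spec._edge_items():
            drift = abs(repaired[i, j] - rhos[k])
            if drift > PD_REPAIR_TOL:
                raise ValueError(
                    f"stage {stage!r}: planted correlation at pair ({i}, {j}) "
                    f"drifted by {drift:.3f} under positive-definite repair; "
                    "spec is not realisable"
                )
        mats[stage] = repaired
    for (i, j), _ in spec.conserved_edges:
        labels[f"{min(i, j)}-{max(i, j)}"] = "stable"
    for (i, j), _ in spec.variable_edges:
        labels[f"{min(i, j)}-{max(i, j)}"] = "variable"
    truth = SyntheticTruth(
        stages=list(stages),
        correlations={s: m.copy() for s, m in mats.items()},
        edge_labels=labels,
        guild1=[],
        guild2=[],
        effect_size=0.0,
        noise_sd=0.0,
    )
    return mats, truth


def generate_counts(
    correlations: dict[str, np.ndarray],
    n_samples: int,
    depth: int = 50_000,
    seed: int = 0,
    log_sd: float = 1.0,
    base_log_abundance: Sequence[float] | None = None,
) -> dict[str, pd.DataFrame]:
    """Logistic-normal--multinomial counts per stage.

    Returns one DataFrame per stage, taxa as rows (``taxon_000`` ...),
    samples as columns; every column sums exactly to ``depth``.
    ``base_log_abundance`` sets per-taxon mean log-abundance (defaults to a
    mildly heterogeneous lognormal profile so relative abundances are not
    uniform, as in real communities).
    """
    if depth < 1000:
        raise ValueError("depth must be >= 1000")
    if n_samples < 10:
        raise ValueError("n_samples must be >= 10")
    out: dict[str, pd.DataFrame] = {}
    for k, (stage, corr) in enumerate(correlations.items()):
        p = corr.shape[0]
        vals = np.linalg.eigvalsh(corr)
        if vals.min() <= 0:
            raise ValueError(f"correlation matrix for stage {stage!r} is not PD")
        rng = _child_rng(seed, _COUNTS + k)
        if base_log_abundance is None:
            base = rng.normal(0.0, 0.8, size=p)
        else:
            base = np.asarray(base_log_abundance, dtype=float)
        chol = np.linalg.cholesky(corr)
        z = rng.standard_normal((n_samples, p)) @ chol.T
        logab = base + log_sd * z
        comp = np.exp(logab - logab.max(axis=1, keepdims=True))
        comp /= comp.sum(axis=1, keepdims=True)
        counts = np.stack([rng.multinomial(depth, comp[s]) for s in range(n_samples)])
        taxa = [f"taxon_{i:03d}" for i in range(p)]
        samples = [f"{stage}_s{j:03d}" for j in range(n_samples)]
        out[stage] = pd.DataFrame(counts.T, index=taxa, columns=samples)
    return out


def generate_phenotype(
    abundances: pd.DataFrame,
    guild_spec: PlantedGuildSpec,
    seed: int = 0,
) -> pd.Series:
    """Per-sample phenotype driven by the guild relative-abundance contrast."""
    if not guild_spec.guild1_members or not guild_spec.guild2_members:
        raise ValueError("guilds must be non-empty")
    p = abundances.shape[0]
    for i in (*guild_spec.guild1_members, *guild_spec.guild2_members):
        if not 0 <= i < p:
            raise ValueError(f"guild member index {i} outside table")
    rel = abundances.to_numpy(dtype=float)
    rel = rel / rel.sum(axis=0, keepdims=True)
    contrast = (
        rel[list(guild_spec.guild1_members)].sum(axis=0)
        - rel[list(guild_spec.guild2_members)].sum(axis=0)
    )
    rng = _child_rng(seed, _PHENOTYPE)
    noise = rng.normal(0.0, guild_spec.noise_sd, size=rel.shape[1]) if guild_spec.noise_sd > 0 else 0.0
    return pd.Series(
        guild_spec.effect_size * contrast + noise,
        index=abundances.columns,
        name="phenotype",
    )


def guild_correlation_spec(
    guild_spec: PlantedGuildSpec,
    n_taxa: int,
    stages: Sequence[str],
    background_rho: float = 0.0,
    beneficial_flags: Sequence[bool] = (),
) -> PlantedNetworkSpec:
    """Expand a guild spec into the pairwise planted-network spec
    (positive within guilds, negative between)."""
    g1 = list(guild_spec.guild1_members)
    g2 = list(guild_spec.guild2_members)
    edges = []
    for members, rho in ((g1, guild_spec.within_rho), (g2, guild_spec.within_rho)):
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                edges.append(((members[a], members[b]), rho))
    for a in g1:
        for b in g2:
            edges.append(((a, b), guild_spec.between_rho))
    return PlantedNetworkSpec(
        n_taxa=n_taxa,
        stages=tuple(stages),
        conserved_edges=tuple(edges),
        background_rho=background_rho,
        beneficial_flags=tuple(beneficial_flags),
    )


@dataclass
class MetabolicFixtures:
    """Bundle of synthetic genome-scale-metabolic-model summary tables."""

    strains: list[str]
    # explicit field(): the name 'mro' would otherwise shadow type.mro and
    # be mistaken for a class-level default by the dataclass machinery
    mro: pd.DataFrame = field()
    mip: pd.DataFrame = field()
    phylo_distance: pd.DataFrame
    pathway_presence: pd.DataFrame
    uptake_sets: dict[str, set[str]]
    secretion_sets: dict[str, set[str]]
    guild_labels: pd.Series


def generate_metabolic_fixtures(
    guild_spec: PlantedGuildSpec,
    n_pathways: int = 60,
    n_metabolites: int = 40,
    seed: int = 0,
) -> MetabolicFixtures:
    """Synthetic MRO/MIP/phylogeny/pathway fixtures for the guild members.

    Construction: each strain gets a binary pathway profile biased toward
    its guild's core pathways.  Resource overlap (MRO) is the pathway
    overlap coefficient, so identical profiles give MRO = 1.  Phylogenetic
    distance is pathway Hamming distance plus noise; complementarity (MIP)
    increases with phylogenetic distance (and therefore decreases with
    MRO), reproducing the empirically observed anti-correlation of the two
    indices and the positive MIP--distance relationship.
    """
    if n_pathways < 20:
        raise ValueError("n_pathways must be >= 20")
    members = list(guild_spec.guild1_members) + list(guild_spec.guild2_members)
    if len(members) < 4:
        raise ValueError("need at least 4 strains")
    rng = _child_rng(seed, _METABOLIC)
    strains = [f"strain_{i:03d}" for i in members]
    guild_of = pd.Series(
        ["guild1"] * len(guild_spec.guild1_members)
        + ["guild2"] * len(guild_spec.guild2_members),
        index=strains,
        name="guild",
    )
    n = len(strains)
    # guild-specific pathway cores: high carriage inside the guild, low outside
    core1 = rng.random(n_pathways) < 0.3
    core2 = rng.random(n_pathways) < 0.3
    base_prob = rng.uniform(0.05, 0.45, size=n_pathways)
    presence = np.zeros((n, n_pathways), dtype=int)
    for s in range(n):
        prob = base_prob.copy()
        core = core1 if guild_of.iloc[s] == "guild1" else core2
        prob[core] = 0.9
        presence[s] = rng.random(n_pathways) < prob
    pathways = [f"pwy_{k:03d}" for k in range(n_pathways)]
    pathway_presence = pd.DataFrame(presence, index=strains, columns=pathways)

    # overlap coefficient => identical rows give 1
    sizes = presence.sum(axis=1)
    inter = presence @ presence.T
    denom = np.minimum.outer(sizes, sizes).astype(float)
    denom[denom == 0] = 1.0
    mro = inter / denom
    np.fill_diagonal(mro, 1.0)

    hamming = (presence[:, None, :] != presence[None, :, :]).mean(axis=2)
    noise = rng.normal(0, 0.03, size=(n, n))
    noise = (noise + noise.T) / 2
    dist = np.clip(hamming + noise, 0.0, None)
    np.fill_diagonal(dist, 0.0)

    mip_noise = rng.normal(0, 0.05, size=(n, n))
    mip_noise = (mip_noise + mip_noise.T) / 2
    mip = np.clip(0.1 + 0.9 * dist / max(dist.max(), 1e-12) + mip_noise, 0.0, 1.0)
    np.fill_diagonal(mip, 0.0)

    mro_df = pd.DataFrame(np.clip(mro, 0, 1), index=strains, columns=strains)
    mip_df = pd.DataFrame(mip, index=strains, columns=strains)
    dist_df = pd.DataFrame(dist, index=strains, columns=strains)

    metabolites = [f"met_{k:03d}" for k in range(n_metabolites)]
    uptake: dict[str, set[str]] = {}
    secretion: dict[str, set[str]] = {}
    # guild-biased demand: shared demands concentrate within a guild
    pref1 = rng.random(n_metabolites) < 0.4
    pref2 = rng.random(n_metabolites) < 0.4
    for s, strain in enumerate(strains):
        pref = pref1 if guild_of.iloc[s] == "guild1" else pref2
        prob = np.where(pref, 0.7, 0.15)
        uptake[strain] = {m for m, keep in zip(metabolites, rng.random(n_metabolites) < prob) if keep}
        secretion[strain] = {
            m for m, keep in zip(metabolites, rng.random(n_metabolites) < 0.2) if keep
        }
    return MetabolicFixtures(
        strains=strains,
        mro=mro_df,
        mip=mip_df,
        phylo_distance=dist_df,
        pathway_presence=pathway_presence,
        uptake_sets=uptake,
        secretion_sets=secretion,
        guild_labels=guild_of,
    )


def write_metabolic_tables(outdir, fixtures: "MetabolicFixtures") -> None:
    """Write MRO/MIP/distance matrices, pathway presence, exchange sets,
    and guild labels as TSVs."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in (
        ("mro", fixtures.mro),
        ("mip", fixtures.mip),
        ("phylo_distance", fixtures.phylo_distance),
        ("pathway_presence", fixtures.pathway_presence),
    ):
        out = df.copy()
        out.index.name = "strain"
        out.to_csv(outdir / f"{name}.tsv", sep="\t")
    rows = []
    for direction, sets in (("uptake", fixtures.uptake_sets), ("secretion", fixtures.secretion_sets)):
        for strain in fixtures.strains:
            for met in sorted(sets[strain]):
                rows.append({"strain": strain, "metabolite": met, "direction": direction})
    pd.DataFrame(rows).to_csv(outdir / "exchange.tsv", sep="\t", index=False)
    fixtures.guild_labels.rename_axis("strain").to_csv(outdir / "guild_labels.tsv", sep="\t")


def write_fixture_tables(
    outdir,
    counts: dict[str, pd.DataFrame],
    phenotype: pd.Series,
    truth: SyntheticTruth,
    beneficial_flags: np.ndarray | None = None,
) -> None:
    """Write abundance/metadata/taxonomy TSVs and the truth JSON."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta_rows = []
    for stage, table in counts.items():
        df = table.copy()
        df.index.name = "taxon"
        df.to_csv(outdir / f"abundance_{stage}.tsv", sep="\t")
        for sample in table.columns:
            meta_rows.append(
                {
                    "sample": sample,
                    "stage": stage,
                    "phenotype": float(phenotype.get(sample, np.nan)),
                }
            )
    pd.DataFrame(meta_rows).to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    any_stage = next(iter(counts.values()))
    taxa = list(any_stage.index)
    flags = (
        beneficial_flags
        if beneficial_flags is not None
        else np.zeros(len(taxa), dtype=bool)
    )
    pd.DataFrame(
        {
            "taxon": taxa,
            "lineage": [f"d__Bacteria;s__{t}" for t in taxa],
            "beneficial": np.asarray(flags, dtype=int),
        }
    ).to_csv(outdir / "taxonomy.tsv", sep="\t", index=False)
    (outdir / "truth.json").write_text(truth.to_json())
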