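"""Association scan, signed-graph guild detection, group comparisons."""

import numpy as np
import pandas as pd
import networkx as nx
import pytest
from sklearn.metrics import adjusted_rand_score

from coabnet import guilds, netinfer, synthdata


def _signed(edges):
    g = nx.Graph()
    for a, b, r in edges:
        g.add_edge(a, b, r=r)
    return g


class TestAssociateFeatures:
    def test_perfect_predictor_ranks_first(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(
            rng.integers(1, 500, size=(30, 60)),
            index=[f"t{i}" for i in range(30)],
            columns=[f"s{j}" for j in range(60)],
        )
        rel = table / table.sum(axis=0)
        phen = pd.Series(np.log2(rel.loc["t0"]), index=table.columns)
        res = guilds.associate_features(table, phen)
        assert res.iloc[0]["feature"] == "t0"
        assert res.iloc[0]["q"] == res["q"].min()

    def test_null_controls_fdr(self):
        """With phenotype independent of all 200 features, <= 25% are
        called at q < 0.2."""
        rng = np.random.default_rng(1)
        table = pd.DataFrame(
            rng.integers(1, 500, size=(200, 100)),
            index=[f"t{i}" for i in range(200)],
            columns=[f"s{j}" for j in range(100)],
        )
        phen = pd.Series(rng.normal(size=100), index=table.columns)
        res = guilds.associate_features(table, phen)
        assert res["significant"].mean() <= 0.25

    def test_planted_guild_recovery(self):
        """Planted effect 5 / noise 1: >= 80% of guild-1 members recovered
        with positive sign."""
        gspec = synthdata.PlantedGuildSpec(
            tuple(range(10)), tuple(range(10, 20)), effect_size=5.0, noise_sd=1.0
        )
        net_spec = synthdata.guild_correlation_spec(gspec, 60, ("S",))
        mats, _ = synthdata.generate_stage_correlations(net_spec, seed=2)
        counts = synthdata.generate_counts(mats, n_samples=200, depth=30_000, seed=2)["S"]
        phen = synthdata.generate_phenotype(counts, gspec, seed=3)
        res = guilds.associate_features(counts, phen).set_index("feature")
        g1 = [f"taxon_{i:03d}" for i in range(10)]
        hits = res.loc[g1]
        frac = ((hits["significant"]) & (hits["direction"] == "positive")).mean()
        assert frac >= 0.8

    def test_too_few_samples_rejected(self):
        table = pd.DataFrame(np.ones((3, 10)), columns=[f"s{j}" for j in range(10)])
        with pytest.raises(ValueError):
            guilds.associate_features(table, pd.Series(np.arange(10.0), index=table.columns))


class TestDetectGuilds:
    def test_two_coloring_by_hand(self):
        g = _signed([(1, 2, 0.5), (3, 4, 0.5), (1, 3, -0.5), (2, 4, -0.5)])
        part = guilds.detect_guilds(g)
        assert {frozenset(part.guild1), frozenset(part.guild2)} == {
            frozenset({1, 2}), frozenset({3, 4})
        }
        assert part.frustrated_edges == [] and part.unassigned == set()

    def test_all_positive_single_guild(self):
        g = _signed([("a", "b", 0.5), ("b", "c", 0.4), ("a", "c", 0.3)])
        part = guilds.detect_guilds(g)
        assert part.guild1 == {"a", "b", "c"} and part.guild2 == set()

    def test_negative_triangle_reports_frustration(self):
        g = _signed([("a", "b", -0.5), ("b", "c", -0.5), ("a", "c", -0.5)])
        part = guilds.detect_guilds(g)
        assert len(part.frustrated_edges) == 1

    def test_negative_edge_inside_positive_component_frustrated(self):
        g = _signed([("a", "b", 0.5), ("b", "c", 0.5), ("a", "c", -0.5), ("a", "d", -0.6)])
        part = guilds.detect_guilds(g)
        assert ("a", "c") in part.frustrated_edges

    def test_phenotype_anchoring(self):
        g = _signed([(1, 2, 0.5), (3, 4, 0.5), (1, 3, -0.5)])
        part = guilds.detect_guilds(
            g, phenotype_direction={3: "positive", 4: "positive", 1: "negative", 2: "negative"}
        )
        assert part.guild1 == {3, 4}

    def test_clean_synthetic_recovery_ari_one(self):
        """Planted two-guild compositional data (within 0.6 / between
        -0.5, n = 300): SparCC graph two-coloring recovers the planted
        membership with adjusted Rand index 1.0."""
        gspec = synthdata.PlantedGuildSpec(
            tuple(range(8)), tuple(range(8, 16)), within_rho=0.6, between_rho=-0.5
        )
        net_spec = synthdata.guild_correlation_spec(gspec, 30, ("S",))
        mats, _ = synthdata.generate_stage_correlations(net_spec, seed=4)
        counts = synthdata.generate_counts(mats, n_samples=300, depth=30_000, seed=4)["S"]
        r, _ = netinfer.sparcc(counts, n_inner=5, seed=4)
        p = netinfer.permutation_pvalues(counts, r, n_permutations=200, seed=5)
        members = list(range(16))
        g = nx.Graph()
        g.add_nodes_from(members)
        for i in members:
            for j in members:
                if i < j and p[i, j] < 0.05:
                    g.add_edge(i, j, r=r[i, j])
        part = guilds.detect_guilds(g)
        pred = [part.label_of(i) or "none" for i in members]
        true = ["g1" if i < 8 else "g2" for i in members]
        assert adjusted_rand_score(true, pred) == 1.0


class TestGuildAbundance:
    def test_sums_and_closure(self):
        table = pd.DataFrame(
            [[10, 20], [30, 40], [60, 40]],
            index=["a", "b", "c"],
            columns=["s1", "s2"],
        )
        part = guilds.GuildPartition(guild1={"a"}, guild2={"b", "c"})
        gab = guilds.guild_abundance(table, part)
        assert gab.loc["s1", "guild1"] == pytest.approx(0.1)
        np.testing.assert_allclose(gab.sum(axis=1), 1.0)


class TestCompareGroups:
    def test_full_separation_exact_p(self):
        vals = [1, 2, 3, 4, 5, 10, 11, 12, 13, 14]
        labels = ["lo"] * 5 + ["hi"] * 5
        _, p = guilds.compare_groups(vals, labels)
        assert p == pytest.approx(2 / 252, rel=1e-10)

    def test_identical_groups_near_one(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=40)
        labels = ["a"] * 20 + ["b"] * 20
        _, p = guilds.compare_groups(np.concatenate([v[:20], v[:20]]), labels)
        assert p > 0.9

    def test_power_on_shifted_normals(self):
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(60):
            a = rng.normal(0, 1, 30)
            b = rng.normal(2, 1, 30)
            _, p = guilds.compare_groups(
                np.concatenate([a, b]), ["a"] * 30 + ["b"] * 30
            )
            hits += p < 0.01
        assert hits / 60 >= 0.95

    def test_errors(self):
        with pytest.raises(ValueError):
            guilds.compare_groups([1, 2, 3], ["a", "a", "a"])


class TestKoShannon:
    def test_hand_values(self):
        table = pd.DataFrame(
            [[5, 0, 0, 0], [1, 1, 1, 1], [1, 1, 2, 0]],
            index=["g1", "g2", "g3"],
        )
        h = guilds.ko_shannon(table)
        assert h["g1"] == pytest.approx(0.0)
        assert h["g2"] == pytest.approx(np.log(4))
        expected = -(0.25 * np.log(0.25) * 2 + 0.5 * np.log(0.5))
        assert h["g3"] == pytest.approx(expected)
        with pytest.raises(ValueError):
            guilds.ko_shannon(pd.DataFrame([[0, 0]], index=["empty"]))


class TestEnrichment:
    def test_separated_feature_significant(self):
        rng = np.random.default_rng(4)
        genomes = [f"g{i}" for i in range(40)]
        labels = pd.Series(["guild1"] * 20 + ["guild2"] * 20, index=genomes)
        mat = pd.DataFrame(
            {
                "sep": [1] * 20 + [0] * 20,
                "flat": [1, 0] * 20,
                "noise": rng.integers(0, 2, 40),
            },
            index=genomes,
        )
        res = guilds.enrichment_scan(mat, labels).set_index("feature")
        assert res.loc["sep", "significant"]
        assert res.loc["sep", "enriched_in"] == "guild1"
        assert not res.loc["flat", "significant"]

    def test_count_features_use_overdispersion(self):
        rng = np.random.default_rng(5)
        genomes = [f"g{i}" for i in range(40)]
        labels = pd.Series(["guild1"] * 20 + ["guild2"] * 20, index=genomes)
        mat = pd.DataFrame(
            {"hi": np.concatenate([rng.poisson(20, 20), rng.poisson(5, 20)])},
            index=genomes,
        )
        res = guilds.enrichment_scan(mat, labels).set_index("feature")
        assert res.loc["hi", "significant"] and res.loc["hi", "enriched_in"] == "guild1"

    def test_null_fdr_control(self):
        """500 null binary features: <= 7% called at FDR 0.05."""
        rng = np.random.default_rng(6)
        genomes = [f"g{i}" for i in range(60)]
        labels = pd.Series(["guild1"] * 30 + ["guild2"] * 30, index=genomes)
        mat = pd.DataFrame(
            rng.integers(0, 2, size=(60, 500)),
            index=genomes,
            columns=[f"k{i}" for i in range(500)],
        )
        res = guilds.enrichment_scan(mat, labels)
        assert res["significant"].mean() <= 0.07


class TestProportionTest:
    @pytest.mark.parametrize(
        "table,check",
        [
            ((10, 0, 0, 10), lambda p: p < 1e-4),
            ((5, 5, 5, 5), lambda p: p == pytest.approx(1.0)),
            ((1, 9, 9, 1), lambda p: p == pytest.approx(0.0011, abs=0.0002)),
        ],
    )
    def test_fisher_examples(self, table, check):
        _, p = guilds.proportion_test(*table)
        assert check(p)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            guilds.proportion_test(-1, 2, 3, 4)
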