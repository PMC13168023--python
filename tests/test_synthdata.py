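"""Synthetic-data generator: planted structure, closure, determinism."""

import numpy as np
import pandas as pd
import pytest

from coabnet import netinfer, synthdata
from coabnet.synthdata import (
    PlantedGuildSpec,
    PlantedNetworkSpec,
    SyntheticTruth,
    generate_counts,
    generate_metabolic_fixtures,
    generate_phenotype,
    generate_stage_correlations,
)


class TestStageCorrelations:
    def test_zero_edges_yield_identity(self):
        spec = PlantedNetworkSpec(n_taxa=5, stages=("A", "B"))
        mats, _ = generate_stage_correlations(spec)
        for m in mats.values():
            np.testing.assert_allclose(m, np.eye(5))

    def test_conserved_edge_present_in_all_stages(self):
        spec = PlantedNetworkSpec(
            n_taxa=6, stages=("A", "B", "C"), conserved_edges=(((1, 4), 0.5),)
        )
        mats, truth = generate_stage_correlations(spec)
        for m in mats.values():
            assert m[1, 4] == pytest.approx(0.5, abs=synthdata.PD_REPAIR_TOL)
        assert truth.edge_labels == {"1-4": "stable"}

    def test_variable_edge_only_difference(self):
        spec = PlantedNetworkSpec(
            n_taxa=6,
            stages=("A", "B", "C"),
            variable_edges=(((0, 5), (0.4, -0.4, 0.4)),),
        )
        mats, _ = generate_stage_correlations(spec)
        diff = mats["A"] - mats["B"]
        mask = np.zeros((6, 6), dtype=bool)
        mask[0, 5] = mask[5, 0] = True
        assert np.all(diff[~mask] == 0)
        assert diff[0, 5] == pytest.approx(0.8, abs=2 * synthdata.PD_REPAIR_TOL)
        np.testing.assert_array_equal(mats["A"], mats["C"])

    def test_matrices_are_symmetric_unit_diagonal_pd(self):
        spec = PlantedNetworkSpec(
            n_taxa=8,
            stages=("A",),
            conserved_edges=(((0, 1), 0.7), ((2, 3), -0.6)),
            background_rho=0.05,
        )
        mats, _ = generate_stage_correlations(spec)
        m = mats["A"]
        np.testing.assert_allclose(m, m.T)
        np.testing.assert_allclose(np.diag(m), 1.0)
        assert np.linalg.eigvalsh(m).min() > 0

    def test_unrealisable_spec_names_stage(self):
        # rho(0,1)=rho(0,2)=0.9 with rho(1,2)=-0.9 cannot be a correlation
        spec = PlantedNetworkSpec(
            n_taxa=4,
            stages=("bad",),
            conserved_edges=(((0, 1), 0.9), ((0, 2), 0.9), ((1, 2), -0.9)),
        )
        with pytest.raises(ValueError, match="bad"):
            generate_stage_correlations(spec)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_taxa=4, stages=("A",), conserved_edges=(((0, 7), 0.5),)),
            dict(n_taxa=4, stages=("A",),
                 conserved_edges=(((0, 1), 0.5),),
                 variable_edges=(((1, 0), (0.2,)),)),
            dict(n_taxa=4, stages=("A", "A")),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PlantedNetworkSpec(**kwargs)


class TestCounts:
    def test_columns_sum_to_depth_and_determinism(self, three_stage_counts):
        _, mats, counts, _ = three_stage_counts
        for stage, table in counts.items():
            assert (table.sum(axis=0) == 20_000).all()
        again = generate_counts(mats, n_samples=200, depth=20_000, seed=11)
        for stage in counts:
            pd.testing.assert_frame_equal(counts[stage], again[stage])

    def test_planted_correlation_visible_in_clr(self):
        """rho = 0.8 pair at n = 500, depth = 50k: CLR-transformed counts
        correlate > 0.5."""
        spec = PlantedNetworkSpec(
            n_taxa=10, stages=("A",), conserved_edges=(((0, 1), 0.8),)
        )
        mats, _ = generate_stage_correlations(spec)
        counts = generate_counts(mats, n_samples=500, depth=50_000, seed=3)["A"]
        x = counts.to_numpy(dtype=float) + 0.5
        logx = np.log(x)
        clr = logx - logx.mean(axis=0, keepdims=True)
        r = np.corrcoef(clr[0], clr[1])[0, 1]
        assert r > 0.5

    def test_sign_recovery_of_strong_planted_edges(self):
        """SparCC recovers the sign of every |rho| >= 0.6 planted edge at
        n = 300, depth = 20k (>= 95% required)."""
        edges = tuple(((2 * k, 2 * k + 1), 0.7 if k % 2 else -0.6) for k in range(10))
        spec = PlantedNetworkSpec(n_taxa=25, stages=("A",), conserved_edges=edges)
        mats, _ = generate_stage_correlations(spec)
        counts = generate_counts(mats, n_samples=300, depth=20_000, seed=4)["A"]
        r, _ = netinfer.sparcc(counts, n_inner=1)
        correct = sum(
            1 for (i, j), rho in edges if np.sign(r[i, j]) == np.sign(rho)
        )
        assert correct / len(edges) >= 0.95

    def test_input_validation(self):
        mats = {"A": np.eye(3)}
        with pytest.raises(ValueError):
            generate_counts(mats, n_samples=5, depth=20_000)
        with pytest.raises(ValueError):
            generate_counts(mats, n_samples=20, depth=10)
        bad = {"A": np.array([[1.0, 2.0], [2.0, 1.0]])}
        with pytest.raises(ValueError, match="PD"):
            generate_counts(bad, n_samples=20, depth=2000)


@pytest.fixture(scope="module")
def table():
    rng = np.random.default_rng(9)
    return pd.DataFrame(
        rng.integers(1, 200, size=(12, 200)),
        index=[f"t{i}" for i in range(12)],
        columns=[f"s{j}" for j in range(200)],
    )


@pytest.fixture(scope="module")
def fixtures():
    spec = PlantedGuildSpec(tuple(range(8)), tuple(range(8, 16)))
    return generate_metabolic_fixtures(spec, n_pathways=40, seed=2)


class TestPhenotype:
    def test_null_and_exact_cases(self, table):
        spec = PlantedGuildSpec((0, 1), (2, 3), effect_size=0.0, noise_sd=0.0)
        y = generate_phenotype(table, spec)
        np.testing.assert_allclose(y, 0.0)
        spec = PlantedGuildSpec((0, 1), (2, 3), effect_size=1.0, noise_sd=0.0)
        y = generate_phenotype(table, spec)
        rel = table / table.sum(axis=0)
        expected = rel.iloc[[0, 1]].sum() - rel.iloc[[2, 3]].sum()
        np.testing.assert_allclose(y, expected)

    def test_signal_dominates_at_planted_effect(self, table):
        spec = PlantedGuildSpec((0, 1, 2), (3, 4, 5), effect_size=5.0, noise_sd=0.01)
        y = generate_phenotype(table, spec, seed=1)
        rel = table / table.sum(axis=0)
        contrast = rel.iloc[[0, 1, 2]].sum() - rel.iloc[[3, 4, 5]].sum()
        assert np.corrcoef(y, contrast)[0, 1] > 0.8

    def test_empty_guild_rejected(self, table):
        with pytest.raises(ValueError):
            generate_phenotype(table, PlantedGuildSpec((), (1,)))


class TestMetabolicFixtures:
    def test_matrices_symmetric_in_range(self, fixtures):
        for m in (fixtures.mro, fixtures.mip):
            v = m.to_numpy()
            np.testing.assert_allclose(v, v.T)
            assert v.min() >= 0 and v.max() <= 1
        assert set(np.unique(fixtures.pathway_presence)) <= {0, 1}

    def test_mro_mip_anticorrelated_and_mip_tracks_phylogeny(self, fixtures):
        iu = np.triu_indices(len(fixtures.strains), k=1)
        mro = fixtures.mro.to_numpy()[iu]
        mip = fixtures.mip.to_numpy()[iu]
        dist = fixtures.phylo_distance.to_numpy()[iu]
        assert np.corrcoef(mro, mip)[0, 1] < 0
        assert np.corrcoef(mip, dist)[0, 1] > 0

    def test_identical_strains_full_overlap(self):
        spec = PlantedGuildSpec(tuple(range(4)), tuple(range(4, 8)))
        fx = generate_metabolic_fixtures(spec, n_pathways=30, seed=0)
        fx.pathway_presence.iloc[1] = fx.pathway_presence.iloc[0]
        # recompute overlap coefficient for the duplicated pair
        a = fx.pathway_presence.iloc[0].to_numpy()
        b = fx.pathway_presence.iloc[1].to_numpy()
        assert (a & b).sum() / min(a.sum(), b.sum()) == 1.0

    def test_determinism_and_small_input_rejected(self):
        spec = PlantedGuildSpec((0, 1, 2, 3), (4, 5, 6, 7))
        f1 = generate_metabolic_fixtures(spec, seed=5)
        f2 = generate_metabolic_fixtures(spec, seed=5)
        pd.testing.assert_frame_equal(f1.mro, f2.mro)
        pd.testing.assert_frame_equal(f1.mip, f2.mip)
        assert f1.uptake_sets == f2.uptake_sets
        with pytest.raises(ValueError):
            generate_metabolic_fixtures(PlantedGuildSpec((0,), (1, 2)), seed=0)
        with pytest.raises(ValueError):
            generate_metabolic_fixtures(spec, n_pathways=10, seed=0)


def test_truth_serialization_round_trip(three_stage_counts):
    *_, truth = three_stage_counts
    truth.guild1, truth.guild2 = [0, 1], [2, 3]
    clone = SyntheticTruth.from_json(truth.to_json())
    assert clone == truth
    assert clone.to_json() == truth.to_json()
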