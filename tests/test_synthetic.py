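"""Synthetic generators: SAD shapes, sampling, RNA derivation, scenarios."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reactscape import (
    ContinuumScenario,
    MockScenario,
    SadSpec,
    default_mock_grid,
    derive_rna,
    generate_sad,
    pielou_evenness,
    sample_assemblage,
    simulate_continuum,
    simulate_mock_experiment,
)


class TestGenerateSad:
    def test_uniform_limit_is_exactly_even(self):
        p = generate_sad(SadSpec("near_uniform", 4, float("inf")))
        np.testing.assert_allclose(p, [0.25, 0.25, 0.25, 0.25])

    def test_geometric_closed_form(self):
        # ratio 1/2 over 3 species: proportions 4:2:1
        p = generate_sad(SadSpec("geometric", 3, 0.5))
        np.testing.assert_allclose(p, [4 / 7, 2 / 7, 1 / 7])

    @pytest.mark.parametrize(
        "kind,lo,hi",
        [
            ("geometric", 0.5, 0.9),
            ("lognormal", 0.5, 2.0),
            ("broken_stick", 0.2, 0.8),
            ("near_uniform", 1.0, 100.0),
        ],
    )
    def test_evenness_param_orders_pielou(self, kind, lo, hi):
        j_lo = pielou_evenness(generate_sad(SadSpec(kind, 40, lo, seed=7)))
        j_hi = pielou_evenness(generate_sad(SadSpec(kind, 40, hi, seed=7)))
        assert j_lo < j_hi

    @given(
        kind=st.sampled_from(["geometric", "lognormal", "broken_stick"]),
        richness=st.integers(2, 200),
        par=st.floats(0.05, 0.95),
    )
    @settings(max_examples=50, deadline=None)
    def test_simplex_and_sorted(self, kind, richness, par):
        p = generate_sad(SadSpec(kind, richness, par))
        assert len(p) == richness
        assert (p > 0).all()
        assert abs(p.sum() - 1.0) < 1e-9
        assert (np.diff(p) <= 1e-15).all()

    @pytest.mark.parametrize(
        "spec",
        [
            ("no_such_family", 5, 0.5),
            ("geometric", 1, 0.5),
            ("geometric", 5, 1.5),
            ("near_uniform", 5, -1.0),
        ],
    )
    def test_invalid_specs_raise(self, spec):
        with pytest.raises(ValueError):
            generate_sad(SadSpec(*spec))


class TestSampleAssemblage:
    def test_degenerate_distribution(self):
        np.testing.assert_array_equal(sample_assemblage([1.0, 0, 0], 100, 0), [100, 0, 0])

    def test_seed_reproducibility(self):
        p = generate_sad(SadSpec("lognormal", 20, 1.0))
        a = sample_assemblage(p, 500, seed=42)
        b = sample_assemblage(p, 500, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_uniform_counts_near_expectation(self):
        counts = sample_assemblage([0.25] * 4, 10_000, seed=3)
        sd = np.sqrt(10_000 * 0.25 * 0.75)
        assert (np.abs(counts - 2500) < 5 * sd).all()
        assert counts.sum() == 10_000

    def test_bad_probs_raise(self):
        with pytest.raises(ValueError):
            sample_assemblage([0.5, 0.3], 10, 0)


class TestDeriveRna:
    def test_zero_removal_is_identity(self):
        dna = np.array([5, 0, 3, 2])
        np.testing.assert_array_equal(derive_rna(dna, 0, 0), dna)

    def test_total_removal(self):
        np.testing.assert_array_equal(derive_rna(np.array([5, 3, 2]), 3, 0), [0, 0, 0])

    def test_survivors_keep_dna_counts(self, rng):
        dna = rng.integers(1, 50, size=10)
        rna = derive_rna(dna, 4, seed=9)
        assert (rna > 0).sum() == 6
        kept = rna > 0
        np.testing.assert_array_equal(rna[kept], dna[kept])

    def test_removal_exceeding_nonzero_raises(self):
        with pytest.raises(ValueError):
            derive_rna(np.array([1, 0, 2]), 3, 0)


class TestMockExperiment:
    def test_grid_sample_count(self):
        scenarios = default_mock_grid(removal_levels=(0, 5, 10), n_sites=5)
        table = simulate_mock_experiment(scenarios, seed=0)
        # 4 families x 3 levels x 5 sites, DNA + RNA each
        assert len(table.sample_ids) == 120
        assert len(table.pairs()) == 60

    def test_each_pair_has_one_dna_one_rna(self):
        table = simulate_mock_experiment(default_mock_grid(n_sites=2), seed=0)
        for _, grp in table.metadata.groupby("pair_id"):
            assert sorted(grp["nucleic_acid"]) == ["DNA", "RNA"]

    def test_depth_conservation(self):
        sc = default_mock_grid(removal_levels=(0, 5), n_sites=3, depth=800)
        table = simulate_mock_experiment(sc, seed=1)
        dna_cols = table.metadata.index[table.metadata["nucleic_acid"] == "DNA"]
        assert (table.counts[list(dna_cols)].sum(axis=0) == 800).all()
        rna_cols = table.metadata.index[table.metadata["nucleic_acid"] == "RNA"]
        assert (table.counts[list(rna_cols)].sum(axis=0) <= 800).all()

    def test_bit_identical_under_seed(self):
        a = simulate_mock_experiment(default_mock_grid(n_sites=2), seed=5)
        b = simulate_mock_experiment(default_mock_grid(n_sites=2), seed=5)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_empty_scenario_list_raises(self):
        with pytest.raises(ValueError):
            simulate_mock_experiment([])

    def test_removal_must_stay_below_richness(self):
        with pytest.raises(ValueError):
            MockScenario(sad=SadSpec("geometric", 10, 0.8), n_remove=10)


class TestContinuum:
    def test_zero_recruitment_single_origin(self):
        sc = ContinuumScenario(recruitment_rate=0.0, source_pool_size=50, depth=2000, seed=0)
        _, truth = simulate_continuum(sc)
        assert (truth.origin == sc.habitat_order[0]).all()

    def test_bit_identical_under_seed(self):
        sc = ContinuumScenario(source_pool_size=50, depth=2000, seed=11)
        a, _ = simulate_continuum(sc)
        b, _ = simulate_continuum(sc)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_default_seasons_differ_in_carryover(self):
        sc = ContinuumScenario()
        assert len(set(sc.carryover_unreactive_frac)) > 1

    def test_depth_conservation(self):
        sc = ContinuumScenario(source_pool_size=50, depth=3000, seed=2)
        table, _ = simulate_continuum(sc)
        assert (table.counts.sum(axis=0) == 3000).all()

    def test_truth_covers_available_otus(self):
        sc = ContinuumScenario(source_pool_size=40, depth=2000, seed=3)
        table, truth = simulate_continuum(sc)
        # soil-origin OTUs are available in every stratum
        n_strata = len(sc.habitat_order) * len(sc.seasons)
        soil_otus = truth.origin[truth.origin == "soil"].index
        counts = truth.reactivity.groupby("otu_id").size()
        assert (counts.loc[soil_otus] == n_strata).all()

    @pytest.mark.parametrize("bad", [{"recruitment_rate": 1.5}, {"carryover_unreactive_frac": (0.5, -0.1)}])
    def test_invalid_rates_raise(self, bad):
        with pytest.raises(ValueError):
            ContinuumScenario(**bad)

    def test_duplicate_habitats_raise(self):
        with pytest.raises(ValueError):
            ContinuumScenario(habitat_order=("soil", "soil"))
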