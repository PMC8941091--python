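"""Phantom correction, stratum singleton filtering, CSS, rarefaction."""

import numpy as np
import pandas as pd
import pytest

from reactscape import (
    CountTable,
    correct_phantoms,
    css_normalize,
    filter_combination_singletons,
    make_metadata,
    rarefy,
)

from .conftest import build_table


class TestCorrectPhantoms:
    def test_phantom_promoted_to_one(self, paired_table):
        out = correct_phantoms(paired_table)
        assert out.counts.loc["otu3", "p2_DNA"] == 1  # RNA=4, DNA was 0

    def test_non_phantoms_untouched(self, paired_table):
        out = correct_phantoms(paired_table)
        # DNA>0 stays as-is even when RNA differs; double zeros stay zero
        assert out.counts.loc["otu0", "p1_DNA"] == 10
        assert out.counts.loc["otu3", "p1_DNA"] == 0
        assert out.counts.loc["otu1", "p1_DNA"] == 5  # RNA=0 does not touch DNA

    def test_never_decreases_dna(self, paired_table):
        out = correct_phantoms(paired_table)
        dna_cols = [s for s in paired_table.sample_ids if s.endswith("_DNA")]
        assert (out.counts[dna_cols] >= paired_table.counts[dna_cols]).all().all()
        changed = out.counts[dna_cols] != paired_table.counts[dna_cols]
        assert (out.counts[dna_cols][changed].fillna(1) == 1).all().all()


def _stratum_table():
    """5 soil/spring DNA samples; otu0 singleton w/ 6 reads, otu1 singleton
    w/ 10 reads, otu2 present twice with 3 reads each, otu3 common."""
    counts = pd.DataFrame(
        {
            "s1": [6, 0, 3, 20],
            "s2": [0, 10, 3, 25],
            "s3": [0, 0, 0, 30],
            "s4": [0, 0, 0, 15],
            "s5": [0, 0, 0, 18],
        },
        index=["otu0", "otu1", "otu2", "otu3"],
    )
    meta = make_metadata(list(counts.columns), "soil", "spring", "DNA", "")
    return CountTable(counts, meta)


class TestSingletonFilter:
    def test_low_count_singleton_removed(self):
        out, report = filter_combination_singletons(_stratum_table())
        assert out.counts.loc["otu0", "s1"] == 0
        assert len(report) == 1
        assert report.removed.iloc[0]["otu_id"] == "otu0"
        assert report.removed.iloc[0]["count"] == 6

    def test_boundary_ten_reads_kept(self):
        out, _ = filter_combination_singletons(_stratum_table())
        assert out.counts.loc["otu1", "s2"] == 10

    def test_doubleton_kept(self):
        out, _ = filter_combination_singletons(_stratum_table())
        assert out.counts.loc["otu2", "s1"] == 3
        assert out.counts.loc["otu2", "s2"] == 3

    def test_idempotent(self):
        once, _ = filter_combination_singletons(_stratum_table())
        twice, report = filter_combination_singletons(once)
        pd.testing.assert_frame_equal(once.counts, twice.counts)
        assert len(report) == 0

    def test_strata_are_independent(self):
        # same OTU a singleton in two different strata: both removed
        counts = pd.DataFrame({"a": [4, 9], "b": [0, 8], "c": [5, 7], "d": [0, 11]},
                              index=["otuA", "otuB"])
        meta = make_metadata(
            ["a", "b", "c", "d"],
            ["soil", "soil", "stream", "stream"],
            "spring",
            "DNA",
            "",
        )
        out, report = filter_combination_singletons(CountTable(counts, meta))
        assert out.counts.loc["otuA"].tolist() == [0, 0, 0, 0]
        assert len(report) == 2


class TestCssNormalize:
    def test_worked_example(self):
        t = build_table({"s_DNA": [1, 2, 3, 10]}, paired=False)
        norm = css_normalize(t, quantile=0.5, scale_constant=1000)
        np.testing.assert_allclose(
            norm.values["s_DNA"], [1000 / 3, 2000 / 3, 1000.0, 10000 / 3]
        )
        assert norm.scaling_factors["s_DNA"] == 3

    def test_all_equal_counts(self):
        t = build_table({"s_DNA": [5, 5, 5, 5]}, paired=False)
        norm = css_normalize(t, quantile=0.5)
        np.testing.assert_allclose(norm.values["s_DNA"], [250.0] * 4)

    def test_single_otu_self_scaling(self):
        t = build_table({"s_DNA": [7]}, paired=False)
        norm = css_normalize(t, quantile=0.5, scale_constant=1000)
        assert norm.values.iloc[0, 0] == 1000.0

    def test_zeros_preserved(self, paired_table):
        norm = css_normalize(paired_table)
        assert ((norm.values.to_numpy() == 0) == (paired_table.counts.to_numpy() == 0)).all()

    def test_scale_equivariance_on_duplicated_counts(self):
        base = [1, 1, 2, 2, 3, 3, 8, 8]
        a = css_normalize(build_table({"s_DNA": base}, paired=False), quantile=0.5)
        b = css_normalize(
            build_table({"s_DNA": [5 * x for x in base]}, paired=False), quantile=0.5
        )
        np.testing.assert_allclose(a.values.to_numpy(), b.values.to_numpy())

    def test_all_zero_sample_raises(self):
        with pytest.raises(ValueError):
            css_normalize(build_table({"s_DNA": [0, 0]}, paired=False))

    def test_bad_quantile_raises(self, paired_table):
        with pytest.raises(ValueError):
            css_normalize(paired_table, quantile=1.5)

    def test_adaptive_quantile_runs(self, paired_table):
        norm = css_normalize(paired_table, quantile=None)
        assert (norm.scaling_factors > 0).all()


class TestRarefy:
    def test_exact_depth_sample_unchanged(self, paired_table):
        depth = int(paired_table.counts["p1_DNA"].sum())
        out, dropped = rarefy(paired_table, depth, seed=0)
        np.testing.assert_array_equal(out.counts["p1_DNA"], paired_table.counts["p1_DNA"])

    def test_single_nonzero_otu(self):
        t = build_table({"s_DNA": [10, 0, 0]}, paired=False)
        out, _ = rarefy(t, 5, seed=0)
        np.testing.assert_array_equal(out.counts["s_DNA"], [5, 0, 0])

    def test_column_sums_equal_depth_and_short_samples_dropped(self, rng):
        counts = pd.DataFrame(rng.integers(0, 60, size=(30, 6)),
                              index=[f"otu{i}" for i in range(30)],
                              columns=[f"s{i}" for i in range(6)])
        counts["s5"] = 0
        counts.loc["otu0", "s5"] = 3  # library of 3 reads, below depth
        meta = make_metadata(list(counts.columns), "soil", "spring", "DNA", "")
        out, dropped = rarefy(CountTable(counts, meta), 100, seed=1)
        assert dropped == ["s5"]
        assert (out.counts.sum(axis=0) == 100).all()
        assert (out.counts.to_numpy() <= counts[out.sample_ids].to_numpy()).all()

    def test_reproducible(self, paired_table):
        a, _ = rarefy(paired_table, 8, seed=4)
        b, _ = rarefy(paired_table, 8, seed=4)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_depth_above_all_libraries_raises(self, paired_table):
        with pytest.raises(ValueError):
            rarefy(paired_table, 10_000)
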