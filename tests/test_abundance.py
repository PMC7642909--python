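"""Tests for coverage, masking, normalization and aggregation."""

import numpy as np
import pandas as pd
import pytest

from mlivirome import abundance as ab


@pytest.fixture
def coverage_table():
    return pd.DataFrame(
        {
            "contig_id": ["c1", "c1", "c2", "c2"],
            "sample_id": ["s1", "s2", "s1", "s2"],
            "length_bp": [1000, 1000, 2000, 2000],
            "mapped_reads": [10, 5, 0, 100],
            "covered_positions": [750, 0, 0, 2000],
        }
    )


class TestBreadth:
    def test_breadth_ratio(self, coverage_table):
        b = ab.breadth_from_coverage(coverage_table)
        assert b.loc["c1", "s1"] == 0.75
        assert b.loc["c1", "s2"] == 0.0
        assert b.loc["c2", "s2"] == 1.0

    def test_depth_table_interval_union(self):
        """Positions 1..500 plus 400..800 on a 1000 bp contig: 800 covered."""
        rows = [("c1", "s1", p, 1) for p in range(1, 501)]
        rows += [("c1", "s1", p, 2) for p in range(400, 801)]
        depth = pd.DataFrame(rows, columns=["contig_id", "sample_id", "position", "depth"])
        b = ab.breadth_from_depth(depth, pd.Series({"c1": 1000}))
        assert b.loc["c1", "s1"] == 0.8

    def test_zero_depth_positions_not_covered(self):
        depth = pd.DataFrame(
            {"contig_id": ["c1"] * 3, "sample_id": ["s1"] * 3,
             "position": [1, 2, 3], "depth": [1, 0, 2]}
        )
        b = ab.breadth_from_depth(depth, pd.Series({"c1": 10}))
        assert b.loc["c1", "s1"] == 0.2

    def test_breadth_invariant_to_row_permutation(self, coverage_table):
        shuffled = coverage_table.sample(frac=1, random_state=0)
        pd.testing.assert_frame_equal(
            ab.breadth_from_coverage(coverage_table), ab.breadth_from_coverage(shuffled)
        )

    def test_invalid_coverage_rejected(self, coverage_table):
        bad = coverage_table.copy()
        bad.loc[0, "covered_positions"] = 2000
        with pytest.raises(ValueError):
            ab.breadth_from_coverage(bad)


class TestBreadthMask:
    def test_threshold_boundary_inclusive(self):
        counts = pd.DataFrame({"s1": [10, 20]}, index=["a", "b"])
        breadth = pd.DataFrame({"s1": [0.75, 0.7499]}, index=["a", "b"])
        masked = ab.apply_breadth_mask(counts, breadth)
        assert masked.loc["a", "s1"] == 10
        assert masked.loc["b", "s1"] == 0

    def test_full_breadth_is_identity(self):
        counts = pd.DataFrame(np.arange(6).reshape(3, 2), index=list("abc"), columns=["s1", "s2"])
        breadth = pd.DataFrame(1.0, index=counts.index, columns=counts.columns)
        pd.testing.assert_frame_equal(ab.apply_breadth_mask(counts, breadth), counts)

    def test_per_sample_masking(self):
        """One sub-threshold cell in a 3x2 matrix zeroes exactly that entry."""
        counts = pd.DataFrame({"s1": [1, 2, 3], "s2": [4, 5, 6]}, index=list("abc"))
        breadth = pd.DataFrame({"s1": [1.0, 0.5, 1.0], "s2": [1.0, 1.0, 1.0]}, index=list("abc"))
        masked = ab.apply_breadth_mask(counts, breadth)
        assert masked.loc["b", "s1"] == 0
        assert (masked.drop(index="b") == counts.drop(index="b")).all().all()
        assert masked.loc["b", "s2"] == 5

    def test_mask_never_increases(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 100, (20, 5)))
        breadth = pd.DataFrame(rng.random((20, 5)))
        assert (ab.apply_breadth_mask(counts, breadth) <= counts).all().all()


class TestRpkm:
    @pytest.mark.parametrize(
        "count,length,lib,expected",
        [(10, 1000, 10**6, 10.0), (4, 2000, 2 * 10**6, 1.0), (0, 1500, 10**6, 0.0)],
    )
    def test_closed_form(self, count, length, lib, expected):
        counts = pd.DataFrame({"s1": [count]}, index=["c"])
        out = ab.rpkm_normalize(counts, pd.Series({"c": length}), pd.Series({"s1": lib}))
        assert out.loc["c", "s1"] == pytest.approx(expected)

    def test_invariant_to_joint_doubling(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(0, 50, (10, 3)), columns=list("xyz"))
        lengths = pd.Series(rng.integers(1000, 9000, 10), index=counts.index)
        lib = counts.sum(axis=0)
        a = ab.rpkm_normalize(counts, lengths, lib)
        b = ab.rpkm_normalize(counts * 2, lengths, lib * 2)
        pd.testing.assert_frame_equal(a, b)


class TestPrevalenceFilter:
    def test_boundary_inclusive(self):
        """A feature at exactly 0.01% relative abundance in one sample is kept."""
        m = pd.DataFrame({"s1": [1.0, 9999.0], "s2": [0.0, 100.0]}, index=["low", "high"])
        out = ab.prevalence_filter(m)
        assert "low" in out.index  # 1/10000 == 1e-4 exactly

    def test_sub_threshold_everywhere_dropped(self):
        m = pd.DataFrame({"s1": [0.5, 9999.5], "s2": [0.4, 7999.6]}, index=["low", "high"])
        out = ab.prevalence_filter(m)
        assert list(out.index) == ["high"]

    def test_empty_matrix(self):
        m = pd.DataFrame()
        assert ab.prevalence_filter(m).empty


class TestRarefy:
    def test_depth_equal_to_total_is_identity(self):
        counts = pd.DataFrame({"s1": [30, 20], "s2": [5, 10]}, index=["a", "b"])
        out = ab.rarefy(counts, depth=15, seed=0)
        pd.testing.assert_frame_equal(out["s2"].to_frame(), counts["s2"].to_frame())

    def test_single_feature_mass(self):
        counts = pd.DataFrame({"s1": [100, 0]}, index=["a", "b"])
        out = ab.rarefy(counts, depth=50, seed=0)
        assert out.loc["a", "s1"] == 50 and out.loc["b", "s1"] == 0

    def test_columns_sum_to_min(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.integers(0, 200, (30, 4)))
        out = ab.rarefy(counts, "min", seed=1)
        assert (out.sum(axis=0) == counts.sum(axis=0).min()).all()

    def test_hypergeometric_expectation(self):
        counts = pd.DataFrame({"s1": [500, 500]}, index=["a", "b"])
        firsts = [ab.rarefy(counts, 100, seed=s).loc["a", "s1"] for s in range(200)]
        sd = np.sqrt(100 * 0.5 * 0.5 * (1000 - 100) / 999)
        assert abs(np.mean(firsts) - 50) < 3 * sd / np.sqrt(200)

    def test_shallow_sample_rejected(self):
        counts = pd.DataFrame({"s1": [5], "s2": [100]}, index=["a"])
        with pytest.raises(ValueError, match="shallower"):
            ab.rarefy(counts, depth=50, seed=0)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.integers(0, 100, (10, 3)))
        pd.testing.assert_frame_equal(ab.rarefy(counts, "min", 7), ab.rarefy(counts, "min", 7))


class TestClusterAggregation:
    def test_identity_membership(self):
        m = pd.DataFrame({"s1": [3, 4]}, index=["a", "b"])
        out = ab.aggregate_by_cluster(m, pd.Series({"a": "a", "b": "b"}))
        assert out.loc["a", "s1"] == 3 and out.loc["b", "s1"] == 4

    def test_two_member_cluster(self):
        m = pd.DataFrame({"s1": [3, 4]}, index=["a", "b"])
        out = ab.aggregate_by_cluster(m, pd.Series({"a": "c1", "b": "c1"}))
        assert out.loc["c1", "s1"] == 7

    def test_unclustered_become_singletons_and_totals_conserved(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.integers(0, 20, (50, 4)), index=[f"f{i}" for i in range(50)])
        membership = pd.Series({f"f{i}": f"cl{i % 7}" for i in range(25)})
        out = ab.aggregate_by_cluster(m, membership)
        np.testing.assert_array_equal(out.sum(axis=0), m.sum(axis=0))
        assert "f40" in out.index


class TestSharedness:
    @pytest.fixture
    def meta(self):
        return pd.DataFrame(
            {
                "sample_id": ["A-PC", "A-DC", "B-PC", "B-DC"],
                "subject": ["A", "A", "B", "B"],
                "site": ["PC", "DC", "PC", "DC"],
            }
        )

    def test_caption_taxonomy(self, meta):
        presence = pd.DataFrame(
            {
                "A-PC": [True, True, True, False],
                "A-DC": [False, True, False, False],
                "B-PC": [False, False, True, False],
                "B-DC": [False, False, False, False],
            },
            index=["only_apc", "a_both_sites", "two_subjects", "absent"],
        )
        labels = ab.classify_sharedness(presence, meta)
        assert labels["only_apc"] == "sample_specific"
        assert labels["a_both_sites"] == "subject_specific"
        assert labels["two_subjects"] == "shared"
        assert pd.isna(labels["absent"])

    def test_labels_partition_present_vcs(self, meta):
        rng = np.random.default_rng(5)
        presence = pd.DataFrame(
            rng.random((40, 4)) < 0.4, columns=meta["sample_id"], index=range(40)
        )
        labels = ab.classify_sharedness(presence, meta)
        present = presence.any(axis=1)
        assert labels[present].notna().all()
        assert labels[~present].isna().all()


class TestContaminationFold:
    def test_simple_fold(self):
        folds, mean = ab.contamination_fold(0.5, 0.005)
        assert folds[0] == pytest.approx(100.0)

    def test_identity(self):
        folds, mean = ab.contamination_fold([0.3], [0.3])
        assert mean == pytest.approx(1.0)

    def test_mean_of_folds_not_fold_of_means(self):
        folds, mean = ab.contamination_fold([0.1, 0.1], [0.01, 0.0001])
        np.testing.assert_allclose(folds, [10.0, 1000.0])
        assert mean == pytest.approx(505.0)

    def test_zero_virome_proportion_flagged_infinite(self):
        folds, mean = ab.contamination_fold([0.1, 0.2], [0.0, 0.1])
        assert np.isinf(folds[0])
        assert mean == pytest.approx(2.0)  # mean over finite folds
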