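import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import tfannot as tf
from tfannot.expression import (
    ExpressionCall,
    ExpressionMatrix,
    call_expressed,
    conserved_preference,
    expressed_by_tissue,
    preferential_fold,
    preferential_zscore,
    quantile_normalize,
)
from tfannot.orthology import OrthologPair


def matrix(values, samples, groups, platform="rnaseq", datasets=None):
    df = pd.DataFrame(values, columns=samples)
    df.index = [f"g{i}" for i in range(len(df))]
    return ExpressionMatrix(df, platform, dict(zip(samples, groups)), datasets=datasets)


class TestQuantileNormalize:
    def test_hand_computed_two_by_two(self):
        """s1=[5,1], s2=[2,4] → rank means [1.5, 4.5] → s1=[4.5,1.5], s2=[1.5,4.5]."""
        m = matrix([[5, 2], [1, 4]], ["s1", "s2"], ["a", "b"])
        out = quantile_normalize(m).values
        assert out["s1"].tolist() == [4.5, 1.5]
        assert out["s2"].tolist() == [1.5, 4.5]

    def test_identical_columns_fixed_point(self):
        m = matrix([[3, 3], [7, 7], [1, 1]], ["s1", "s2"], ["a", "b"])
        out = quantile_normalize(m).values
        pd.testing.assert_frame_equal(out, m.values, check_dtype=False)

    def test_single_sample_unchanged_with_warning(self):
        m = matrix([[3], [7]], ["s1"], ["a"])
        with pytest.warns(UserWarning):
            out = quantile_normalize(m)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_per_dataset_units_normalized_independently(self):
        m = matrix(
            [[5, 2, 100], [1, 4, 50]],
            ["s1", "s2", "s3"],
            ["a", "a", "b"],
            datasets={"s1": "d1", "s2": "d1", "s3": "d2"},
        )
        out = quantile_normalize(m).values
        # d1 columns normalized together, d2's single column untouched
        assert sorted(out["s1"]) == sorted(out["s2"]) == [1.5, 4.5]
        assert out["s3"].tolist() == [100, 50]

    @settings(derandomize=True, max_examples=40)
    @given(
        n_rows=st.integers(2, 12),
        n_cols=st.integers(2, 6),
        data=st.data(),
    )
    def test_columns_share_multiset_and_idempotent(self, n_rows, n_cols, data):
        # the defining multiset property (and exact idempotence) holds for
        # tie-free columns; ties receive rank-average values instead
        flat = data.draw(
            st.lists(
                st.floats(0, 1e4, allow_nan=False),
                min_size=n_rows * n_cols,
                max_size=n_rows * n_cols,
                unique=True,
            )
        )
        X = np.array(flat).reshape(n_rows, n_cols)
        samples = [f"s{j}" for j in range(X.shape[1])]
        m = matrix(X, samples, ["t"] * len(samples))
        out = quantile_normalize(m)
        sorted_cols = np.sort(out.values.to_numpy(), axis=0)
        for j in range(1, X.shape[1]):
            np.testing.assert_allclose(sorted_cols[:, j], sorted_cols[:, 0])
        again = quantile_normalize(out)
        np.testing.assert_allclose(
            again.values.to_numpy(), out.values.to_numpy(), rtol=1e-9, atol=1e-9
        )

    def test_ties_get_rank_average_target(self):
        # s1 has a tie at ranks 1-2 → both entries get the mean of the
        # first two target values
        m = matrix([[1.0, 10.0], [1.0, 20.0], [5.0, 30.0]], ["s1", "s2"], ["a", "b"])
        out = quantile_normalize(m).values
        target = np.sort(m.values.to_numpy(), axis=0).mean(axis=1)  # [5.5, 10.5, 17.5]
        assert out["s1"].tolist() == [
            pytest.approx((target[0] + target[1]) / 2),
            pytest.approx((target[0] + target[1]) / 2),
            pytest.approx(target[2]),
        ]


class TestCallExpressed:
    def test_fpkm_threshold_inclusive(self):
        m = matrix([[0.2, 1.0, 0.5], [0.99, 0.99, 0.99]], ["s1", "s2", "s3"], list("abc"))
        flags = call_expressed(m)
        assert flags.tolist() == [True, False]

    def test_microarray_threshold(self):
        m = matrix([[7.65, 5.0], [7.64, 7.0]], ["s1", "s2"], list("ab"), platform="microarray")
        assert call_expressed(m).tolist() == [True, False]

    def test_invalid_platform_rejected(self):
        with pytest.raises(ValueError, match="platform"):
            matrix([[1.0]], ["s1"], ["a"], platform="nanostring")


class TestZscoreRule:
    def test_single_outlier_sample_drives_its_group_only(self):
        # 29 samples at 1.0, one at 50.0 → z of the outlier ≫ 3
        values = np.ones((1, 30))
        values[0, -1] = 50.0
        samples = [f"s{j}" for j in range(30)]
        groups = ["other"] * 29 + ["target"]
        calls = preferential_zscore(matrix(values, samples, groups))
        assert calls[0].preferred_tissues == frozenset({"target"})
        # direct z computation agrees
        z = (50.0 - values.mean()) / values.std(ddof=1)
        assert z > 3

    def test_constant_gene_gets_no_preference(self):
        m = matrix(np.full((1, 6), 2.0), [f"s{j}" for j in range(6)], ["a"] * 3 + ["b"] * 3)
        calls = preferential_zscore(m)
        assert calls[0].preferred_tissues == frozenset()

    def test_mild_noise_below_threshold_gives_no_calls(self):
        rng = np.random.default_rng(0)
        X = 5.0 * rng.uniform(0.7, 1.3, size=(40, 30))
        samples = [f"s{j}" for j in range(30)]
        groups = [f"t{j % 6}" for j in range(30)]
        calls = preferential_zscore(matrix(X, samples, groups))
        flagged = [c for c in calls if c.preferred_tissues]
        # verify against brute-force z computation
        z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=1, keepdims=True)
        assert (z < 3).all()
        assert flagged == []

    def test_too_few_samples_error(self):
        m = matrix([[1.0, 2.0]], ["s1", "s2"], ["a", "b"])
        with pytest.raises(ValueError, match="3 samples"):
            preferential_zscore(m)

    def test_scaling_invariance_of_pattern(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(1, 2, size=(5, 12))
        X[0, :2] *= 30
        samples = [f"s{j}" for j in range(12)]
        groups = ["a"] * 2 + ["b"] * 10
        base = preferential_zscore(matrix(X, samples, groups))
        scaled = preferential_zscore(matrix(X * 7.0, samples, groups))
        assert [c.preferred_tissues for c in base] == [
            c.preferred_tissues for c in scaled
        ]


class TestFoldRule:
    def samples(self, tissues):
        return [f"{t}_s1" for t in tissues]

    def test_double_every_other_tissue_flags(self):
        tissues = ["leaf", "root", "stem", "tassel"]
        m = matrix([[10, 4, 3, 1]], self.samples(tissues), tissues)
        calls = preferential_fold(m)
        assert calls[0].preferred_tissues == frozenset({"leaf"})

    def test_less_than_double_not_flagged(self):
        tissues = ["leaf", "root", "stem", "tassel"]
        m = matrix([[10, 6, 3, 1]], self.samples(tissues), tissues)
        assert preferential_fold(m)[0].preferred_tissues == frozenset()

    def test_exactly_double_is_strict(self):
        tissues = ["a", "b", "c", "d"]
        m = matrix([[4, 2, 2, 2]], self.samples(tissues), tissues)
        assert preferential_fold(m)[0].preferred_tissues == frozenset()

    def test_scale_invariance(self):
        tissues = ["a", "b", "c"]
        m1 = matrix([[10, 4, 3]], self.samples(tissues), tissues)
        m2 = matrix([[10 * 3.7, 4 * 3.7, 3 * 3.7]], self.samples(tissues), tissues)
        assert (
            preferential_fold(m1)[0].preferred_tissues
            == preferential_fold(m2)[0].preferred_tissues
        )

    def test_requires_one_value_per_tissue(self):
        m = matrix([[1, 2, 3]], ["s1", "s2", "s3"], ["a", "a", "b"])
        with pytest.raises(ValueError, match="exactly one"):
            preferential_fold(m)

    def test_fewer_than_two_tissues_error(self):
        m = matrix([[5]], ["s1"], ["a"])
        with pytest.raises(ValueError, match="2 tissues"):
            preferential_fold(m)


class TestConservedPreference:
    def mk(self, gene, tissues, rule="zscore"):
        return ExpressionCall(gene, True, frozenset(tissues), rule)

    def test_leaf_merge_across_species(self):
        """Embryonic leaf (species A) and leaf (species B) share the label Leaf."""
        pairs = [OrthologPair("zm1", "si1")]
        out = conserved_preference(
            pairs,
            [self.mk("zm1", ["embryonic_leaf"])],
            [self.mk("si1", ["leaf"], rule="fold")],
            {"embryonic_leaf": "Leaf", "mature_leaf": "Leaf", "root": "Root"},
            {"leaf": "Leaf", "root": "Root"},
        )
        assert out == [("zm1", "si1", "Leaf")]

    def test_different_tissues_not_conserved(self):
        pairs = [OrthologPair("zm1", "si1")]
        out = conserved_preference(
            pairs,
            [self.mk("zm1", ["root"])],
            [self.mk("si1", ["tassel"], rule="fold")],
            {"root": "Root", "tassel": "Tassel"},
            {"root": "Root", "tassel": "Tassel"},
        )
        assert out == []

    def test_non_reciprocal_pair_excluded(self):
        pairs = [OrthologPair("zm1", "si1", reciprocal=False)]
        out = conserved_preference(
            pairs,
            [self.mk("zm1", ["root"])],
            [self.mk("si1", ["root"], rule="fold")],
            {"root": "Root"},
            {"root": "Root"},
        )
        assert out == []

    def test_unmapped_group_errors(self):
        pairs = [OrthologPair("zm1", "si1")]
        with pytest.raises(KeyError, match="shoot"):
            conserved_preference(
                pairs,
                [self.mk("zm1", ["shoot"])],
                [self.mk("si1", ["root"], rule="fold")],
                {"root": "Root"},
                {"root": "Root"},
            )


class TestTissueExpressionFlags:
    def test_flag_requires_threshold_in_group_sample(self):
        m = matrix(
            [[2.0, 0.5, 0.2], [0.5, 0.5, 3.0]],
            ["a_s1", "a_s2", "b_s1"],
            ["a", "a", "b"],
        )
        flags = expressed_by_tissue(m)
        assert flags.loc["g0"].tolist() == [True, False]
        assert flags.loc["g1"].tolist() == [False, True]


class TestExpressionCallInvariant:
    def test_preferential_implies_expressed(self):
        with pytest.raises(ValueError):
            ExpressionCall("g", False, frozenset({"root"}), "zscore")
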