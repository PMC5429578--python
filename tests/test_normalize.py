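import subprocess
import textwrap

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from epinorm import (
    ChromSizes,
    DegenerateSampleError,
    make_bins,
    quantile_normalize,
    select_enriched_bins,
    zscore_scale,
)
from epinorm.rci import RCIMatrix

from conftest import naive_quantile_normalize


def as_matrix(values, names=None):
    values = np.asarray(values)
    scheme = make_bins(ChromSizes({"chr1": values.shape[0] * 200}), 200)
    names = names or [f"s{j}" for j in range(values.shape[1])]
    return RCIMatrix(values=values, sample_names=names, bin_scheme=scheme, stage="raw")


count_matrices = arrays(
    dtype=np.int64,
    shape=st.tuples(st.integers(2, 50), st.integers(2, 5)),
    elements=st.integers(0, 20),  # small integers: ties everywhere, zeros dominant
)


class TestQuantileNormalize:
    def test_hand_worked_two_columns(self):
        q = quantile_normalize(as_matrix([[2, 3], [4, 6], [6, 9]]))
        expected = np.array([[2.5, 2.5], [5.0, 5.0], [7.5, 7.5]])
        np.testing.assert_allclose(q.norm_matrix.values, expected)
        np.testing.assert_allclose(q.reference_distribution, [2.5, 5.0, 7.5])

    def test_identical_columns_are_a_fixed_point(self):
        values = np.array([[3, 3], [0, 0], [7, 7], [3, 3]])
        q = quantile_normalize(as_matrix(values))
        np.testing.assert_allclose(q.norm_matrix.values, values)

    def test_tied_values_get_mean_of_reference_span(self):
        # zeros occupy tied ranks 1-2; reference is [0.5, 1.0, 4.0]
        q = quantile_normalize(as_matrix([[0, 1], [0, 2], [5, 3]]))
        np.testing.assert_allclose(q.norm_matrix.values[:, 0], [0.75, 0.75, 4.0])
        np.testing.assert_allclose(q.norm_matrix.values[:, 1], [0.5, 1.0, 4.0])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            quantile_normalize(as_matrix([[1, 2], [-1, 0]]))

    def test_matches_limma_reference_implementation(self, tmp_path):
        """Cross-check against Bioconductor limma's normalizeQuantiles(ties=TRUE)."""
        rng = np.random.default_rng(0)
        X = rng.integers(0, 12, size=(8, 3))
        q = quantile_normalize(as_matrix(X))
        infile, outfile = tmp_path / "in.txt", tmp_path / "out.txt"
        np.savetxt(infile, X, fmt="%d")
        script = textwrap.dedent(f"""
            suppressMessages(library(limma))
            x <- as.matrix(read.table("{infile}"))
            y <- normalizeQuantiles(x, ties=TRUE)
            write.table(y, "{outfile}", row.names=FALSE, col.names=FALSE)
        """)
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        expected = np.loadtxt(outfile)
        np.testing.assert_allclose(q.norm_matrix.values, expected, atol=1e-9)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(count_matrices)
    def test_matches_naive_oracle(self, X):
        q = quantile_normalize(as_matrix(X))
        np.testing.assert_allclose(q.norm_matrix.values, naive_quantile_normalize(X), atol=1e-9)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(count_matrices)
    def test_equalization_rank_preservation_and_conservation(self, X):
        q = quantile_normalize(as_matrix(X))
        norm = q.norm_matrix.values
        ref = q.reference_distribution
        # every sorted column equals the shared reference up to tie-averaging:
        # each tied span of raw values carries the mean of the reference there
        for j in range(norm.shape[1]):
            order = np.argsort(X[:, j], kind="stable")
            expected = ref.copy()
            uniq, inverse = np.unique(X[order, j], return_inverse=True)
            for g in range(len(uniq)):
                span = inverse == g
                expected[span] = ref[span].mean()
            np.testing.assert_allclose(norm[order, j], expected, atol=1e-9)
        # monotone within columns (ties allowed)
        for j in range(norm.shape[1]):
            order = np.argsort(X[:, j], kind="stable")
            assert (np.diff(norm[order, j]) >= -1e-12).all()
        # each normalized column sums to the mean of the raw column sums
        np.testing.assert_allclose(
            norm.sum(axis=0),
            np.full(norm.shape[1], X.sum(axis=1).sum() / norm.shape[1]),
            rtol=1e-6,
        )

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(2, 40), st.integers(2, 5), st.integers(0, 10_000))
    def test_idempotent_on_tie_free_matrices(self, B, N, seed):
        # a second pass re-averages tie spans against a new reference, so
        # idempotence is a tie-free property; rank permutations are tie-free
        X = np.argsort(np.random.default_rng(seed).random((B, N)), axis=0)
        q1 = quantile_normalize(as_matrix(X))
        q2 = quantile_normalize(
            RCIMatrix(
                values=q1.norm_matrix.values,
                sample_names=q1.norm_matrix.sample_names,
                bin_scheme=q1.norm_matrix.bin_scheme,
                stage="raw",
            )
        )
        np.testing.assert_allclose(q2.norm_matrix.values, q1.norm_matrix.values, atol=1e-9)


class TestZScore:
    def test_hand_worked_column(self):
        z = zscore_scale(quantile_normalize(as_matrix([[2, 2], [5, 5], [8, 8]])))
        np.testing.assert_allclose(z.z_matrix.values[:, 0], [-1.22474487, 0.0, 1.22474487])
        np.testing.assert_allclose(z.sds, [np.sqrt(6.0), np.sqrt(6.0)])

    def test_columns_centered_and_unit_population_sd(self, trio_pipeline):
        z = zscore_scale(trio_pipeline["qres"])
        np.testing.assert_allclose(z.z_matrix.values.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.z_matrix.values.std(axis=0), 1.0, atol=1e-9)

    def test_identical_multisets_after_tie_free_normalization(self):
        rng = np.random.default_rng(1)
        X = np.argsort(rng.random((40, 3)), axis=0)  # permutations: no within-column ties
        z = zscore_scale(quantile_normalize(as_matrix(X)))
        cols = [np.sort(z.z_matrix.values[:, j]) for j in range(3)]
        np.testing.assert_allclose(cols[1], cols[0], atol=1e-12)
        np.testing.assert_allclose(cols[2], cols[0], atol=1e-12)

    def test_constant_column_raises_naming_sample(self):
        with pytest.raises(DegenerateSampleError, match="flat"):
            zscore_scale(as_matrix([[1, 2], [1, 4]], names=["flat", "ok"]))

    def test_invariant_to_positive_column_scaling(self):
        rng = np.random.default_rng(2)
        X = rng.integers(0, 30, size=(25, 2)).astype(float)
        base = zscore_scale(as_matrix(X))
        scaled = zscore_scale(as_matrix(X * np.array([7.3, 0.4])))
        np.testing.assert_allclose(scaled.z_matrix.values, base.z_matrix.values, atol=1e-9)


class TestEnrichedBinSelection:
    def test_threshold_is_strict_on_log2_fold(self):
        ip, ctrl = np.array([8.0]), np.array([1.0])
        # log2(9/2) ~ 2.17: selected at threshold 2, not at 3
        assert select_enriched_bins(ip, ctrl, 2, pseudocount=1).tolist() == [0]
        assert select_enriched_bins(ip, ctrl, 3, pseudocount=1).tolist() == []

    def test_equal_ip_and_input_never_selected_at_zero(self):
        v = np.array([0.0, 3.0, 10.0])
        assert select_enriched_bins(v, v, 0).size == 0

    def test_all_zero_empty_at_any_threshold(self):
        z = np.zeros(5)
        for thr in (0, 1, 4):
            assert select_enriched_bins(z, z, thr).size == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            select_enriched_bins(np.ones(3), np.ones(4), 1)
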