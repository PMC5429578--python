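import numpy as np
import pytest

from epinorm import (
    ChromSizes,
    RegionSet,
    average_profile,
    ma_transform,
    make_bins,
    region_count_matrix,
    render_plots,
    stratify_regions,
)
from epinorm.profiles_plots import DEFAULT_STRATA, RegionMatrix, profile_table
from epinorm.rci import RCIMatrix


def matrix_from(values, names, chrom_len=None, S=200):
    values = np.asarray(values, dtype=float)
    chrom_len = chrom_len or values.shape[0] * S
    scheme = make_bins(ChromSizes({"chr1": chrom_len}), S)
    return RCIMatrix(values=values, sample_names=names, bin_scheme=scheme, stage="raw")


class TestMATransform:
    def test_identical_samples_give_flat_zero(self):
        x = np.array([0, 2, 5, 9, 20], dtype=float)
        ma = ma_transform(x, x, 1.0)
        assert np.allclose(ma.M, 0) and np.allclose(ma.loess_M, 0, atol=1e-12)

    def test_hand_worked_point(self):
        ma = ma_transform(np.array([7.0]), np.array([1.0]), 1.0)
        assert ma.A[0] == pytest.approx(2.0) and ma.M[0] == pytest.approx(2.0)

    def test_doubled_sample_approaches_unit_log_ratio(self):
        x = np.linspace(100, 1000, 50)
        ma = ma_transform(2 * x, x, 1e-9)
        assert np.allclose(ma.M, 1.0, atol=1e-6)

    def test_antisymmetry_under_sample_swap(self):
        rng = np.random.default_rng(3)
        a, b = rng.integers(0, 50, 200).astype(float), rng.integers(0, 50, 200).astype(float)
        fwd, rev = ma_transform(a, b, 1.0), ma_transform(b, a, 1.0)
        np.testing.assert_allclose(fwd.M, -rev.M, atol=1e-12)
        np.testing.assert_allclose(fwd.A, rev.A, atol=1e-12)

    def test_invalid_pseudocount_and_length_rejected(self):
        with pytest.raises(ValueError, match="pseudocount"):
            ma_transform(np.ones(3), np.ones(3), 0.0)
        with pytest.raises(ValueError, match="mismatch"):
            ma_transform(np.ones(3), np.ones(4), 1.0)


class TestRegionCountMatrix:
    def test_tss_window_width_in_bins(self):
        mat = matrix_from(np.arange(40).reshape(20, 2), ["a", "b"], S=300)
        ann = RegionSet.from_tuples([("chr1", 3000, 4500, "g", "+")])
        rm = region_count_matrix(mat, ann, anchor="tss", flank_bp=1500)
        assert rm.per_sample["a"].shape == (1, 10)  # 2*1500/300
        assert rm.offsets.tolist() == [(-5 + i) * 300 for i in range(10)]

    def test_minus_strand_rows_are_flipped(self):
        values = np.zeros((30, 1))
        values[10] = 7.0  # one bin left of position 2200 anchor at S=200
        mat = matrix_from(values, ["s"])
        ann = RegionSet.from_tuples(
            [("chr1", 2200, 3000, "plus", "+"), ("chr1", 1400, 2200, "minus", "-")]
        )
        rm = region_count_matrix(mat, ann, anchor="tss", flank_bp=600)
        plus, minus = rm.per_sample["s"]
        # bin [2000,2200) is upstream of the + TSS (index 2 of 6) and on the
        # gene-body side of the - TSS, so flipping mirrors it across the anchor
        np.testing.assert_allclose(plus, [0, 0, 7, 0, 0, 0])
        np.testing.assert_allclose(minus, [0, 0, 0, 7, 0, 0])

    def test_regions_off_the_binned_genome_dropped(self):
        mat = matrix_from(np.zeros((10, 1)), ["s"])
        ann = RegionSet.from_tuples(
            [("chr1", 100, 500, "edge", "+"), ("chr1", 1000, 1500, "ok", "+")]
        )
        rm = region_count_matrix(mat, ann, anchor="tss", flank_bp=600)
        assert rm.n_dropped == 1 and rm.region_names == ["ok"]

    def test_flank_not_multiple_of_bin_size_warns_and_rounds(self):
        mat = matrix_from(np.zeros((20, 1)), ["s"])
        ann = RegionSet.from_tuples([("chr1", 2000, 2600, "g", "+")])
        with pytest.warns(UserWarning, match="rounding"):
            rm = region_count_matrix(mat, ann, anchor="tss", flank_bp=500)
        assert rm.per_sample["s"].shape[1] == 4  # flank used: 400 bp = 2 bins per side

    def test_body_anchor_scales_gene_to_fixed_meta_bins(self):
        mat = matrix_from(np.arange(50).reshape(50, 1), ["s"])
        ann = RegionSet.from_tuples(
            [("chr1", 2000, 4000, "short", "+"), ("chr1", 5000, 9000, "long", "+")]
        )
        rm = region_count_matrix(mat, ann, anchor="body", flank_bp=400, n_body_bins=20)
        assert rm.per_sample["s"].shape == (2, 2 + 20 + 2)


class TestAverageProfile:
    def region_matrix(self, rows, names=None):
        rows = np.asarray(rows, dtype=float)
        return RegionMatrix(
            per_sample={"s": rows},
            offsets=np.arange(rows.shape[1]) * 200,
            region_names=names or [f"r{i}" for i in range(rows.shape[0])],
        )

    def test_constant_regions_average_to_constant(self):
        rm = self.region_matrix(np.full((4, 5), 3.0))
        prof = average_profile(rm)
        np.testing.assert_allclose(prof.profiles["background"]["s"], 3.0)

    def test_arithmetic_mean_of_member_regions(self):
        rm = self.region_matrix([[0, 2, 0], [0, 4, 0]])
        prof = average_profile(rm)
        np.testing.assert_allclose(prof.profiles["background"]["s"], [0, 3, 0])

    def test_medium_stratum_boundaries(self):
        rows = np.zeros((4, 3))
        rows[0, 1] = 24.9  # less
        rows[1, 1] = 25.0  # medium (inclusive lower bound)
        rows[2, 1] = 49.9  # medium
        rows[3, 1] = 50.0  # high (exclusive upper bound for medium)
        membership = stratify_regions(self.region_matrix(rows))
        assert membership["medium"].tolist() == [1, 2]
        assert membership["less"].tolist() == [0]
        assert membership["high"].tolist() == [3]

    def test_membership_reusable_across_matrices(self):
        raw = self.region_matrix([[60, 60, 60], [1, 1, 1]])
        membership = stratify_regions(raw)
        norm = self.region_matrix([[30, 30, 30], [2, 2, 2]])
        with pytest.warns(UserWarning, match="empty"):
            prof = average_profile(norm, membership=membership)
        # region 0 stays in 'high' even though its normalized max is < 50
        np.testing.assert_allclose(prof.profiles["high"]["s"], 30.0)

    def test_empty_stratum_warned_and_omitted(self):
        rm = self.region_matrix([[100, 0, 0]])
        with pytest.warns(UserWarning, match="empty"):
            prof = average_profile(rm)
        assert list(prof.profiles) == ["high"]

    def test_profile_table_long_format(self):
        prof = average_profile(self.region_matrix([[0, 2, 0]]))
        table = profile_table(prof)
        assert list(table.columns) == ["offset", "stratum", "sample", "mean_rci"]
        assert len(table) == 3


class TestRenderPlots:
    def test_one_panel_per_pair_and_per_stratum(self, tmp_path):
        rng = np.random.default_rng(0)
        counts = {n: rng.integers(0, 30, 100).astype(float) for n in ("a", "b", "c")}
        pairs = [("a", "b"), ("a", "c"), ("b", "c")]
        ma = {p: ma_transform(counts[p[0]], counts[p[1]], 1.0) for p in pairs}
        rm = RegionMatrix(
            per_sample={"a": np.full((2, 4), 60.0), "b": np.full((2, 4), 55.0)},
            offsets=np.arange(4) * 200,
            region_names=["r0", "r1"],
        )
        prof = average_profile(rm)
        written = render_plots(ma, ma, prof, prof, tmp_path)
        names = sorted(p.name for p in written)
        assert sum(n.startswith("ma_") and n.endswith(".png") for n in names) == 3
        assert "profile_high.png" in names and "profile_high.svg" in names

    def test_without_annotation_only_ma_panels(self, tmp_path):
        ma = {("a", "b"): ma_transform(np.ones(10), np.ones(10), 1.0)}
        written = render_plots(ma, ma, None, None, tmp_path)
        assert all(p.name.startswith("ma_") for p in written)
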