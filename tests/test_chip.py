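"""Promoter quantification: normalization arithmetic, strand symmetry,
trimming, ranking and the phase-comparison ANOVA."""

import numpy as np
import pandas as pd
import pytest

from cyclechrom import chip
from cyclechrom.core import SignalTrack, TSSAnnotation

from conftest import constant_track, single_gene_annotation

SIZES = {"chr1": 20_000}


def _track(values_chr1, library_size=None, **meta):
    return SignalTrack(values={"chr1": np.asarray(values_chr1, dtype=float)},
                       chrom_sizes={"chr1": len(values_chr1) * 10},
                       library_size=library_size, **meta)


class TestNormalizeTrack:
    def test_signal_equal_input_gives_zero(self):
        sig = _track([5, 3, 7], library_size=1000)
        inp = _track([5, 3, 7], library_size=1000)
        out = chip.normalize_track(sig, inp)
        np.testing.assert_array_equal(out.values["chr1"], [0, 0, 0])
        assert out.normalized

    def test_rpm_subtraction_arithmetic(self):
        sig = _track([10], library_size=1_000_000)
        inp = _track([2], library_size=1_000_000)
        out = chip.normalize_track(sig, inp)
        assert out.values["chr1"][0] == pytest.approx(8.0)

    def test_scale_invariance(self):
        sig = _track([10, 0, 4], library_size=1_000_000)
        inp = _track([2, 1, 1], library_size=2_000_000)
        base = chip.normalize_track(sig, inp).values["chr1"]
        sig10 = _track([100, 0, 40], library_size=10_000_000)
        inp10 = _track([20, 10, 10], library_size=20_000_000)
        scaled = chip.normalize_track(sig10, inp10).values["chr1"]
        np.testing.assert_allclose(scaled, base)

    def test_mismatched_chromosomes_rejected(self):
        sig = _track([1, 2], library_size=10)
        inp = SignalTrack(values={"chrX": np.zeros(2)},
                          chrom_sizes={"chrX": 20}, library_size=10)
        with pytest.raises(ValueError, match="chromosome"):
            chip.normalize_track(sig, inp)

    def test_zero_library_rejected(self):
        sig = _track([1], library_size=0)
        inp = _track([1], library_size=10)
        with pytest.raises(ValueError, match="library_size"):
            chip.normalize_track(sig, inp)


def _mirror_annotation(annotation: TSSAnnotation, length: int) -> TSSAnnotation:
    df = annotation.df.copy()
    df["tss"] = length - df["tss"]
    df["strand"] = df["strand"].map({"+": "-", "-": "+"})
    return TSSAnnotation(df)


def _mirror_track(track: SignalTrack) -> SignalTrack:
    return SignalTrack(
        values={c: v[::-1].copy() for c, v in track.values.items()},
        chrom_sizes=dict(track.chrom_sizes), bin_size=track.bin_size,
        library_size=track.library_size, normalized=track.normalized)


class TestPromoterCoverage:
    def test_constant_track_gives_constant_regardless_of_strand(self):
        track = constant_track(2.5, SIZES, normalized=True)
        ann = TSSAnnotation(pd.DataFrame({
            "chrom": ["chr1", "chr1"], "tss": [5000, 9000],
            "strand": ["+", "-"], "gene_id": ["a", "b"]}))
        cov = chip.promoter_coverage(track, ann)
        assert cov["a"] == pytest.approx(2.5)
        assert cov["b"] == pytest.approx(2.5)

    def test_plus_gene_partial_window(self):
        # signal 1.0 only on [tss, tss+1000): half of the 2 kb window
        track = constant_track(0.0, SIZES, normalized=True)
        track.values["chr1"][500:600] = 1.0  # [5000, 6000)
        ann = single_gene_annotation(tss=5000, strand="+")
        cov = chip.promoter_coverage(track, ann)
        assert cov["g1"] == pytest.approx(0.5)

    def test_minus_gene_equals_plus_gene_on_mirrored_genome(self):
        # integer-valued signal keeps the mean exact under reversal
        rng = np.random.default_rng(5)
        track = SignalTrack(
            values={"chr1": rng.integers(0, 50, size=2000).astype(float)},
            chrom_sizes=SIZES, normalized=True)
        ann = single_gene_annotation(tss=5000, strand="+")
        plus = chip.promoter_coverage(track, ann)["g1"]
        minus = chip.promoter_coverage(
            _mirror_track(track),
            _mirror_annotation(ann, SIZES["chr1"]))["g1"]
        assert minus == plus  # bit-exact strand symmetry

    def test_window_truncated_at_chromosome_edge(self):
        track = constant_track(1.0, SIZES, normalized=True)
        ann = single_gene_annotation(tss=100, strand="+")
        cov = chip.promoter_coverage(track, ann)
        assert cov["g1"] == pytest.approx(1.0)

    def test_gene_on_missing_chromosome_rejected(self):
        track = constant_track(1.0, SIZES, normalized=True)
        ann = single_gene_annotation(chrom="chr9")
        with pytest.raises(ValueError, match="chr9"):
            chip.promoter_coverage(track, ann)


class TestProfileMatrix:
    def test_constant_track_and_column_count(self):
        track = constant_track(1.5, SIZES, normalized=True)
        ann = single_gene_annotation(tss=10_000)
        mat = chip.profile_matrix(track, ann)
        assert mat.values.shape == (1, 2000)
        assert np.all(mat.values == 1.5)

    def test_minus_profile_is_mirror_of_plus(self):
        rng = np.random.default_rng(6)
        track = SignalTrack(values={"chr1": rng.normal(size=2000)},
                            chrom_sizes=SIZES, normalized=True)
        ann = single_gene_annotation(tss=10_000, strand="+")
        plus = chip.profile_matrix(track, ann, span=2000)
        minus = chip.profile_matrix(
            _mirror_track(track),
            _mirror_annotation(ann, SIZES["chr1"]), span=2000)
        np.testing.assert_array_equal(minus.values, plus.values)

    def test_out_of_bounds_bins_zeroed_and_flagged(self):
        track = constant_track(1.0, SIZES, normalized=True)
        ann = single_gene_annotation(tss=500)
        mat = chip.profile_matrix(track, ann, span=2000)
        assert mat.oob[0, :150].all()      # bins before the chromosome
        assert np.all(mat.values[0, :150] == 0)
        assert not mat.oob[0, 150:].any()


class TestTrimPercentiles:
    def test_constant_matrix_unchanged(self):
        track = constant_track(4.0, SIZES, normalized=True)
        mat = chip.profile_matrix(track, single_gene_annotation(tss=10_000))
        out = chip.trim_percentiles(mat)
        np.testing.assert_array_equal(out.values, mat.values)
        assert out.trimmed

    def test_winsorizes_to_interpolated_percentiles(self):
        values = np.arange(1.0, 101.0).reshape(1, 100)
        mat = chip.ProfileMatrix(values=values, gene_ids=["g"], span=500,
                                 bin_size=10, oob=np.zeros_like(values, bool))
        out = chip.trim_percentiles(mat, 5, 95)
        # brute-force percentile of 1..100 by linear interpolation
        srt = np.sort(values.ravel())
        lo = np.interp(0.05 * (len(srt) - 1), np.arange(len(srt)), srt)
        hi = np.interp(0.95 * (len(srt) - 1), np.arange(len(srt)), srt)
        assert out.values.min() == pytest.approx(lo)
        assert out.values.max() == pytest.approx(hi)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(10, 50))
        mat = chip.ProfileMatrix(values=values, gene_ids=list("abcdefghij"),
                                 span=250, bin_size=10,
                                 oob=np.zeros_like(values, bool))
        once = chip.trim_percentiles(mat)
        twice = chip.trim_percentiles(once)
        np.testing.assert_allclose(twice.values, once.values)

    def test_joint_percentiles_across_phases(self):
        lo_mat = chip.ProfileMatrix(
            values=np.arange(1.0, 21.0).reshape(2, 10), gene_ids=["a", "b"],
            span=50, bin_size=10, oob=np.zeros((2, 10), bool))
        hi_mat = chip.ProfileMatrix(
            values=np.arange(21.0, 41.0).reshape(2, 10), gene_ids=["a", "b"],
            span=50, bin_size=10, oob=np.zeros((2, 10), bool))
        t_lo, t_hi = chip.trim_percentiles([lo_mat, hi_mat])
        joint_lo, joint_hi = np.percentile(np.arange(1.0, 41.0), [5, 95])
        # the low matrix is clipped at the JOINT 5th percentile (2.95), not
        # its own; the high matrix at the joint 95th
        assert t_lo.values.min() == pytest.approx(joint_lo)
        assert t_lo.values.min() > 1.0
        assert t_hi.values.max() == pytest.approx(joint_hi)


class TestRanking:
    def test_descending_reference_order_with_tie_break(self):
        sig = {"G2": pd.Series({"a": 5.0, "b": 3.0, "c": 3.0, "d": 9.0})}
        assert chip.rank_by_reference(sig) == ["d", "a", "b", "c"]

    def test_row_permutation_invariance(self):
        sig = pd.Series({"a": 1.0, "b": 7.0, "c": 4.0})
        shuffled = sig.sample(frac=1, random_state=3)
        assert chip.rank_by_reference({"G2": sig}) \
            == chip.rank_by_reference({"G2": shuffled})


def test_average_profile_is_column_mean():
    values = np.array([[1.0, 3.0], [3.0, 5.0]])
    mat = chip.ProfileMatrix(values=values, gene_ids=["a", "b"], span=10,
                             bin_size=10, oob=np.zeros_like(values, bool))
    np.testing.assert_allclose(chip.average_profile(mat), [2.0, 4.0])


class TestProfileAnova:
    def test_identical_groups_defined_as_zero(self):
        sig = {p: pd.Series([1.0, 1.0, 1.0]) for p in ("G1", "S", "G2")}
        assert chip.profile_anova(sig) == (0.0, 1.0)

    def test_textbook_sums_of_squares(self):
        groups = {"G1": pd.Series([1.0, 2, 3]), "S": pd.Series([4.0, 5, 6]),
                  "G2": pd.Series([7.0, 8, 9])}
        f, p = chip.profile_anova(groups)
        # by hand: SSB = 3((2-5)^2+(5-5)^2+(8-5)^2) = 54, SSW = 6,
        # F = (54/2)/(6/6) = 27
        assert f == pytest.approx(27.0, abs=1e-9)
        assert 0 < p < 0.05

    def test_location_invariance(self):
        groups = {"G1": pd.Series([1.0, 2, 4]), "G2": pd.Series([2.0, 5, 6])}
        f1, _ = chip.profile_anova(groups)
        shifted = {k: v + 100.0 for k, v in groups.items()}
        f2, _ = chip.profile_anova(shifted)
        assert f1 == pytest.approx(f2)


class TestPromoterLog2FC:
    def test_equal_signals_give_zero(self):
        a = pd.Series({"g": 3.0})
        assert chip.promoter_log2fc(a, a)["g"] == 0.0

    def test_plain_ratio_without_pseudocount(self):
        a, b = pd.Series({"g": 4.0}), pd.Series({"g": 2.0})
        assert chip.promoter_log2fc(a, b, pseudocount=0.0)["g"] == \
            pytest.approx(1.0)

    def test_double_zero_resolved_by_pseudocount(self):
        z = pd.Series({"g": 0.0})
        assert chip.promoter_log2fc(z, z)["g"] == 0.0

    def test_negative_normalized_values_floored(self):
        a, b = pd.Series({"g": -3.0}), pd.Series({"g": 0.0})
        assert chip.promoter_log2fc(a, b)["g"] == 0.0
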