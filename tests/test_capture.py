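"""Capture-C quantification: normalization formula, interaction calling,
summit-normalized flipped metaprofiles and distance-matched controls."""

import numpy as np
import pandas as pd
import pytest

from cyclechrom import capture as cap
from cyclechrom import simulate as sim
from cyclechrom.core import FragmentMap, InteractionTable, PeakSet


class TestNormCounts:
    def test_published_formula_example(self):
        norm = cap.CaptureNormalization(cov=1e6, nprom=122)
        assert cap.norm_counts(10, norm) == pytest.approx(122.0)

    def test_zero_counts_stay_zero(self):
        norm = cap.CaptureNormalization(cov=5e5, nprom=10)
        assert cap.norm_counts(0, norm) == 0.0

    def test_joint_rescaling_invariance(self):
        a = cap.norm_counts(10, cap.CaptureNormalization(cov=1e6, nprom=122))
        b = cap.norm_counts(70, cap.CaptureNormalization(cov=7e6, nprom=122))
        assert a == pytest.approx(b)

    def test_nonpositive_cov_rejected(self):
        with pytest.raises(ValueError, match="cov"):
            cap.CaptureNormalization(cov=0, nprom=5)


def _uniform_fragmap(n=200, frag_len=100, chrom="chr1"):
    starts = np.arange(n) * frag_len
    return FragmentMap({chrom: pd.DataFrame({
        "index": np.arange(n), "start": starts, "end": starts + frag_len})})


def _toy_table(score_by_frag, counts_by_frag, vp="g1", chrom="chr1",
               conditions=("G1_WT", "G2_WT"), n=200, frag_len=100):
    rows = []
    for cond in conditions:
        for frag, score in score_by_frag.items():
            rows.append({
                "viewpoint_id": vp, "chrom": chrom, "frag_index": frag,
                "frag_start": frag * frag_len,
                "frag_end": (frag + 1) * frag_len, "condition": cond,
                "counts": counts_by_frag.get((cond, frag),
                                             counts_by_frag.get(frag, 1)),
                "score": score})
    return InteractionTable(pd.DataFrame(rows))


def _atac(frags, frag_len=100, chrom="chr1"):
    df = pd.DataFrame({"chrom": chrom,
                       "start": [f * frag_len for f in frags],
                       "end": [(f + 1) * frag_len for f in frags]})
    return PeakSet(df)


VIEWPOINTS = pd.DataFrame({"gene_id": ["g1"], "chrom": ["chr1"],
                           "frag_index": [100]})


class TestCallInteractions:
    def test_threshold_is_geq_and_run_extent(self):
        table = _toy_table({10: 4.9, 11: 5.0, 12: 6.0, 13: 3.0},
                           {10: 1, 11: 2, 12: 5, 13: 1})
        out = cap.call_interactions(table, _atac([10, 11, 12, 13]),
                                    _uniform_fragmap(), VIEWPOINTS)
        assert len(out) == 1
        inter = out[0]
        assert (inter.i_lo, inter.i_hi) == (11, 12)
        assert inter.summit == 12      # larger G2 normCounts
        assert inter.side == -1        # summit below the viewpoint fragment

    def test_gap_splits_runs(self):
        table = _toy_table({10: 6.0, 11: 2.0, 12: 6.0},
                           {10: 3, 11: 1, 12: 3})
        out = cap.call_interactions(table, _atac([10, 11, 12]),
                                    _uniform_fragmap(), VIEWPOINTS)
        assert len(out) == 2
        assert [(i.i_lo, i.i_hi) for i in out] == [(10, 10), (12, 12)]

    def test_significant_fragment_without_atac_ignored(self):
        table = _toy_table({10: 8.0}, {10: 3})
        assert cap.call_interactions(table, _atac([50]), _uniform_fragmap(),
                                     VIEWPOINTS) == []

    def test_summit_tie_breaks_toward_viewpoint(self):
        table = _toy_table({10: 6.0, 11: 6.0}, {10: 2, 11: 2})
        out = cap.call_interactions(table, _atac([10, 11]),
                                    _uniform_fragmap(), VIEWPOINTS)
        assert out[0].summit == 11     # closest to viewpoint fragment 100

    def test_unresolvable_viewpoint_rejected(self):
        table = _toy_table({10: 6.0}, {10: 2})
        with pytest.raises(ValueError, match="unresolvable"):
            cap.call_interactions(table, _atac([10]), _uniform_fragmap(),
                                  pd.DataFrame(columns=["gene_id", "chrom",
                                                        "frag_index"]))


class TestSumIntervalCounts:
    def _interaction(self, lo, hi, summit):
        return cap.Interaction(viewpoint_id="g1", chrom="chr1",
                               viewpoint_fragment=100, i_lo=lo, i_hi=hi,
                               summit=summit, distance=100 - summit, side=-1)

    def test_single_fragment_and_additivity(self):
        table = _toy_table({10: 6.0, 11: 6.0, 12: 6.0},
                           {10: 2, 11: 3, 12: 5})
        norm = cap.normalization_from_table(table, "G1_WT")
        single, _ = cap.sum_interval_counts(self._interaction(11, 11, 11),
                                            table, "G1_WT", norm)
        assert single == pytest.approx(cap.norm_counts(3, norm))
        whole, _ = cap.sum_interval_counts(self._interaction(10, 12, 11),
                                           table, "G1_WT", norm)
        left, _ = cap.sum_interval_counts(self._interaction(10, 10, 10),
                                          table, "G1_WT", norm)
        right, _ = cap.sum_interval_counts(self._interaction(11, 12, 11),
                                           table, "G1_WT", norm)
        assert whole == pytest.approx(left + right)

    def test_all_zero_fragments_sum_to_zero(self):
        table = _toy_table({10: 6.0}, {10: 0, (("G2_WT", 10)): 1})
        norm = cap.CaptureNormalization(cov=100, nprom=1)
        total, _ = cap.sum_interval_counts(self._interaction(10, 10, 10),
                                           table, "G1_WT", norm)
        assert total == 0.0


def test_orientation_flip_is_involution():
    offsets = np.arange(-40, 41)
    for side in (-1, 1):
        once = cap.orient_offsets(offsets, side)
        np.testing.assert_array_equal(cap.orient_offsets(once, side), offsets)


class TestMetaprofile:
    def test_g2_position_zero_is_one_and_symmetry(self):
        # symmetric counts around one summit
        scores = {f: (6.0 if f == 20 else 0.0) for f in range(10, 31)}
        counts = {}
        for cond in ("G1_WT", "G2_WT"):
            for f in range(10, 31):
                counts[(cond, f)] = 10 - abs(f - 20)
        table = _toy_table(scores, counts)
        inter = cap.Interaction(viewpoint_id="g1", chrom="chr1",
                                viewpoint_fragment=100, i_lo=20, i_hi=20,
                                summit=20, distance=80, side=-1)
        prof = cap.build_metaprofile([inter], table, _uniform_fragmap(),
                                     span=5)
        g2 = prof["G2_WT"]
        assert g2.mean[g2.positions == 0][0] == pytest.approx(1.0)
        np.testing.assert_allclose(g2.mean, g2.mean[::-1])  # symmetric input

    def test_mirror_genome_invariance(self, capture_sim, fragmap,
                                      small_config):
        table = capture_sim.table
        inters = cap.call_interactions(table, capture_sim.atac_peaks, fragmap,
                                       capture_sim.viewpoints)
        prof = cap.build_metaprofile(inters, table, fragmap, span=20)

        # reverse every chromosome: fragment i -> n-1-i
        n_frag = {c: fragmap.n_fragments(c) for c in fragmap.frames}
        length = small_config.chrom_length
        mdf = table.df.copy()
        mdf["frag_index"] = [n_frag[c] - 1 - i for c, i in
                             zip(mdf["chrom"], mdf["frag_index"])]
        mdf["frag_start"], mdf["frag_end"] = (length - mdf["frag_end"],
                                              length - mdf["frag_start"])
        mtable = InteractionTable(mdf)
        mframes = {}
        for c, df in fragmap.frames.items():
            rev = df.iloc[::-1].reset_index(drop=True)
            mframes[c] = pd.DataFrame({
                "index": np.arange(len(rev)),
                "start": length - rev["end"].to_numpy(),
                "end": length - rev["start"].to_numpy()})
        mfragmap = FragmentMap(mframes)
        mpeaks = PeakSet(pd.DataFrame({
            "chrom": capture_sim.atac_peaks.df["chrom"],
            "start": length - capture_sim.atac_peaks.df["end"],
            "end": length - capture_sim.atac_peaks.df["start"]}))
        mviews = capture_sim.viewpoints.copy()
        mviews["frag_index"] = [n_frag[c] - 1 - i for c, i in
                                zip(mviews["chrom"], mviews["frag_index"])]
        minters = cap.call_interactions(mtable, mpeaks, mfragmap, mviews)
        mprof = cap.build_metaprofile(minters, mtable, mfragmap, span=20)
        for cond in prof:
            np.testing.assert_array_equal(prof[cond].mean, mprof[cond].mean)
            np.testing.assert_array_equal(prof[cond].n, mprof[cond].n)

    def test_nonpositive_reference_summit_dropped(self, caplog):
        table = _toy_table({20: 6.0, 25: 0.0},
                           {("G2_WT", 20): 0, ("G1_WT", 20): 5,
                            ("G2_WT", 25): 3, ("G1_WT", 25): 1})
        inter = cap.Interaction(viewpoint_id="g1", chrom="chr1",
                                viewpoint_fragment=100, i_lo=20, i_hi=20,
                                summit=20, distance=80, side=-1)
        prof = cap.build_metaprofile([inter], table, _uniform_fragmap(),
                                     span=3)
        assert prof["G1_WT"].n.sum() == 0


class TestDistanceMatchedControls:
    def test_reflection_example_and_involution(self):
        inter = cap.Interaction(viewpoint_id="g1", chrom="chr1",
                                viewpoint_fragment=100, i_lo=119, i_hi=121,
                                summit=120, distance=20, side=1)
        assert cap.control_site(inter) == 80
        mirrored = cap.Interaction(viewpoint_id="g1", chrom="chr1",
                                   viewpoint_fragment=100, i_lo=79, i_hi=81,
                                   summit=cap.control_site(inter),
                                   distance=20, side=-1)
        assert cap.control_site(mirrored) == 120

    def test_control_profile_flat_on_synthetic_background(self, capture_sim,
                                                          fragmap):
        inters = cap.call_interactions(capture_sim.table,
                                       capture_sim.atac_peaks, fragmap,
                                       capture_sim.viewpoints)
        ctrl = cap.distance_matched_controls(inters, capture_sim.table,
                                             fragmap, span=40)
        curve = ctrl["G2_WT"].mean
        assert np.nanmax(curve) / np.nanmedian(curve) < 1.5
        # and no enrichment at position 0 relative to neighbours
        pos0 = curve[ctrl["G2_WT"].positions == 0][0]
        assert pos0 < 1.3 * np.nanmedian(curve)


class TestCompareInteractionGroups:
    def test_exact_enumeration_example(self):
        res = cap.compare_interaction_groups([1, 2, 3], [4, 5, 6])
        assert res["u"] == 0.0
        assert res["pval"] == pytest.approx(0.1)  # 2 of 20 assignments

    def test_identical_groups_p_one(self):
        res = cap.compare_interaction_groups([1, 2, 3], [1, 2, 3])
        assert res["pval"] == pytest.approx(1.0)

    def test_scaling_invariance(self):
        a = cap.compare_interaction_groups([1.0, 2, 3, 10], [4.0, 5, 6, 2])
        b = cap.compare_interaction_groups([7.0, 14, 21, 70],
                                           [28.0, 35, 42, 14])
        assert a["u"] == b["u"]
        assert a["pval"] == pytest.approx(b["pval"])
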