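"""Thickness traces, contraction-phase detection, phase summaries."""

import numpy as np
import pandas as pd
import pytest

from fasciatrack import (
    FasciaSegmentation,
    PhaseAnnotation,
    PhaseParams,
    build_traces,
    detect_contraction_phase,
    generate_video,
    place_measurement_points,
    segment_fasciae,
    summarize_phases,
    thickness_at_point,
    track_video,
)
from fasciatrack.thickness import summary_to_par_inputs


def flat_segmentation(rows, n_cols=100):
    bounds = np.tile(np.asarray(rows, dtype=float)[:, None], (1, n_cols))
    return FasciaSegmentation(frame_index=0, boundaries=bounds, column_range=(0, n_cols))


def step_trace(n=120, low=4.6, high=5.4, start=40, end=80):
    """Noise-free 3-point TrA trace with a thickness step on [start, end)."""
    rows = []
    for f in range(n):
        value = high if start <= f < end else low
        for m, v in (("TrA", value), ("OI", 9.0), ("OE", 5.0)):
            for p in range(3):
                rows.append({"frame": f, "time_s": f / 20.0, "muscle": m,
                             "point_id": p, "thickness_mm": v, "flag": ""})
    return pd.DataFrame(rows)


class TestThicknessAtPoint:
    def test_flat_boundaries_give_calibrated_distance(self):
        seg = flat_segmentation([10, 20, 60, 100])
        assert thickness_at_point(seg, "OE", (10.0, 50.0), 0.1) == pytest.approx(1.0)

    def test_doubling_spacing_doubles_thickness(self):
        seg = flat_segmentation([10, 20, 60, 100])
        t1 = thickness_at_point(seg, "OI", (20.0, 30.0), 0.1)
        t2 = thickness_at_point(seg, "OI", (20.0, 30.0), 0.2)
        assert t2 == pytest.approx(2 * t1)

    def test_point_outside_column_range_rejected(self):
        seg = flat_segmentation([10, 20, 60, 100])
        with pytest.raises(ValueError, match="column"):
            thickness_at_point(seg, "OE", (10.0, 150.0), 0.1)

    def test_point_below_lower_boundary_rejected(self):
        seg = flat_segmentation([10, 20, 60, 100])
        with pytest.raises(ValueError, match="not below"):
            thickness_at_point(seg, "OE", (25.0, 50.0), 0.1)

    def test_all_nine_points_match_ground_truth(self, adim_video):
        video, truth = adim_video
        seg = segment_fasciae(video.frames[0], frame_index=0)
        pts = place_measurement_points(seg)
        for mi, m in enumerate(("OE", "OI", "TrA")):
            for p in range(3):
                measured = thickness_at_point(seg, m, tuple(pts.points[m][p]), 0.1)
                assert measured == pytest.approx(truth.thickness_mm[0, mi], abs=0.05)


class TestBuildTraces:
    def test_static_video_gives_constant_traces(self, static_script):
        video, truth = generate_video(static_script, seed=13)
        seg0 = segment_fasciae(video.frames[0], frame_index=0)
        pts = place_measurement_points(seg0)
        segs, tracks = track_video(video, {0: seg0}, pts)
        trace = build_traces(segs, tracks, video)
        spread = trace.groupby(["muscle", "point_id"])["thickness_mm"].agg(np.ptp)
        assert spread.max() <= 0.05
        assert np.allclose(trace["time_s"], trace["frame"] / static_script.frame_rate)

    def test_flagged_point_leaves_other_points_reported(self, static_script):
        video, _ = generate_video(static_script, seed=13)
        seg0 = segment_fasciae(video.frames[0], frame_index=0)
        pts = place_measurement_points(seg0)
        segs, tracks = track_video(video, {0: seg0}, pts)
        tracks.loc[(tracks.muscle == "TrA") & (tracks.point_id == 0), "flag"] = "lost"
        trace = build_traces(segs, tracks, video)
        tra0 = trace[(trace.muscle == "TrA") & (trace.point_id == 0)]
        tra_rest = trace[(trace.muscle == "TrA") & (trace.point_id != 0)]
        assert tra0["thickness_mm"].isna().all()
        assert tra_rest["thickness_mm"].notna().all()

    def test_majority_lost_muscle_raises(self, static_script):
        video, _ = generate_video(static_script, seed=13)
        seg0 = segment_fasciae(video.frames[0], frame_index=0)
        pts = place_measurement_points(seg0)
        segs, tracks = track_video(video, {0: seg0}, pts)
        tracks.loc[tracks.muscle == "OI", "flag"] = "lost"
        with pytest.raises(ValueError, match="OI"):
            build_traces(segs, tracks, video)


class TestPhaseDetection:
    def test_flat_trace_has_empty_contracted_interval(self):
        trace = step_trace(high=4.6)  # no step at all
        with pytest.warns(UserWarning, match="no contraction"):
            phases = detect_contraction_phase(trace)
        assert phases.contracted == []
        assert phases.rest == [(0, 120)]

    def test_noise_free_step_detected_exactly(self):
        phases = detect_contraction_phase(step_trace())
        assert phases.contracted == [(40, 80)]
        assert phases.rest == [(0, 40), (80, 120)]

    def test_invariant_to_constant_offset(self):
        trace = step_trace()
        shifted = trace.copy()
        shifted["thickness_mm"] += 7.0
        assert (detect_contraction_phase(trace).contracted
                == detect_contraction_phase(shifted).contracted)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="20 frames"):
            detect_contraction_phase(step_trace(n=10, start=3, end=6))

    @pytest.mark.parametrize("seed", range(3))
    def test_scripted_ramp_overlaps_true_hold(self, adim_script, seed):
        video, truth = generate_video(adim_script, seed=100 + seed)
        seg0 = segment_fasciae(video.frames[0], frame_index=0)
        pts = place_measurement_points(seg0)
        segs, tracks = track_video(video, {0: seg0}, pts)
        trace = build_traces(segs, tracks, video)
        phases = detect_contraction_phase(trace)
        (s, e), = phases.contracted
        hold = set(range(adim_script.hold_start, adim_script.hold_end))
        got = set(range(s, e))
        jaccard = len(hold & got) / len(hold | got)
        assert jaccard >= 0.5  # hysteresis admits ramp frames by design


class TestSummaries:
    def test_constant_trace_rest_equals_contracted(self):
        trace = step_trace(high=5.0, low=5.0)
        phases = PhaseAnnotation(rest=[(0, 40), (80, 120)], contracted=[(40, 80)])
        summary = summarize_phases(trace, phases)
        tra = summary[summary.muscle == "TrA"].iloc[0]
        assert tra.rest_mm == pytest.approx(5.0)
        assert tra.contracted_mm == pytest.approx(5.0)

    def test_step_trace_summary_matches_plateaus(self):
        summary = summarize_phases(step_trace(), detect_contraction_phase(step_trace()))
        tra = summary.set_index("muscle").loc["TrA"]
        assert tra.rest_mm == pytest.approx(4.6)
        assert tra.contracted_mm == pytest.approx(5.4)
        inputs = summary_to_par_inputs(summary)
        assert inputs["TrA_C"] == pytest.approx(5.4)
        assert inputs["OI_R"] == pytest.approx(9.0)

    def test_pooled_rest_mode_uses_both_rest_intervals(self):
        trace = step_trace()
        # post-contraction rest is different from pre-contraction rest
        post = trace["frame"] >= 80
        trace.loc[post & (trace.muscle == "TrA"), "thickness_mm"] = 4.0
        phases = PhaseAnnotation(rest=[(0, 40), (80, 120)], contracted=[(40, 80)])
        pre = summarize_phases(trace, phases, rest_mode="pre")
        pooled = summarize_phases(trace, phases, rest_mode="pooled")
        assert pre.set_index("muscle").loc["TrA", "rest_mm"] == pytest.approx(4.6)
        assert pooled.set_index("muscle").loc["TrA", "rest_mm"] == pytest.approx(4.3)

    def test_empty_contracted_phase_raises(self):
        phases = PhaseAnnotation(rest=[(0, 120)], contracted=[])
        with pytest.raises(ValueError, match="empty contracted"):
            summarize_phases(step_trace(), phases)

    def test_end_to_end_summary_matches_script(self, adim_video, adim_script):
        video, truth = adim_video
        seg0 = segment_fasciae(video.frames[0], frame_index=0)
        pts = place_measurement_points(seg0)
        segs, tracks = track_video(video, {0: seg0}, pts)
        trace = build_traces(segs, tracks, video)
        phases = detect_contraction_phase(trace)
        summary = summarize_phases(trace, phases).set_index("muscle")
        assert summary.loc["TrA", "rest_mm"] == pytest.approx(
            adim_script.rest_thickness["TrA"], abs=0.15
        )
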