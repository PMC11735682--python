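"""ROI detection maps, grouping, and every exclusion rule."""

import numpy as np
import pytest

from hvospipe.detect import (
    ROI,
    CandidateGroup,
    adjacency_exclusion,
    amplitude_outlier_exclusion,
    build_maps,
    detect_candidates,
    direct_stimulation_exclusion,
    kmeans_snr_exclude,
    size_exclusion,
    threshold_and_group,
)
from hvospipe.preprocess import DffMovie, preprocess
from hvospipe.simulate import SceneConfig, filter_attenuation, render_trial_stack
from oracles import flood_fill_groups

PITCH = 19.0 / 3.0


def _movie(data, stim=10.0):
    return DffMovie(np.asarray(data, float), 0.5, stim, (0, 16), pixel_pitch=PITCH)


def _group(pixels):
    return CandidateGroup(pixels=sorted(pixels), mean_snr=10.0, mean_amplitude=0.005)


# --- maps -----------------------------------------------------------------

def test_zero_movie_gives_zero_maps():
    amp, snr, _ = build_maps(_movie(np.zeros((80, 8, 8))))
    assert np.all(amp.values == 0) and np.all(snr.values == 0)


def test_amplitude_at_cell_center_is_injected_times_attenuation(noiseless_single_cell):
    stack, truth, cfg = noiseless_single_cell
    dff = preprocess(stack)
    amp, _, _ = build_maps(dff)
    cell = truth.cells[0]
    r, c = int(cell.center[0]), int(cell.center[1])
    att = filter_attenuation(cell, cfg, pixels=[(r, c)])
    assert amp.values[r, c] == pytest.approx(cell.amplitude_true * att, rel=0.01)


def test_noise_only_median_snr_below_five():
    cfg = SceneConfig(shape=(40, 40), n_frames=200, stim_time=20.0, noise_scale=0.2, seed=5)
    stack, _ = render_trial_stack(cfg, [])
    dff = preprocess(stack)
    _, snr, _ = build_maps(dff)
    vals = snr.values[np.isfinite(snr.values)]
    assert np.median(vals) < 5.0


def test_zero_rms_pixels_are_flagged_infinite_and_not_grouped():
    data = np.zeros((80, 6, 6))
    data[30:40, 2, 2] = -0.01  # response with a perfectly flat baseline
    amp, snr, _ = build_maps(_movie(data))
    assert np.isinf(snr.values[2, 2])
    groups = threshold_and_group(amp, snr, 1e-4, 5.0)
    assert groups == []


# --- grouping -------------------------------------------------------------

def test_empty_suprathreshold_set_gives_no_groups():
    amp, snr, _ = build_maps(_movie(np.zeros((80, 6, 6))))
    assert threshold_and_group(amp, snr, 0.001, 5.0) == []


def test_l_shaped_blob_is_one_group_matching_flood_fill():
    data = np.zeros((80, 8, 8))
    rng = np.random.default_rng(0)
    data[:16] = rng.normal(0, 1e-4, (16, 8, 8))  # nonzero baseline RMS
    for (r, c) in [(3, 3), (4, 3), (4, 4)]:
        data[30:40, r, c] = -0.05
    amp, snr, _ = build_maps(_movie(data))
    groups = threshold_and_group(amp, snr, 0.01, 5.0)
    mask = (amp.values > 0.01) & (snr.values > 5)
    oracle = flood_fill_groups(mask)
    assert len(groups) == len(oracle) == 1
    assert set(groups[0].pixels) == oracle[0] == {(3, 3), (4, 3), (4, 4)}


def test_diagonal_contact_is_not_contiguous():
    data = np.zeros((80, 8, 8))
    data[:16] = np.random.default_rng(0).normal(0, 1e-4, (16, 8, 8))
    data[30:40, 2, 2] = -0.05
    data[30:40, 3, 3] = -0.05
    amp, snr, _ = build_maps(_movie(data))
    groups = threshold_and_group(amp, snr, 0.01, 5.0)
    assert len(groups) == 2


# --- k-means SNR exclusion ------------------------------------------------

def test_low_snr_cluster_is_excluded():
    survive = kmeans_snr_exclude(np.array([2.0, 2, 2, 20, 20, 20]), k=2)
    np.testing.assert_array_equal(survive, [False] * 3 + [True] * 3)


def test_uniform_snr_above_cutoff_all_survive():
    assert np.all(kmeans_snr_exclude(np.full(8, 10.0), k=2))


def test_fewer_pixels_than_k_falls_back_to_pooled_mean():
    assert np.all(kmeans_snr_exclude(np.array([8.0, 9.0]), k=4))
    assert not np.any(kmeans_snr_exclude(np.array([3.0, 4.0]), k=4))


# --- size rule ------------------------------------------------------------

def test_line_of_four_pixels_is_too_large():
    kept, removed = size_exclusion([_group([(0, c) for c in range(4)])], PITCH)
    assert kept == [] and len(removed) == 1


def test_two_by_two_square_is_kept():
    g = _group([(0, 0), (0, 1), (1, 0), (1, 1)])
    kept, removed = size_exclusion([g], PITCH)
    assert removed == [] and kept == [g]
    assert g.area_um2(PITCH) == pytest.approx(4 * (19 / 3) ** 2)


def test_full_three_by_three_square_exceeds_area_rule():
    g = _group([(r, c) for r in range(3) for c in range(3)])
    assert g.area_um2(PITCH) == pytest.approx(361.0, abs=0.05)
    kept, removed = size_exclusion([g], PITCH)
    assert kept == [] and len(removed) == 1


# --- adjacency ------------------------------------------------------------

def test_vertex_contact_removes_both_groups():
    a, b = _group([(0, 0)]), _group([(1, 1)])
    kept, removed = adjacency_exclusion([a, b])
    assert kept == [] and len(removed) == 2


def test_separated_groups_are_kept():
    a, b = _group([(0, 0)]), _group([(0, 2)])
    kept, removed = adjacency_exclusion([a, b])
    assert removed == [] and len(kept) == 2


def test_only_the_touching_pair_is_removed():
    a, b, c = _group([(0, 0)]), _group([(1, 1)]), _group([(5, 5)])
    kept, removed = adjacency_exclusion([a, b, c])
    assert kept == [c] and len(removed) == 2
    # oracle: pairwise 8-neighbor check
    def touch(g1, g2):
        return any(abs(r1 - r2) <= 1 and abs(c1 - c2) <= 1
                   for r1, c1 in g1.pixels for r2, c2 in g2.pixels)
    assert touch(a, b) and not touch(a, c) and not touch(b, c)


# --- direct stimulation ---------------------------------------------------

def _roi_at(roi_id, um):
    px = (um[0] / PITCH, um[1] / PITCH)
    return ROI(roi_id=roi_id, group=_group([(round(px[0]), round(px[1]))]))


def test_near_electrode_and_short_latency_rules():
    electrode = (0.0, 0.0)
    rois = [
        ROI(0, CandidateGroup([(6, 0)], 10, 0.005)),   # 6 px -> 38 um
        ROI(1, CandidateGroup([(15, 0)], 10, 0.005)),  # 95 um
        ROI(2, CandidateGroup([(8, 0)], 10, 0.005)),   # ~50.7 um
    ]
    latencies = {0: 2.0, 1: 0.8, 2: 1.0}
    direct_stimulation_exclusion(rois, electrode, latencies, PITCH)
    assert rois[0].rejection_reason == "near_electrode"
    assert rois[1].rejection_reason == "short_latency"
    assert rois[2].accepted  # 50.7 um and exactly 1.0 ms: strict thresholds


def test_boundary_values_survive_strict_inequalities():
    rois = [ROI(0, CandidateGroup([(0, 0)], 10, 0.005))]
    # distance exactly 45 um, latency exactly 1 ms
    direct_stimulation_exclusion(rois, (45.0, 0.0), {0: 1.0}, PITCH)
    assert rois[0].accepted


# --- amplitude outliers ---------------------------------------------------

def test_outlier_rule_matches_direct_computation():
    amps = {i: a for i, a in enumerate([1.0, 1, 1, 1, 100])}
    rois = [ROI(i, _group([(i, 0)])) for i in amps]
    amplitude_outlier_exclusion(rois, amps)
    vals = np.array(list(amps.values()))
    cutoff = vals.mean() + 3 * vals.std(ddof=1)
    for roi in rois:
        assert roi.accepted == (amps[roi.roi_id] <= cutoff)


def test_equal_amplitudes_remove_nothing():
    amps = {i: 2.0 for i in range(5)}
    rois = [ROI(i, _group([(i, 0)])) for i in amps]
    amplitude_outlier_exclusion(rois, amps)
    assert all(r.accepted for r in rois)


def test_low_outlier_is_kept_rule_is_one_sided():
    amps = {0: 0.001, 1: 1.0, 2: 1.0, 3: 1.0, 4: 1.0, 5: 1.0}
    rois = [ROI(i, _group([(i, 0)])) for i in amps]
    amplitude_outlier_exclusion(rois, amps)
    assert rois[0].accepted


# --- conservation on a full scene ----------------------------------------

def test_rejections_are_exclusive_and_exhaustive():
    from hvospipe.pipeline import RunConfig, analyze_slice
    from hvospipe.simulate import recovery_scene

    cfg, cells = recovery_scene(3, n_cells=5)
    stack, _ = render_trial_stack(cfg, cells)
    dff = preprocess(stack)
    rois, params, diag = analyze_slice(dff, RunConfig())
    assert diag["n_candidates"] == len(rois)
    n_acc = sum(r.accepted for r in rois)
    n_rej = sum(not r.accepted for r in rois)
    assert n_acc + n_rej == len(rois)
    for r in rois:
        assert (r.rejection_reason == "none") == r.accepted
        if r.accepted:
            er, ec = r.group.bbox_extent
            assert er <= 3 and ec <= 3
            assert r.group.area_um2(dff.pixel_pitch) <= 360.0
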