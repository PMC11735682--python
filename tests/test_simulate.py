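"""The synthetic scene renderer and its ground truth."""

from dataclasses import replace

import numpy as np
import pytest

from hvospipe.preprocess import average_trials, compute_dff
from hvospipe.simulate import (
    SceneConfig,
    SynthCell,
    cell_mask,
    random_scene,
    recovery_scene,
    render_trial_stack,
    true_latency,
)
from hvospipe.waveform import make_epsp_waveform


def test_same_seed_gives_bit_identical_stacks():
    cfg = SceneConfig(shape=(20, 20), n_frames=100, stim_time=20.0, noise_scale=0.2, seed=7)
    cells = [SynthCell(center=(10.0, 14.0), amplitude_true=0.005)]
    s1, _ = render_trial_stack(cfg, cells)
    s2, _ = render_trial_stack(cfg, cells)
    assert np.array_equal(s1.data, s2.data)


def test_noiseless_dff_roundtrip_recovers_waveform_exactly(noiseless_single_cell):
    stack, truth, cfg = noiseless_single_cell
    dff = compute_dff(average_trials(stack))
    cell = truth.cells[0]
    r, c = int(cell.center[0]), int(cell.center[1])
    expected = make_epsp_waveform(
        cell.amplitude_true, cell.tau_rise, cell.tau_decay,
        cfg.stim_time + truth.latencies[0], cfg.time_axis,
    )
    np.testing.assert_allclose(dff.data[:, r, c], expected, atol=1e-14)


def test_conduction_delay_separates_onsets_by_distance():
    # two cells at 100 and 200 um from the electrode: onsets differ by
    # exactly 100 um x 0.015 ms/um = 1.5 ms in the ground truth, and the
    # rendered noiseless traces reproduce that within one frame (0.5 ms)
    pitch = 19.0 / 3.0
    cfg = SceneConfig(
        shape=(40, 40), n_frames=200, stim_time=20.0, electrode_um=(0.0, 0.0),
        conduction_delay_per_um=0.015, noise_scale=0.0, seed=3,
    )
    cells = [
        SynthCell(center=(0.0, 100.0 / pitch), amplitude_true=0.005, latency_offset=1.0),
        SynthCell(center=(0.0, 200.0 / pitch), amplitude_true=0.005, latency_offset=1.0),
    ]
    stack, truth = render_trial_stack(cfg, cells)
    assert truth.latencies[1] - truth.latencies[0] == pytest.approx(1.5, abs=1e-9)
    dff = compute_dff(average_trials(stack))
    onsets = []
    for cell in cells:
        tr = dff.data[:, int(round(cell.center[0])), int(round(cell.center[1]))]
        onsets.append(cfg.time_axis[np.argmax(tr < -1e-9)])
    assert onsets[1] - onsets[0] == pytest.approx(1.5, abs=cfg.frame_interval)


def test_prestimulus_noise_rms_matches_shot_noise_model():
    # empirical dF/F RMS converges to noise_scale / sqrt(resting_light)
    cfg = SceneConfig(
        shape=(20, 20), n_frames=120, stim_time=30.0, n_trials=1,
        noise_scale=0.5, resting_light=900.0, seed=11,
    )
    stack, _ = render_trial_stack(cfg, [])
    dff = compute_dff(average_trials(stack), baseline_window=(0, 50))
    seg = dff.data[:50]  # 50 frames x 400 pixels = 20,000 samples
    rms = np.sqrt(np.mean(seg**2))
    assert rms == pytest.approx(cfg.noise_scale / np.sqrt(900.0), rel=0.05)


def test_default_footprint_spans_at_most_three_pixels():
    cfg = SceneConfig()
    mask = cell_mask(SynthCell(center=(40.0, 40.0), amplitude_true=0.005), cfg)
    rows, cols = np.nonzero(mask)
    assert np.ptp(rows) + 1 <= 3 and np.ptp(cols) + 1 <= 3


@pytest.mark.parametrize(
    "bad",
    [
        dict(center=(99.0, 5.0)),  # outside grid
        dict(center=(5.0, -1.0)),
    ],
)
def test_cell_outside_grid_raises(bad):
    cfg = SceneConfig(shape=(40, 40), n_frames=100)
    with pytest.raises(ValueError):
        render_trial_stack(cfg, [SynthCell(amplitude_true=0.005, **bad)])


def test_negative_resting_light_raises():
    cfg = SceneConfig(shape=(10, 10), n_frames=100, resting_light=-5.0)
    with pytest.raises(ValueError):
        render_trial_stack(cfg, [])


def test_overlapping_footprints_rejected_unless_allowed():
    cfg = SceneConfig(shape=(40, 40), n_frames=100)
    cells = [
        SynthCell(center=(20.0, 20.0), amplitude_true=0.005),
        SynthCell(center=(20.0, 21.0), amplitude_true=0.005),
    ]
    with pytest.raises(ValueError):
        render_trial_stack(cfg, cells)
    stack, _ = render_trial_stack(cfg, cells, allow_overlap=True)
    assert stack.data.shape[0] == cfg.n_trials


def test_ground_truth_latency_is_offset_plus_conduction():
    cfg = SceneConfig(electrode_um=(100.0, 100.0), conduction_delay_per_um=0.02)
    cell = SynthCell(center=(40.0, 40.0), amplitude_true=0.004, latency_offset=1.3)
    d = np.hypot(40 * cfg.pixel_pitch - 100, 40 * cfg.pixel_pitch - 100)
    assert true_latency(cell, cfg) == pytest.approx(1.3 + d * 0.02)


def test_scene_generators_are_deterministic_and_respect_constraints():
    cfg1, cells1 = random_scene(5, n_cells=4)
    cfg2, cells2 = random_scene(5, n_cells=4)
    assert [c.center for c in cells1] == [c.center for c in cells2]
    # spacing and electrode-distance constraints
    for i, a in enumerate(cells1):
        d_el = np.hypot(a.center[0] * cfg1.pixel_pitch - cfg1.electrode_um[0],
                        a.center[1] * cfg1.pixel_pitch - cfg1.electrode_um[1])
        assert d_el >= 60.0
        for b in cells1[i + 1:]:
            assert np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1]) >= 6.0
    _, rcells = recovery_scene(5, n_cells=4)
    assert all(c.amplitude_true > 0 for c in rcells)
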