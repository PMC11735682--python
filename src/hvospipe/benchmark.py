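"""Ground-truth benchmarks: detection recovery, calibration, power.

These routines rerun the full pipeline on seeded synthetic scenes and
score it against the generator's ground truth, or exercise the
statistical machinery on simulated cohorts at the group scales the
recordings report.  They are used by the acceptance checks and are
available to users as an end-to-end self-test.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .pipeline import RunConfig, analyze_slice
from .preprocess import BINOMIAL9, preprocess
from .simulate import SceneConfig, SynthCell, filter_attenuation, recovery_scene, render_trial_stack, true_latency
from .stats import bootstrap_anova, simulate_layer_units
from .waveform import make_epsp_waveform

__all__ = ["expected_filtered_params", "recovery_benchmark", "bootstrap_type1_error", "genotype_power"]


def expected_filtered_params(cell: SynthCell, config: SceneConfig, dt: float = 0.001) -> dict:
    """Expected extracted parameters for a cell, by brute force.

    Builds the true waveform on a dense (1 us) grid, applies the
    binomial-9 temporal kernel as a sum of shifted copies, and reads the
    peak and half-maximum crossings directly off the dense grid — no code
    shared with the sample-based extractor it benchmarks.
    """
    onset = config.stim_time + true_latency(cell, config)
    t = np.arange(0.0, config.n_frames * config.frame_interval, dt)
    base = make_epsp_waveform(cell.amplitude_true, cell.tau_rise, cell.tau_decay, onset, t)
    w = np.zeros_like(t)
    for i, b in enumerate(BINOMIAL9):
        w += b * np.interp(t - (i - 4) * config.frame_interval, t, base, left=0.0, right=0.0)
    pk = int(np.argmin(w))
    half = w[pk] / 2.0
    lead = t[:pk][np.nonzero(w[:pk] <= half)[0][0]]
    trail = t[pk:][np.nonzero(w[pk:] >= half)[0][0]]
    return {
        "amplitude": float(-w[pk]),
        "latency": float(lead - config.stim_time),
        "rise_time": float(t[pk] - lead),
        "decay_time": float(trail - t[pk]),
        "half_width": float(trail - lead),
    }


def recovery_benchmark(
    seed: int,
    n_scenes: int = 20,
    n_cells: int = 5,
    run_config: RunConfig | None = None,
    match_radius_px: float = 1.0,
) -> dict:
    """Detect and measure cells in seeded scenes; score against truth.

    A detected ROI matches a true cell when its centroid lies within
    ``match_radius_px`` of the cell's center (greedy, one match per cell).
    Timing errors are against :func:`expected_filtered_params`; amplitude
    errors are after dividing out the kernel-derived filter attenuation.
    """
    run_config = run_config or RunConfig()
    tp = fp = fn = 0
    errors = {k: [] for k in ("latency", "rise_time", "decay_time", "half_width")}
    amp_rel = []
    latencies, distances, true_delays = [], [], []
    hw_residuals = []
    pixel_counts = []
    for i in range(n_scenes):
        cfg, cells = recovery_scene(seed + i, n_cells=n_cells)
        stack, truth = render_trial_stack(cfg, cells)
        dff = preprocess(stack, sigma=run_config.spatial_sigma)
        rois, params, _ = analyze_slice(dff, run_config)
        centers = truth.centers_px()
        matched: set[int] = set()
        for roi in rois:
            if not roi.accepted:
                continue
            c = np.array(roi.group.centroid_px)
            d = np.linalg.norm(centers - c, axis=1)
            j = int(np.argmin(d))
            if d[j] <= match_radius_px and j not in matched:
                matched.add(j)
                tp += 1
                pixel_counts.append(len(roi.group.pixels))
                cell, p = cells[j], params[roi.roi_id]
                oracle = expected_filtered_params(cell, cfg)
                for key in errors:
                    errors[key].append(abs(getattr(p, key if key != "latency" else "latency") - oracle[key]))
                att = filter_attenuation(cell, cfg, pixels=roi.group.pixels)
                amp_rel.append(abs(p.amplitude / att - cell.amplitude_true) / cell.amplitude_true)
                latencies.append(p.latency)
                distances.append(p.distance)
                hw_residuals.append(abs(p.half_width - (p.rise_time + p.decay_time)))
            else:
                fp += 1
        fn += len(cells) - len(matched)
        true_delays.append(cfg.conduction_delay_per_um)
    pooled = np.concatenate([errors[k] for k in errors])
    slope = sps.linregress(distances, latencies).slope if len(distances) > 2 else np.nan
    return {
        "n_true": tp + fn,
        "n_accepted": tp + fp,
        "n_matched": tp,
        "recall": tp / (tp + fn) if tp + fn else np.nan,
        "precision": tp / (tp + fp) if tp + fp else np.nan,
        "median_timing_error_ms": float(np.median(pooled)),
        "median_errors_ms": {k: float(np.median(v)) for k, v in errors.items()},
        "amplitude_median_rel_error": float(np.median(amp_rel)),
        "conduction_delay_ms_per_um": float(slope),
        "conduction_delay_true": float(np.mean(true_delays)),
        "half_width_identity_max_residual_ms": float(np.max(hw_residuals)) if hw_residuals else np.nan,
        "mean_roi_pixels": float(np.mean(pixel_counts)) if pixel_counts else np.nan,
    }


#: unit-level SDs implied by the printed group standard errors (SE * sqrt(n))
_AMP_SD = (0.020 * np.sqrt(55), 0.031 * np.sqrt(54))


def bootstrap_type1_error(
    seed: int, n_reps: int = 500, B: int = 1000, alpha: float = 0.05
) -> dict:
    """Type-I error of the parametric-bootstrap ANOVA under a
    heteroscedastic null (equal means, the two genotypes' amplitude SDs).

    The common null mean sits far above zero: the cohort simulator
    truncates amplitudes at zero, and with unequal SDs a mean near the
    boundary would acquire a genotype mean *difference* from truncation
    alone, contaminating the null.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for i in range(n_reps):
        units = simulate_layer_units(
            seed=int(rng.integers(2**31 - 1)),
            amplitude_means=(5.0, 5.0),
            amplitude_se=(_AMP_SD[0] / np.sqrt(55), _AMP_SD[1] / np.sqrt(54)),
        )
        res = bootstrap_anova(
            units, "amplitude_pct", ["genotype"], "genotype", B=B,
            seed=int(rng.integers(2**31 - 1)), include_interactions=False,
            transform="identity",
        )
        rejections += res.p_value < alpha
    return {"rate": rejections / n_reps, "n_reps": n_reps, "B": B}


def genotype_power(
    seed: int, n_reps: int = 200, B: int = 1000, alpha: float = 0.05
) -> dict:
    """Power to detect the printed genotype separations at n = 55 vs 54.

    Each simulated cohort carries both printed effects; amplitude is
    tested with the bootstrap ANOVA (its heteroscedastic branch) and
    distance-normalized latency with a classical F test on the log scale.
    The cohort-level detection counts a cohort when either test rejects.
    """
    rng = np.random.default_rng(seed)
    hits_amp = hits_lat = hits_either = 0
    for i in range(n_reps):
        units = simulate_layer_units(seed=int(rng.integers(2**31 - 1)))
        res = bootstrap_anova(
            units, "amplitude_pct", ["genotype"], "genotype", B=B,
            seed=int(rng.integers(2**31 - 1)), include_interactions=False,
            transform="identity",
        )
        a = np.log(units[units.genotype == "WT"]["dn_latency_ms_per_um"])
        b = np.log(units[units.genotype == "cKO"]["dn_latency_ms_per_um"])
        p_lat = sps.f_oneway(a, b).pvalue
        amp_hit = res.p_value < alpha
        lat_hit = p_lat < alpha
        hits_amp += amp_hit
        hits_lat += lat_hit
        hits_either += amp_hit or lat_hit
    return {
        "power_amplitude": hits_amp / n_reps,
        "power_dn_latency": hits_lat / n_reps,
        "power_either": hits_either / n_reps,
        "n_reps": n_reps,
        "B": B,
    }
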