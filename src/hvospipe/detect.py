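"""Automatic single-neuron ROI detection from dF/F movies.

Responsive PV interneurons are found as small contiguous groups of pixels
whose stimulus-evoked fluorescence *decrease* exceeds both an amplitude
cutoff and an SNR cutoff, followed by the full chain of inclusion /
exclusion rules:

* 1-D k-means clustering of suprathreshold pixel SNRs; pixels in clusters
  whose mean SNR falls below 5 are dropped (they may sit at a cell's edge).
* size rule: a group wider than 3 pixels in either bounding-box dimension,
  or with area above 360 um^2, is larger than a PV soma and is rejected.
* adjacency rule: two groups that touch even at a single vertex
  (8-neighborhood contact) are BOTH rejected to avoid mixing neurons.
* direct-stimulation rule: centroid within 45 um of the electrode, or
  response latency below 1 ms, means likely direct (non-synaptic)
  activation -> rejected.
* amplitude outliers: cells more than 3 SD above the dataset mean
  amplitude (a one-sided, single-pass rule) are rejected.

Contiguity of a group uses 4-connectivity; "bordering" for the mutual
exclusion uses 8-connectivity — the stricter reading that a shared vertex
already disqualifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .kmeans1d import kmeans_1d
from .preprocess import DffMovie, baseline_rms_map

__all__ = [
    "PixelMap",
    "CandidateGroup",
    "ROI",
    "REJECTION_REASONS",
    "build_maps",
    "threshold_and_group",
    "kmeans_snr_exclude",
    "size_exclusion",
    "adjacency_exclusion",
    "direct_stimulation_exclusion",
    "amplitude_outlier_exclusion",
    "detect_candidates",
    "default_response_window",
]

REJECTION_REASONS = (
    "none",
    "too_large",
    "adjacent_group",
    "low_snr_cluster",
    "near_electrode",
    "short_latency",
    "amplitude_outlier",
    "noisy_waveform",
)


@dataclass
class PixelMap:
    values: np.ndarray  # (H, W)
    kind: str  # "amplitude" | "snr"


@dataclass
class CandidateGroup:
    pixels: list[tuple[int, int]]
    mean_snr: float
    mean_amplitude: float

    @property
    def bbox_extent(self) -> tuple[int, int]:
        rows = [p[0] for p in self.pixels]
        cols = [p[1] for p in self.pixels]
        return (max(rows) - min(rows) + 1, max(cols) - min(cols) + 1)

    @property
    def centroid_px(self) -> tuple[float, float]:
        arr = np.asarray(self.pixels, dtype=float)
        return tuple(arr.mean(axis=0))

    def centroid_um(self, pixel_pitch: float) -> tuple[float, float]:
        r, c = self.centroid_px
        return (r * pixel_pitch, c * pixel_pitch)

    def area_um2(self, pixel_pitch: float) -> float:
        return len(self.pixels) * pixel_pitch**2


@dataclass
class ROI:
    """A candidate group with its accept/reject provenance and trace."""

    roi_id: int
    group: CandidateGroup
    accepted: bool = True
    rejection_reason: str = "none"
    trace: np.ndarray | None = None

    def reject(self, reason: str) -> None:
        if reason not in REJECTION_REASONS or reason == "none":
            raise ValueError(f"unknown rejection reason {reason!r}")
        # the first rule to fire wins; each ROI carries exactly one reason
        if self.accepted:
            self.accepted = False
            self.rejection_reason = reason


def default_response_window(movie: DffMovie, length_ms: float = 50.0) -> tuple[int, int]:
    """Frames from the stimulus to stim + 50 ms (clipped to the record)."""
    dt = movie.frame_interval
    start = int(np.ceil(movie.stim_time / dt))
    stop = min(movie.n_frames, int(np.floor((movie.stim_time + length_ms) / dt)) + 1)
    return start, stop


def build_maps(
    movie: DffMovie, response_window: tuple[int, int] | None = None
) -> tuple[PixelMap, PixelMap, np.ndarray]:
    """Peak-amplitude and SNR maps from the filtered movie.

    amplitude = max negative-going |dF/F| inside the response window;
    SNR = amplitude / prestimulus RMS.  Zero-RMS pixels get SNR = inf and
    are excluded from clustering by the caller.  Returns the RMS map too.
    """
    if response_window is None:
        response_window = default_response_window(movie)
    start, stop = response_window
    if start * movie.frame_interval < movie.stim_time:
        raise ValueError("response window must start at or after the stimulus")
    window = movie.data[start:stop]
    amplitude = np.maximum(0.0, -window.min(axis=0))
    rms = baseline_rms_map(movie)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(rms > 0, amplitude / np.where(rms > 0, rms, 1.0), np.inf)
    snr = np.where(amplitude == 0, 0.0, snr)
    if movie.excluded_pixels is not None:
        amplitude[movie.excluded_pixels] = 0.0
        snr[movie.excluded_pixels] = 0.0
    return PixelMap(amplitude, "amplitude"), PixelMap(snr, "snr"), rms


_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def _groups_from_mask(mask: np.ndarray, amp: np.ndarray, snr: np.ndarray) -> list[CandidateGroup]:
    labeled, n = ndimage.label(mask, structure=_FOUR_CONN)
    groups = []
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labeled == lab)
        pixels = sorted(zip(rows.tolist(), cols.tolist()))
        sel = (rows, cols)
        groups.append(
            CandidateGroup(
                pixels=pixels,
                mean_snr=float(np.mean(snr[sel])),
                mean_amplitude=float(np.mean(amp[sel])),
            )
        )
    # deterministic order: by first (top-left) pixel
    groups.sort(key=lambda g: g.pixels[0])
    return groups


def threshold_and_group(
    amplitude_map: PixelMap,
    snr_map: PixelMap,
    amp_cutoff: float,
    snr_cutoff: float,
) -> list[CandidateGroup]:
    """Pixels passing BOTH cutoffs, grouped by 4-connectivity."""
    if amp_cutoff <= 0 or snr_cutoff <= 0:
        raise ValueError("cutoffs must be positive")
    amp, snr = amplitude_map.values, snr_map.values
    mask = (amp > amp_cutoff) & (snr > snr_cutoff) & np.isfinite(snr)
    return _groups_from_mask(mask, amp, snr)


def kmeans_snr_exclude(
    snr_values: np.ndarray, k: int = 4, cluster_mean_cutoff: float = 5.0
) -> np.ndarray:
    """Boolean survival mask over pixels after k-means SNR clustering.

    Pixels falling in clusters whose mean SNR is below the cutoff are
    excluded.  With fewer pixels than k, falls back to testing the single
    pooled cluster against the cutoff.
    """
    snr_values = np.asarray(snr_values, dtype=float).ravel()
    if snr_values.size == 0:
        return np.zeros(0, dtype=bool)
    if snr_values.size < k or k < 2:
        return np.repeat(snr_values.mean() >= cluster_mean_cutoff, snr_values.size)
    labels, centers, _ = kmeans_1d(snr_values, k)
    good_clusters = np.nonzero(centers >= cluster_mean_cutoff)[0]
    return np.isin(labels, good_clusters)


def size_exclusion(
    groups: list[CandidateGroup],
    pixel_pitch: float,
    max_extent_px: int = 3,
    max_area_um2: float = 360.0,
) -> tuple[list[CandidateGroup], list[CandidateGroup]]:
    """Split groups into (kept, too_large) by the PV-soma size rule."""
    if pixel_pitch <= 0:
        raise ValueError("pixel_pitch must be positive")
    kept, removed = [], []
    for g in groups:
        er, ec = g.bbox_extent
        if er > max_extent_px or ec > max_extent_px or g.area_um2(pixel_pitch) > max_area_um2:
            removed.append(g)
        else:
            kept.append(g)
    return kept, removed


def _touch_8(a: CandidateGroup, b: CandidateGroup) -> bool:
    pb = set(b.pixels)
    for r, c in a.pixels:
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if (r + dr, c + dc) in pb:
                    return True
    return False


def adjacency_exclusion(
    groups: list[CandidateGroup],
) -> tuple[list[CandidateGroup], list[CandidateGroup]]:
    """Remove BOTH members of any pair in 8-neighbor (edge or vertex) contact."""
    bad = set()
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            if _touch_8(groups[i], groups[j]):
                bad.update((i, j))
    kept = [g for i, g in enumerate(groups) if i not in bad]
    removed = [g for i, g in enumerate(groups) if i in bad]
    return kept, removed


def direct_stimulation_exclusion(
    rois: list[ROI],
    electrode_um: tuple[float, float],
    latencies_ms: dict[int, float],
    pixel_pitch: float,
    min_distance_um: float = 45.0,
    min_latency_ms: float = 1.0,
) -> None:
    """Reject ROIs near the electrode or with sub-millisecond latency.

    Both thresholds are strict inequalities: distance 45 um or latency
    exactly 1 ms survive.  Operates in place on accepted ROIs.
    """
    for roi in rois:
        if not roi.accepted:
            continue
        cy, cx = roi.group.centroid_um(pixel_pitch)
        dist = float(np.hypot(cy - electrode_um[0], cx - electrode_um[1]))
        if dist < min_distance_um:
            roi.reject("near_electrode")
            continue
        lat = latencies_ms.get(roi.roi_id)
        if lat is not None and lat < min_latency_ms:
            roi.reject("short_latency")


def amplitude_outlier_exclusion(
    rois: list[ROI], amplitudes: dict[int, float], n_sd: float = 3.0
) -> None:
    """Single-pass, one-sided outlier rule over the pooled dataset.

    Cells whose amplitude exceeds mean + n_sd * SD (sample SD over all
    currently accepted cells) are rejected; low outliers are kept.
    """
    ids = [r.roi_id for r in rois if r.accepted and r.roi_id in amplitudes]
    if len(ids) < 3:
        return
    vals = np.array([amplitudes[i] for i in ids])
    mean, sd = vals.mean(), vals.std(ddof=1)
    cutoff = mean + n_sd * sd
    for roi in rois:
        if roi.accepted and amplitudes.get(roi.roi_id, -np.inf) > cutoff:
            roi.reject("amplitude_outlier")


def select_group_snr_level(
    group: CandidateGroup,
    snr_map_values: np.ndarray,
    k: int = 4,
    merge_ratio: float = 0.8,
) -> list[tuple[int, int]]:
    """Pixels of the group's top SNR level (per-group 1-D k-means).

    Spatial smoothing bleeds a bright soma's signal into a fringe of
    lower-SNR pixels; an ROI keeps only pixels within the same (highest)
    SNR level so the fringe — possibly another cell's edge — is dropped.
    Clusters whose mean reaches ``merge_ratio`` of the top cluster's mean
    count as the same level (k-means splits noise-jittered near-equal
    core pixels into separate clusters otherwise).
    """
    if len(group.pixels) <= 1:
        return list(group.pixels)
    vals = np.array([snr_map_values[p] for p in group.pixels])
    kk = min(k, len(vals))
    labels, centers, _ = kmeans_1d(vals, kk)
    top_level = {j for j, c in enumerate(centers) if c >= merge_ratio * centers.max()}
    return [p for p, lab in zip(group.pixels, labels) if lab in top_level]


def detect_candidates(
    movie: DffMovie,
    amp_cutoff: float | None = None,
    amp_cutoff_mult: float = 7.0,
    snr_cutoff: float = 5.0,
    k: int = 4,
    cluster_mean_cutoff: float = 5.0,
    response_window: tuple[int, int] | None = None,
    max_extent_px: int = 3,
    max_area_um2: float = 360.0,
) -> tuple[list[ROI], dict]:
    """Map -> threshold -> adjacency -> k-means exclusions -> size rule.

    The amplitude cutoff defaults to ``amp_cutoff_mult`` x the median
    prestimulus RMS, placed above the extreme-value tail of the filtered
    noise over the response window.  Candidate groups are judged for
    mutual adjacency at their full (pre-shrink) extent; each surviving
    group is then reduced to its top SNR level (see
    :func:`select_group_snr_level`) after the global cluster-mean >= 5
    exclusion, and finally size-checked.  Returns ROIs carrying their
    pixel-averaged traces and a first-rule-wins rejection reason; the
    extraction-based rules (latency / electrode distance / outliers) are
    applied later by the pipeline once kinetics are known.
    """
    amp_map, snr_map, rms = build_maps(movie, response_window)
    if amp_cutoff is None:
        amp_cutoff = amp_cutoff_mult * float(np.median(rms))
        if amp_cutoff <= 0:
            amp_cutoff = 1e-12
    candidates = threshold_and_group(amp_map, snr_map, amp_cutoff, snr_cutoff)
    diagnostics = {
        "amp_cutoff": amp_cutoff,
        "snr_cutoff": snr_cutoff,
        "k": k,
        "n_candidates": len(candidates),
    }

    # mutual adjacency on the full candidate extents (distinct neurons)
    _, removed_adj = adjacency_exclusion(candidates)
    adj_ids = {i for i, g in enumerate(candidates) if g in removed_adj}

    # global k-means on all suprathreshold pixel SNRs: clusters with mean
    # SNR below the cutoff are excluded wholesale
    all_pixels = [p for g in candidates for p in g.pixels]
    if all_pixels:
        snr_vals = np.array([snr_map.values[p] for p in all_pixels])
        survive = kmeans_snr_exclude(snr_vals, k=k, cluster_mean_cutoff=cluster_mean_cutoff)
        surviving = {p for p, s in zip(all_pixels, survive) if s}
    else:
        surviving = set()

    rois: list[ROI] = []
    for i, g in enumerate(candidates):
        keep = [p for p in g.pixels if p in surviving]
        if not keep:
            roi = ROI(roi_id=i, group=_empty_group(g))
            roi.reject("low_snr_cluster")
            rois.append(roi)
            continue
        sub = CandidateGroup(
            pixels=sorted(keep),
            mean_snr=float(np.mean([snr_map.values[p] for p in keep])),
            mean_amplitude=float(np.mean([amp_map.values[p] for p in keep])),
        )
        level = select_group_snr_level(sub, snr_map.values, k=k)
        comps = _groups_from_mask(
            _pixels_to_mask(level, movie.data.shape[1:]), amp_map.values, snr_map.values
        )
        best = max(comps, key=lambda s: (s.mean_snr, len(s.pixels)))
        roi = ROI(roi_id=i, group=best)
        if i in adj_ids:
            roi.reject("adjacent_group")
        else:
            er, ec = best.bbox_extent
            if (
                er > max_extent_px
                or ec > max_extent_px
                or best.area_um2(movie.pixel_pitch) > max_area_um2
            ):
                roi.reject("too_large")
        idx = tuple(np.array(best.pixels).T)
        roi.trace = movie.data[:, idx[0], idx[1]].mean(axis=1)
        rois.append(roi)

    diagnostics["n_accepted_spatial"] = sum(r.accepted for r in rois)
    return rois, diagnostics


def _pixels_to_mask(pixels: list[tuple[int, int]], shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for r, c in pixels:
        mask[r, c] = True
    return mask


def _empty_group(original: CandidateGroup) -> CandidateGroup:
    # pruned-away group: keep the original pixel footprint for provenance
    return CandidateGroup(
        pixels=list(original.pixels),
        mean_snr=original.mean_snr,
        mean_amplitude=original.mean_amplitude,
    )
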