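"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by the most direct method available
(exhaustive search, flood fill, dense-grid evaluation) so the pipeline's
optimized implementations can be checked against something that shares
no code with them.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from hvospipe.preprocess import BINOMIAL9
from hvospipe.simulate import SceneConfig, SynthCell, true_latency
from hvospipe.waveform import make_epsp_waveform


def brute_force_kmeans_cost(values: np.ndarray, k: int) -> float:
    """Exhaustive optimum over all contiguous partitions of sorted data."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size

    def block(i, j):
        seg = x[i:j]
        return float(np.sum((seg - seg.mean()) ** 2))

    best = np.inf
    for cuts in combinations(range(1, n), k - 1):
        bounds = (0,) + cuts + (n,)
        cost = sum(block(bounds[i], bounds[i + 1]) for i in range(k))
        best = min(best, cost)
    return best


def flood_fill_groups(mask: np.ndarray) -> list[set[tuple[int, int]]]:
    """4-connected components by explicit flood fill."""
    seen = np.zeros_like(mask, dtype=bool)
    groups = []
    h, w = mask.shape
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                comp = set()
                stack = [(r, c)]
                seen[r, c] = True
                while stack:
                    rr, cc = stack.pop()
                    comp.add((rr, cc))
                    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] and not seen[nr, nc]:
                            seen[nr, nc] = True
                            stack.append((nr, nc))
                groups.append(comp)
    return groups


def dense_grid_epsp_params(cell: SynthCell, config: SceneConfig, dt: float = 0.001) -> dict:
    """Expected extracted parameters of the binomial-filtered true waveform,
    found by brute force on a dense (1 us) time grid."""
    lat = true_latency(cell, config)
    onset = config.stim_time + lat
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


def gaussian_kernel_2d(sigma: float, radius: int) -> np.ndarray:
    """Explicit sampled-and-normalized Gaussian kernel (what a sigma-pixel
    smoother applies away from borders)."""
    ax = np.arange(-radius, radius + 1)
    g = np.exp(-(ax**2) / (2 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def levene_by_hand(groups: list[np.ndarray]) -> tuple[float, float]:
    """Levene's W (center = mean) computed from its textbook formula."""
    from scipy.stats import f as fdist

    k = len(groups)
    z = [np.abs(g - g.mean()) for g in groups]
    n = sum(len(g) for g in groups)
    zbar = np.concatenate(z).mean()
    zibar = [zi.mean() for zi in z]
    num = (n - k) * sum(len(g) * (zb - zbar) ** 2 for g, zb in zip(groups, zibar))
    den = (k - 1) * sum(np.sum((zi - zb) ** 2) for zi, zb in zip(z, zibar))
    w = num / den
    p = float(fdist.sf(w, k - 1, n - k))
    return float(w), p


def welch_by_hand(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch t and Satterthwaite df from their definitions."""
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va / na + vb / nb)
    df = (va / na + vb / nb) ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return float(t), float(df)


def balanced_oneway_f(groups: list[np.ndarray]) -> float:
    """One-way ANOVA F from the between/within sum-of-squares ratio."""
    k = len(groups)
    n = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(np.sum((g - g.mean()) ** 2) for g in groups)
    return float((ss_between / (k - 1)) / (ss_within / (n - k)))
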