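"""Calcium-imaging statistics: dF/F traces, per-pixel activity maps,
population sparseness and inter-odour correlations.

Population sparseness follows the Vinje-Gallant / Willmore-Tolhurst
statistic

    SP = (1 / (1 - 1/N)) * (1 - (sum r_i / N)^2 / (sum r_i^2 / N))

over the N valid pixels of an activity map: 0 for a uniform response,
exactly 1 for a single responsive pixel.  Negative dF/F pixels are used
as-is (no response threshold is applied); the [0, 1] bound is only
guaranteed for non-negative maps, and maps dominated by negative values
are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


class ImagingError(ValueError):
    pass


@dataclass
class ActivityMap:
    """Per-pixel dF/F response map with its baseline image and mask."""

    dff: np.ndarray
    baseline: np.ndarray
    mask: np.ndarray
    rejected_frames: list = field(default_factory=list)  # (index, correlation)
    negative_dominated: bool = False

    def __post_init__(self):
        if self.dff.shape != self.mask.shape or self.dff.shape != self.baseline.shape:
            raise ImagingError("map, baseline and mask must share a shape")
        self.negative_dominated = bool(np.nansum(self.dff[self.mask]) < 0)


@dataclass(frozen=True)
class SparsenessResult:
    sp: float
    n: int
    masked_pixels: int


def dff_trace(
    f_signal: np.ndarray, f_background: np.ndarray, t_s: np.ndarray,
    stim_window_s: tuple, boxcar_s: float = 0.2,
):
    """Background-subtracted, boxcar-smoothed dF/F trace and mean response.

    Baseline is the mean background-subtracted fluorescence before
    stimulus onset.  Returns (dff, mean_dff_during_stim).
    """
    f = np.asarray(f_signal, float) - np.asarray(f_background, float)
    t_s = np.asarray(t_s, float)
    pre = f[t_s < stim_window_s[0]]
    if len(pre) == 0:
        raise ImagingError("no pre-stimulus frames")
    f0 = pre.mean()
    if f0 == 0:
        raise ImagingError("all-zero baseline fluorescence")
    dff = (f - f0) / f0
    frame_dt = float(np.median(np.diff(t_s)))
    w = max(1, int(round(boxcar_s / frame_dt)))
    if w > 1:
        if w % 2 == 0:
            w += 1
        dff = np.convolve(dff, np.ones(w) / w, mode="same")
    stim = (t_s >= stim_window_s[0]) & (t_s < stim_window_s[1])
    return dff, float(dff[stim].mean())


def resample_traces(traces: list, target_rate_hz: float):
    """Linearly interpolate (t, y) traces to a common frame rate and average.

    Used when traces acquired at different frame times must be averaged.
    Returns (t_common, mean_trace).
    """
    t0 = max(t[0] for t, _ in traces)
    t1 = min(t[-1] for t, _ in traces)
    t_common = np.arange(t0, t1, 1.0 / target_rate_hz)
    ys = [np.interp(t_common, t, y) for t, y in traces]
    return t_common, np.mean(ys, axis=0)


def activity_map(
    movie: np.ndarray, stim_frames: slice | np.ndarray,
    baseline_frames: slice | np.ndarray, rejection_threshold: float = 0.0,
    gaussian_sigma_px: float = 2.0, kernel_px: int = 5,
) -> ActivityMap:
    """Per-pixel dF/F map from a (T, H, W) movie.

    Frames are smoothed with a kernel_px-square Gaussian filter
    (sigma 2 px, reflect edges); frames whose correlation with the
    baseline image falls below the rejection threshold are discarded
    (sudden axial movement).  dF/F = (stim mean - baseline)/baseline
    per pixel, with no thresholding of low-responding pixels.
    """
    movie = np.asarray(movie, float)
    if movie.ndim != 3:
        raise ImagingError("movie must be (frames, height, width)")
    truncate = (kernel_px // 2) / gaussian_sigma_px
    sm = np.stack([
        ndimage.gaussian_filter(f, gaussian_sigma_px, mode="reflect",
                                truncate=truncate)
        for f in movie
    ])
    idx = np.arange(movie.shape[0])
    base_idx = idx[baseline_frames]
    stim_idx = idx[stim_frames]
    if len(base_idx) == 0:
        raise ImagingError("no pre-stimulus frames")
    baseline = sm[base_idx].mean(axis=0)
    bflat = baseline.ravel()

    def corr(frame):
        f = frame.ravel()
        sb, sf = bflat.std(), f.std()
        if sb == 0 or sf == 0:
            return 1.0 if np.allclose(f, bflat) else 0.0
        return float(np.corrcoef(f, bflat)[0, 1])

    corrs = np.array([corr(sm[i]) for i in idx])
    keep = corrs >= rejection_threshold
    rejected = [(int(i), float(corrs[i])) for i in idx[~keep]]
    base_keep = [i for i in base_idx if keep[i]]
    stim_keep = [i for i in stim_idx if keep[i]]
    if len(base_keep) == 0 or len(stim_keep) == 0:
        raise ImagingError("all frames rejected")
    baseline = sm[base_keep].mean(axis=0)
    if np.any(baseline == 0):
        raise ImagingError("zero baseline fluorescence in some pixels")
    dff = (sm[stim_keep].mean(axis=0) - baseline) / baseline
    return ActivityMap(dff=dff, baseline=baseline,
                       mask=np.ones_like(dff, dtype=bool),
                       rejected_frames=rejected)


def population_sparseness(amap: ActivityMap | np.ndarray,
                          mask: np.ndarray | None = None) -> SparsenessResult:
    """Population sparseness SP of an activity map (see module docstring)."""
    if isinstance(amap, ActivityMap):
        r = amap.dff[amap.mask if mask is None else mask]
    else:
        r = np.asarray(amap, float)
        if mask is not None:
            r = r[mask]
        else:
            r = r.ravel()
    n = r.size
    if n < 2:
        raise ImagingError("need at least two valid pixels")
    meansq = float((r ** 2).mean())
    if meansq == 0:
        raise ImagingError("all-zero activity map: sparseness undefined")
    sp = (1.0 - r.mean() ** 2 / meansq) / (1.0 - 1.0 / n)
    return SparsenessResult(sp=float(sp), n=n, masked_pixels=n)


def _shift2d(img: np.ndarray, dy: int, dx: int) -> np.ndarray:
    return np.roll(np.roll(img, dy, axis=0), dx, axis=1)


def align_by_baseline(
    maps: list[ActivityMap], max_shift_px: int = 10,
) -> list[tuple[int, int]]:
    """Integer-pixel translations maximizing baseline correlation vs map 0."""
    ref = maps[0].baseline.ravel()
    shifts = [(0, 0)]
    for am in maps[1:]:
        if ref.std() == 0 or am.baseline.std() == 0:
            shifts.append((0, 0))  # featureless baseline: nothing to align on
            continue
        best, best_c = (0, 0), -np.inf
        for dy in range(-max_shift_px, max_shift_px + 1):
            for dx in range(-max_shift_px, max_shift_px + 1):
                c = np.corrcoef(_shift2d(am.baseline, dy, dx).ravel(), ref)[0, 1]
                if c > best_c:
                    best_c, best = c, (dy, dx)
        shifts.append(best)
    return shifts


def inter_odour_correlation(
    maps: list[ActivityMap], baseline_threshold: float,
    max_shift_px: int = 10, extra_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Pairwise Pearson correlations between aligned, masked odour maps.

    Maps are first aligned by the integer translation that maximizes the
    correlation of their baseline images; a baseline-fluorescence
    threshold masks out pixels with no indicator signal (the threshold
    is a required parameter — it is preparation-specific); an optional
    extra mask removes manually excluded regions.  Returns the symmetric
    correlation matrix with unit diagonal.
    """
    if len(maps) < 2:
        raise ImagingError("need at least two maps")
    shape = maps[0].dff.shape
    if any(m.dff.shape != shape for m in maps):
        raise ImagingError("maps must share a common shape")
    shifts = align_by_baseline(maps, max_shift_px)
    dffs = [_shift2d(m.dff, dy, dx) for m, (dy, dx) in zip(maps, shifts)]
    bases = [_shift2d(m.baseline, dy, dx) for m, (dy, dx) in zip(maps, shifts)]
    masks = [_shift2d(m.mask, dy, dx) for m, (dy, dx) in zip(maps, shifts)]
    mask = np.logical_and.reduce([b > baseline_threshold for b in bases])
    mask &= np.logical_and.reduce(masks)
    if extra_mask is not None:
        mask &= extra_mask
    if not mask.any():
        raise ImagingError("empty mask after thresholding")
    vecs = np.stack([d[mask] for d in dffs])
    cm = np.corrcoef(vecs)
    return cm
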