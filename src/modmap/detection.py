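"""Detection of large spontaneous events in ΔF/F movies.

A pixel is "active" when its ΔF/F exceeds a per-pixel threshold — either
3 SD above the pixel's mean, with mean and SD taken from a Gaussian fitted
to the sub-threshold bulk of the pixel's histogram (large transients are
excluded by truncating the fit at 1.5x the value of the modal bin), or the
80th percentile of the pixel's trace.  Two spatial criteria then define
active frames: active pixels must belong to a contiguous region of at least
0.01 mm², and an active frame must have more than 40% of ROI pixels active.
Consecutive active frames form events, split at interior local minima of
the ROI-mean activity; each event is represented by its maximally active
frame.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from skimage import measure

from .containers import EventCatalog, Movie, RoiMask

__all__ = [
    "PixelThresholdModel",
    "fit_truncated_gaussian",
    "fit_threshold_model",
    "classify_active_pixels",
    "apply_spatial_criteria",
    "segment_events",
    "detect_events",
]

log = logging.getLogger(__name__)

MIN_AREA_MM2 = 0.01
MIN_ACTIVE_FRACTION = 0.40


@dataclass
class PixelThresholdModel:
    """Per-pixel activity threshold.

    ``method`` is ``gaussian3sd`` (threshold = mu + 3 sigma from the
    truncated-Gaussian fit) or ``percentile80`` (threshold = 80th percentile
    of the pixel's trace).  Outside the ROI the threshold is +inf.
    """

    method: str
    threshold: np.ndarray
    mu: np.ndarray | None = None
    sigma: np.ndarray | None = None
    n_fallback: int = 0


def _truncated_gaussian_engine(
    x: np.ndarray, bin_width: float | None = None, n_iter: int = 12
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised truncated-Gaussian fit on columns of ``x`` (T, P).

    Per column: histogram the samples (Freedman–Diaconis width on the
    sub-95th-percentile bulk unless ``bin_width`` is given), locate the
    modal bin, keep only bins whose centers lie at or below 1.5x the modal
    bin's center value, and least-squares fit ``A exp(-(v-mu)^2/2 sigma^2)``
    to the retained bin counts (Gauss–Newton, log-parabola initialisation).

    Returns ``(mu, sigma, fallback)`` where ``fallback`` marks columns for
    which the fit failed and median/MAD estimates were substituted.
    """
    x = np.asarray(x, dtype=np.float64)
    t_len, p_len = x.shape
    xs = np.sort(x, axis=0)
    med = np.median(xs, axis=0)
    mad = np.median(np.abs(x - med), axis=0)
    fb_mu = med
    fb_sigma = 1.4826 * mad
    fallback = np.zeros(p_len, dtype=bool)

    lo = xs[0]
    hi = xs[min(t_len - 1, int(round(0.995 * (t_len - 1))))]
    if bin_width is None:
        n_bulk = int(round(0.95 * (t_len - 1))) + 1
        q25 = xs[int(0.25 * (n_bulk - 1))]
        q75 = xs[int(0.75 * (n_bulk - 1))]
        iqr = q75 - q25
        bw = 2.0 * iqr / n_bulk ** (1.0 / 3.0)
        bad_bw = ~(bw > 0)
        fallback |= bad_bw
        bw = np.where(bad_bw, 1.0, bw)
        nb = np.ceil((hi - lo) / bw).astype(int)
        nb = np.clip(nb, 8, 128)
        span_bad = ~(hi > lo)
        fallback |= span_bad
        bw = np.where(span_bad, 1.0, (hi - lo) / nb)
    else:
        if bin_width <= 0:
            raise ValueError("bin_width must be positive")
        bw = np.full(p_len, float(bin_width))
        nb = np.ceil(np.maximum(hi - lo, bw) / bw).astype(int)
        nb = np.clip(nb, 1, 512)

    nb_max = int(nb.max())
    idx = np.floor((x - lo[None, :]) / bw[None, :]).astype(np.int64)
    in_range = (idx >= 0) & (idx < nb[None, :])
    flat = np.where(in_range, idx + np.arange(p_len)[None, :] * nb_max, p_len * nb_max)
    counts = np.bincount(flat.ravel(), minlength=p_len * nb_max + 1)[:-1]
    counts = counts.reshape(p_len, nb_max).astype(np.float64)

    j = np.arange(nb_max)
    centers = lo[:, None] + (j[None, :] + 0.5) * bw[:, None]
    in_bins = j[None, :] < nb[:, None]
    mode_idx = np.argmax(counts, axis=1)
    mode_center = np.take_along_axis(centers, mode_idx[:, None], axis=1)[:, 0]
    # Truncate the fit at 1.5x the modal bin's position, measured from the
    # histogram origin: v = lo + 1.5 (mode - lo).  For positive-support data
    # (lo ~ 0) this is 1.5x the modal value; for baseline-centred ΔF/F it
    # keeps the bulk up to ~mode + 0.5 (mode - min) and excludes large
    # positive transients, which is the purpose of the truncation.
    v_trunc = lo + 1.5 * (mode_center - lo)
    retain = in_bins & (counts > 0) & (centers <= v_trunc[:, None])
    n_ret = retain.sum(axis=1)
    fallback |= n_ret < 4

    w = retain.astype(np.float64)
    # log-parabola (Caruana) initialisation
    z = np.where(retain, np.log(np.maximum(counts, 1e-12)), 0.0)
    c = np.where(retain, centers, 0.0)
    ata = np.empty((p_len, 3, 3))
    pw = [np.sum(w * c**k, axis=1) for k in range(5)]
    for a in range(3):
        for b in range(3):
            ata[:, a, b] = pw[a + b]
    atz = np.stack([np.sum(z * w * c**k, axis=1) for k in range(3)], axis=1)
    ok = np.linalg.cond(ata) < 1e12 if p_len else np.array([], bool)
    ok = np.isfinite(ok) & ok
    coef = np.zeros((p_len, 3))
    if np.any(ok):
        coef[ok] = np.linalg.solve(ata[ok], atz[ok][..., None])[..., 0]
    a2 = coef[:, 2]
    good = ok & (a2 < -1e-12)
    fallback |= ~good
    a2s = np.where(good, a2, -1.0)
    mu = np.where(good, -coef[:, 1] / (2 * a2s), fb_mu)
    sigma = np.where(good, np.sqrt(-1.0 / (2 * a2s)), np.maximum(fb_sigma, 1e-12))
    amp = np.where(good, np.exp(coef[:, 0] - coef[:, 1] ** 2 / (4 * a2s)), 1.0)

    # Gauss–Newton refinement of least squares on the retained bin counts
    active = good.copy()
    sig_floor = bw / 10.0
    for _ in range(n_iter):
        if not np.any(active):
            break
        u = (c - mu[:, None]) / sigma[:, None]
        e = np.exp(-0.5 * u * u) * w
        model = amp[:, None] * e
        r = model - counts * w
        j1 = e
        j2 = model * u / sigma[:, None]
        j3 = model * u * u / sigma[:, None]
        g = np.empty((p_len, 3, 3))
        g[:, 0, 0] = np.sum(j1 * j1, axis=1)
        g[:, 0, 1] = g[:, 1, 0] = np.sum(j1 * j2, axis=1)
        g[:, 0, 2] = g[:, 2, 0] = np.sum(j1 * j3, axis=1)
        g[:, 1, 1] = np.sum(j2 * j2, axis=1)
        g[:, 1, 2] = g[:, 2, 1] = np.sum(j2 * j3, axis=1)
        g[:, 2, 2] = np.sum(j3 * j3, axis=1)
        g += 1e-9 * np.eye(3)[None, :, :]
        rhs = -np.stack(
            [np.sum(j1 * r, axis=1), np.sum(j2 * r, axis=1), np.sum(j3 * r, axis=1)], axis=1
        )
        step = np.zeros((p_len, 3))
        solvable = active & (np.linalg.cond(g) < 1e12)
        if np.any(solvable):
            step[solvable] = np.linalg.solve(g[solvable], rhs[solvable][..., None])[..., 0]
        # conservative step limits keep the iteration inside the histogram
        step[:, 1] = np.clip(step[:, 1], -5 * bw, 5 * bw)
        step[:, 2] = np.clip(step[:, 2], -5 * bw, 5 * bw)
        amp = np.where(active, np.maximum(amp + step[:, 0], 1e-12), amp)
        mu = np.where(active, mu + step[:, 1], mu)
        sigma = np.where(active, np.maximum(sigma + step[:, 2], sig_floor), sigma)

    bad_final = ~np.isfinite(mu) | ~np.isfinite(sigma) | (sigma <= 0)
    fallback |= bad_final
    mu = np.where(fallback, fb_mu, mu)
    sigma = np.where(fallback, np.maximum(fb_sigma, 1e-12), sigma)
    return mu, sigma, fallback


def fit_truncated_gaussian(
    trace: np.ndarray, bin_width: float | None = None
) -> tuple[float, float]:
    """Fit mean and SD of one pixel's sub-event ΔF/F distribution.

    See :func:`_truncated_gaussian_engine` for the procedure.  Raises on
    degenerate (constant) traces; falls back to median/MAD with a warning
    if the Gaussian fit fails.
    """
    trace = np.asarray(trace, dtype=float).ravel()
    if trace.size < 100:
        raise ValueError("trace must contain at least 100 samples")
    if np.ptp(trace) == 0:
        raise ValueError("constant trace: Gaussian fit undefined")
    mu, sigma, fb = _truncated_gaussian_engine(trace[:, None], bin_width=bin_width)
    if fb[0]:
        warnings.warn("truncated-Gaussian fit failed; using median/MAD estimates")
    return float(mu[0]), float(sigma[0])


def fit_threshold_model(
    dff: Movie,
    method: str = "gaussian3sd",
    roi: RoiMask | None = None,
    bin_width: float | None = None,
) -> PixelThresholdModel:
    """Fit the per-pixel activity threshold for a ΔF/F movie."""
    if dff.kind != "dff":
        raise ValueError("threshold model expects a ΔF/F movie")
    h, w = dff.frame_shape
    inside = roi.mask if roi is not None else np.ones((h, w), dtype=bool)
    data = dff.data.reshape(dff.n_frames, -1)
    cols = np.flatnonzero(inside.ravel())
    threshold = np.full(h * w, np.inf)
    if method == "gaussian3sd":
        mu_c, sigma_c, fb = _truncated_gaussian_engine(data[:, cols], bin_width=bin_width)
        n_fb = int(fb.sum())
        if n_fb:
            log.warning("truncated-Gaussian fit fell back to median/MAD for %d pixels", n_fb)
        mu = np.full(h * w, np.nan)
        sigma = np.full(h * w, np.nan)
        mu[cols] = mu_c
        sigma[cols] = sigma_c
        threshold[cols] = mu_c + 3.0 * sigma_c
        return PixelThresholdModel(
            method=method,
            threshold=threshold.reshape(h, w),
            mu=mu.reshape(h, w),
            sigma=sigma.reshape(h, w),
            n_fallback=n_fb,
        )
    elif method == "percentile80":
        threshold[cols] = np.percentile(data[:, cols], 80, axis=0)
        return PixelThresholdModel(method=method, threshold=threshold.reshape(h, w))
    raise ValueError(f"unknown detection method {method!r}")


def classify_active_pixels(dff: Movie, model: PixelThresholdModel) -> np.ndarray:
    """Boolean (T, H, W) stack: ΔF/F strictly above the per-pixel threshold."""
    if model.threshold.shape != dff.frame_shape:
        raise ValueError("threshold model grid does not match the movie")
    return dff.data > model.threshold[None, :, :]


def apply_spatial_criteria(
    active_frame: np.ndarray,
    roi: RoiMask,
    pixel_um: float,
    min_area_mm2: float = MIN_AREA_MM2,
    min_active_fraction: float = MIN_ACTIVE_FRACTION,
) -> tuple[np.ndarray, bool]:
    """Clean one frame's active-pixel mask and flag whether it is an active frame.

    Active pixels outside any 8-connected component of area >= ``min_area_mm2``
    are discarded (independent pixel noise); the frame is active iff strictly
    more than ``min_active_fraction`` of ROI pixels remain active.
    """
    if active_frame.shape != roi.mask.shape:
        raise ValueError("frame and ROI grids differ")
    am = active_frame & roi.mask
    min_px = int(np.ceil(min_area_mm2 * 1.0e6 / pixel_um**2))
    if am.any():
        labels = measure.label(am, connectivity=2)
        sizes = np.bincount(labels.ravel())
        keep = sizes >= min_px
        keep[0] = False
        cleaned = keep[labels]
    else:
        cleaned = am
    frac = cleaned.sum() / roi.n_pixels
    return cleaned, bool(frac > min_active_fraction)


def segment_events(active_flags: np.ndarray, mean_activity: np.ndarray) -> EventCatalog:
    """Combine runs of active frames into events.

    A run containing an interior local minimum of the ROI-mean activity is
    split there (the minimum frame closes the first event; plateaus of equal
    values resolve to the last frame of the plateau).  Each event's
    representative frame is the argmax of the mean activity within it.
    """
    active_flags = np.asarray(active_flags, dtype=bool)
    mean_activity = np.asarray(mean_activity, dtype=float)
    if active_flags.shape != mean_activity.shape:
        raise ValueError("active_flags and mean_activity must have the same length")
    intervals = []
    t = 0
    n = len(active_flags)
    while t < n:
        if not active_flags[t]:
            t += 1
            continue
        a = t
        while t + 1 < n and active_flags[t + 1]:
            t += 1
        b = t
        # split at interior local minima (descent, optional plateau, ascent)
        start = a
        i = a + 1
        while i < b:
            if mean_activity[i] < mean_activity[i - 1]:
                j = i
                while j + 1 <= b and mean_activity[j + 1] == mean_activity[i]:
                    j += 1
                if j < b and mean_activity[j + 1] > mean_activity[i]:
                    intervals.append((start, j))
                    start = j + 1
                    i = j + 1
                    continue
                i = j + 1
            else:
                i += 1
        intervals.append((start, b))
        t += 1
    rows = []
    for a, b in intervals:
        peak = a + int(np.argmax(mean_activity[a : b + 1]))
        rows.append((a, b, peak))
    return EventCatalog(intervals=np.array(rows, dtype=int).reshape(-1, 3))


def detect_events(
    dff: Movie,
    roi: RoiMask,
    method: str = "gaussian3sd",
    min_area_mm2: float = MIN_AREA_MM2,
    min_active_fraction: float = MIN_ACTIVE_FRACTION,
    bin_width: float | None = None,
) -> EventCatalog:
    """Full event-detection chain on a ΔF/F movie.

    Returns the catalog with the raw (unfiltered) ΔF/F pattern of each
    event's maximally active frame attached.
    """
    model = fit_threshold_model(dff, method=method, roi=roi, bin_width=bin_width)
    active = classify_active_pixels(dff, model)
    roi_flat = roi.mask
    n_roi = roi.n_pixels
    mean_activity = dff.data[:, roi_flat].mean(axis=1)
    flags = np.zeros(dff.n_frames, dtype=bool)
    raw_frac = (active & roi_flat[None]).sum(axis=(1, 2)) / n_roi
    for t in np.flatnonzero(raw_frac > min_active_fraction):
        _, flags[t] = apply_spatial_criteria(
            active[t], roi, dff.pixel_um, min_area_mm2, min_active_fraction
        )
    catalog = segment_events(flags, mean_activity)
    catalog.n_active_frames = int(flags.sum())
    if len(catalog):
        catalog.event_frames_raw = dff.data[catalog.event_frames].astype(np.float32)
    else:
        catalog.event_frames_raw = np.empty((0, *dff.frame_shape), dtype=np.float32)
    return catalog
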