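"""Per-event pattern metrics: wavelength, modularity, module amplitude, and
the bootstrap test of modularity against low-activity control frames.

The wavelength Λ of an event is read from the 1-D radial average of the
spatial autocorrelation of its band-passed pattern: the radius of the first
local minimum is Λ/2.  Modularity is the absolute amplitude difference
between that first minimum and the subsequent maximum — a measure of how
regularly the active domains are spaced.  Module amplitude is computed on
the raw (unfiltered) ΔF/F event frame as peak activity divided by the
median activity half a wavelength away from the peak.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import ndimage

from .containers import (
    EventCatalog,
    ModularitySignificance,
    Movie,
    PatternSet,
    RadialProfile,
    RoiMask,
)
from .filtering import build_pattern_set

__all__ = [
    "radial_autocorrelation",
    "wavelength_and_modularity",
    "module_amplitude",
    "event_metrics_table",
    "modularity_significance",
    "pattern_modularity",
]

log = logging.getLogger(__name__)


def radial_autocorrelation(
    pattern: np.ndarray,
    roi: np.ndarray,
    pixel_um: float,
    bin_width_mm: float | None = None,
) -> RadialProfile:
    """Radially averaged, masked spatial autocorrelation of one pattern.

    The 2-D autocorrelation is computed over pixel pairs that both lie in
    the ROI (FFT of the masked pattern normalised by the mask overlap
    counts), scaled to 1 at zero lag, then averaged over annuli of width
    ``bin_width_mm`` (default: one pixel).

    The pattern is centred on its ROI mean first; a constant pattern has no
    defined autocorrelation and raises.
    """
    roi = np.asarray(roi, dtype=bool)
    if pattern.shape != roi.shape:
        raise ValueError("pattern and ROI grids differ")
    px_mm = pixel_um / 1000.0
    if bin_width_mm is None:
        bin_width_mm = px_mm
    vals = np.where(roi, pattern, np.nan)
    mean = np.nanmean(vals)
    p0 = np.where(roi & np.isfinite(vals), vals - mean, 0.0)
    m = (roi & np.isfinite(vals)).astype(float)
    if np.max(np.abs(p0)) == 0:
        raise ValueError("constant pattern: autocorrelation undefined")

    h, w = pattern.shape
    fh, fw = 2 * h, 2 * w
    fp = np.fft.rfft2(p0, s=(fh, fw))
    fm = np.fft.rfft2(m, s=(fh, fw))
    num = np.fft.irfft2(fp * np.conj(fp), s=(fh, fw))
    cnt = np.fft.irfft2(fm * np.conj(fm), s=(fh, fw))
    num = np.fft.fftshift(num)
    cnt = np.fft.fftshift(cnt)
    with np.errstate(divide="ignore", invalid="ignore"):
        ac = num / cnt
    ok = cnt > 0.5
    cy, cx = fh // 2, fw // 2
    ac0 = ac[cy, cx]
    if not np.isfinite(ac0) or ac0 <= 0:
        raise ValueError("zero-variance pattern inside ROI")
    ac = ac / ac0

    dy = (np.arange(fh) - cy)[:, None]
    dx = (np.arange(fw) - cx)[None, :]
    r_mm = np.hypot(dy, dx) * px_mm
    k = np.rint(r_mm / bin_width_mm).astype(int)
    kmax_geom = int(np.rint((min(h, w) * px_mm) / bin_width_mm))
    sel = ok & (k <= kmax_geom)
    sums = np.bincount(k[sel], weights=ac[sel], minlength=kmax_geom + 1)
    cnts = np.bincount(k[sel], minlength=kmax_geom + 1)
    nz = cnts > 0
    last = np.max(np.flatnonzero(nz))
    radii = np.arange(last + 1) * bin_width_mm
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(nz[: last + 1], sums[: last + 1] / np.maximum(cnts[: last + 1], 1), np.nan)
    return RadialProfile(radii_mm=radii, values=values, bin_width_mm=bin_width_mm)


def _smooth_profile(values: np.ndarray, window: int = 3) -> np.ndarray:
    """Moving average with truncated edges (no reflected data)."""
    kernel = np.ones(window)
    num = np.convolve(np.nan_to_num(values, nan=0.0), kernel, mode="same")
    den = np.convolve(np.isfinite(values).astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def _parabolic_refine(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-bin extremum location/value from a 3-point parabola around i."""
    if i <= 0 or i >= len(y) - 1:
        return float(x[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(x[i]), float(y1)
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    dx = x[1] - x[0]
    return float(x[i] + delta * dx), float(y1 - 0.25 * (y0 - y2) * delta)


def _first_local_min(values: np.ndarray, start: int = 1) -> int | None:
    """First interior strict local minimum; plateaus resolve to their
    smallest radius.  Returns the bin index or None."""
    n = len(values)
    i = start
    while i < n - 1:
        if values[i] < values[i - 1]:
            j = i
            while j + 1 < n and values[j + 1] == values[i]:
                j += 1
            if j + 1 < n and values[j + 1] > values[i]:
                return i
            i = j + 1
        else:
            i += 1
    return None


def _subsequent_max(values: np.ndarray, imin: int, iupper: int) -> int | None:
    """Index of the maximum following the first minimum.

    For a clean quasi-periodic profile this is the first local maximum
    (near one wavelength); taking the argmax over the bounded window
    ``(imin, iupper]`` makes it robust to single-bin wiggles that would
    otherwise be picked up as spurious near-zero-amplitude maxima.
    """
    lo = imin + 1
    hi = min(iupper + 1, len(values))
    if lo >= hi:
        return None
    window = values[lo:hi]
    if not np.any(np.isfinite(window)):
        return None
    return lo + int(np.nanargmax(window))


def wavelength_and_modularity(
    profile: RadialProfile, smooth_window: int = 3
) -> tuple[float, float, bool]:
    """Estimate wavelength and modularity from a radial profile.

    The profile is smoothed with a short moving average, the first interior
    local minimum located (with parabolic sub-bin refinement), and the
    wavelength taken as twice that radius.  Modularity is the absolute
    difference between the profile value at the subsequent maximum (searched
    up to three times the minimum's radius, i.e. ~1.5 wavelengths) and at
    the minimum.  If either extremum is missing within the profile's range
    the metrics are flagged invalid (NaN) rather than guessed.
    """
    if len(profile.values) < 3:
        raise ValueError("radial profile needs at least 3 bins")
    sm = _smooth_profile(profile.values, smooth_window)
    imin = _first_local_min(sm)
    if imin is None:
        return np.nan, np.nan, False
    r_min, v_min = _parabolic_refine(profile.radii_mm, sm, imin)
    imax = _subsequent_max(sm, imin, 3 * imin)
    if imax is None:
        return 2.0 * r_min, np.nan, False
    if imax < len(sm) - 1:
        _, v_max = _parabolic_refine(profile.radii_mm, sm, imax)
    else:
        v_max = float(sm[imax])
    return 2.0 * r_min, abs(v_max - v_min), True


def pattern_modularity(
    pattern: np.ndarray,
    roi: np.ndarray,
    pixel_um: float,
    bin_width_mm: float | None = None,
) -> tuple[float, float, bool]:
    """Convenience: radial autocorrelation then wavelength/modularity."""
    prof = radial_autocorrelation(pattern, roi, pixel_um, bin_width_mm)
    return wavelength_and_modularity(prof)


def module_amplitude(
    event_frame_raw: np.ndarray,
    roi: RoiMask,
    mean_wavelength_mm: float,
    smooth_sd_px: float = 2.0,
    annulus_halfwidth_um: float | None = None,
    noise_sd: float | None = None,
) -> tuple[float, bool]:
    """Peak-to-background ratio of the raw ΔF/F event frame.

    Peaks are local maxima of a lightly smoothed copy of the frame (maximum
    filter over a disc of radius Λ/4, with a floor of the ROI median plus
    twice the pixel-noise SD).  For each peak the background is the median
    raw ΔF/F over an annulus at distance Λ/2 from the peak; the event value
    is the mean peak/background ratio.  Returns ``(amplitude, valid)``.
    """
    if mean_wavelength_mm <= 0 or not np.isfinite(mean_wavelength_mm):
        raise ValueError("mean_wavelength_mm must be positive")
    frame = np.asarray(event_frame_raw, dtype=float)
    mask = roi.mask
    px_um = roi.pixel_um
    if annulus_halfwidth_um is None:
        annulus_halfwidth_um = max(px_um, 22.0)
    sm = ndimage.gaussian_filter(np.where(mask, frame, 0.0), smooth_sd_px)
    norm = ndimage.gaussian_filter(mask.astype(float), smooth_sd_px)
    with np.errstate(divide="ignore", invalid="ignore"):
        sm = np.where(mask & (norm > 1e-12), sm / norm, -np.inf)
    if noise_sd is None:
        resid = (frame - sm)[mask & np.isfinite(sm)]
        noise_sd = 1.4826 * np.median(np.abs(resid - np.median(resid)))
    r_foot = max(1, int(round(0.25 * mean_wavelength_mm * 1000.0 / px_um)))
    yy, xx = np.ogrid[-r_foot : r_foot + 1, -r_foot : r_foot + 1]
    footprint = (yy**2 + xx**2) <= r_foot**2
    local_max = ndimage.maximum_filter(sm, footprint=footprint, mode="constant", cval=-np.inf)
    floor = np.median(sm[mask]) + 2.0 * noise_sd
    # peaks must have their smoothing support inside the ROI: the masked
    # blur creates spurious maxima on the ROI boundary ring
    erode_px = int(np.ceil(2.0 * smooth_sd_px))
    ey, ex = np.ogrid[-erode_px : erode_px + 1, -erode_px : erode_px + 1]
    interior = ndimage.binary_erosion(
        mask, structure=(ey**2 + ex**2) <= erode_px**2, border_value=0
    )
    peaks = np.argwhere((sm == local_max) & interior & (sm > floor))
    if len(peaks) == 0:
        return np.nan, False
    half_wl_um = 0.5 * mean_wavelength_mm * 1000.0
    h, w = frame.shape
    gy, gx = np.mgrid[0:h, 0:w]
    ratios = []
    for py, px in peaks:
        d_um = np.hypot(gy - py, gx - px) * px_um
        ring = mask & (np.abs(d_um - half_wl_um) <= annulus_halfwidth_um)
        if not ring.any():
            continue
        bg = np.median(frame[ring])
        if bg <= 0:
            warnings.warn("nonpositive background at a module peak; peak excluded")
            continue
        ratios.append(frame[py, px] / bg)
    if not ratios:
        return np.nan, False
    return float(np.mean(ratios)), True


def event_metrics_table(
    pset: PatternSet,
    catalog: EventCatalog | None = None,
    roi: RoiMask | None = None,
    bin_width_mm: float | None = None,
    module_amplitude_kwargs: dict | None = None,
):
    """Per-event metrics as a pandas DataFrame.

    Wavelength and modularity come from the band-passed patterns in
    ``pset``; if the catalog carries raw event frames and an ROI is given,
    the module amplitude (computed at the experiment's mean wavelength) is
    added as well.
    """
    import pandas as pd

    rows = []
    for i in range(pset.n_patterns):
        try:
            wl, mod, valid = pattern_modularity(
                pset.patterns[i], pset.roi_ds, pset.pixel_um_ds, bin_width_mm
            )
        except ValueError:
            wl, mod, valid = np.nan, np.nan, False
        rows.append({"event_id": i, "wavelength_mm": wl, "modularity": mod, "valid": valid})
    df = pd.DataFrame(rows)
    if catalog is not None:
        df.insert(1, "start", catalog.starts)
        df.insert(2, "end", catalog.ends)
        df.insert(3, "event_frame", catalog.event_frames)
    if (
        catalog is not None
        and catalog.event_frames_raw is not None
        and roi is not None
        and np.isfinite(df["wavelength_mm"]).any()
    ):
        mean_wl = float(np.nanmean(df.loc[df["valid"], "wavelength_mm"]))
        kw = module_amplitude_kwargs or {}
        amps = []
        for i in range(len(df)):
            amp, _ = module_amplitude(catalog.event_frames_raw[i], roi, mean_wl, **kw)
            amps.append(amp)
        df["module_amplitude"] = amps
    return df


def modularity_significance(
    event_modularities: np.ndarray,
    dff: Movie,
    catalog: EventCatalog,
    roi: RoiMask,
    s_low_um: float,
    s_high_um: float,
    ds_factor: int | None = None,
    bin_width_mm: float | None = None,
    n_sets: int = 100,
    control_fraction: float = 0.10,
    rng_seed: int | np.random.Generator = 0,
) -> ModularitySignificance:
    """Bootstrap test of event modularity against quiet control frames.

    The control pool is the bottom ``control_fraction`` of non-event frames
    ranked by ROI-mean ΔF/F.  Each of ``n_sets`` control sets contains as
    many frames as there are events; every control frame passes through the
    identical band-pass/autocorrelation/modularity path (frames with no
    detectable autocorrelation structure score 0).  The p-value is the
    continuity-corrected fraction of control median modularities at or
    above the observed median.
    """
    event_modularities = np.asarray(event_modularities, dtype=float)
    in_event = np.zeros(dff.n_frames, dtype=bool)
    for a, b, _ in catalog.intervals:
        in_event[a : b + 1] = True
    non_event = np.flatnonzero(~in_event)
    if len(non_event) < 10:
        raise ValueError("need at least 10 non-event frames for the control pool")
    mean_act = dff.data[:, roi.mask].mean(axis=1)
    order = non_event[np.argsort(mean_act[non_event], kind="stable")]
    n_pool = max(1, int(np.floor(control_fraction * len(non_event))))
    pool = order[:n_pool]

    pool_pset = build_pattern_set(
        dff.data[pool], roi, s_low_um, s_high_um, ds_factor=ds_factor
    )
    pool_mod = np.empty(len(pool))
    for i in range(len(pool)):
        try:
            _, mod, valid = pattern_modularity(
                pool_pset.patterns[i], pool_pset.roi_ds, pool_pset.pixel_um_ds, bin_width_mm
            )
        except ValueError:
            mod, valid = np.nan, False
        pool_mod[i] = mod if valid and np.isfinite(mod) else 0.0

    n_events = len(event_modularities)
    obs = float(np.median(np.where(np.isfinite(event_modularities), event_modularities, 0.0)))
    rng = np.random.default_rng(rng_seed)
    replace = n_pool < n_events
    if replace:
        log.warning(
            "control pool (%d frames) smaller than event count (%d); sampling with replacement",
            n_pool,
            n_events,
        )
    control_medians = np.empty(n_sets)
    for k in range(n_sets):
        sel = rng.choice(n_pool, size=n_events, replace=replace)
        control_medians[k] = np.median(pool_mod[sel])
    p = (1 + int(np.sum(control_medians >= obs))) / (n_sets + 1)
    return ModularitySignificance(
        observed_median=obs, control_medians=control_medians, p_value=p
    )
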