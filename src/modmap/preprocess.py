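"""Movie preprocessing: rigid registration, baseline estimation, ΔF/F.

The baseline F0 of each pixel is a running median of its raw trace over a
window of 10–64 s, chosen wide enough to track the slow fluorescence trend
while ignoring second-scale transients; activity is then expressed as
``(F - F0) / F0``.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from numba import njit
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .containers import BaselineTrace, Movie, RoiMask

__all__ = ["register_rigid", "compute_baseline", "compute_dff", "preprocess_movie"]

log = logging.getLogger(__name__)

MIN_WINDOW_S = 10.0
MAX_WINDOW_S = 64.0


def register_rigid(
    movie: Movie,
    reference: int | np.ndarray | str = "median",
    upsample_factor: int = 10,
) -> tuple[Movie, np.ndarray]:
    """Translation-only registration of every frame to a reference.

    The reference defaults to the temporal median frame, which is robust to
    sparse large events.  Shifts are estimated by phase correlation (with
    subpixel refinement) and applied by bilinear interpolation.  Returns the
    registered movie and the per-frame correction shifts ``(dy, dx)`` in
    pixels — the translation applied to each frame, i.e. minus its estimated
    displacement from the reference.
    """
    if movie.kind != "raw":
        raise ValueError("registration expects a raw movie")
    data = np.asarray(movie.data, dtype=np.float32)
    if isinstance(reference, str):
        if reference != "median":
            raise ValueError("reference must be a frame index, an array, or 'median'")
        ref = np.median(data, axis=0)
    elif np.isscalar(reference) or isinstance(reference, (int, np.integer)):
        ref = data[int(reference)]
    else:
        ref = np.asarray(reference, dtype=np.float32)

    out = np.empty_like(data)
    shifts = np.zeros((movie.n_frames, 2))
    for t in range(movie.n_frames):
        frame = data[t]
        if not np.any(frame):
            log.warning("frame %d is all-zero; registered with zero shift", t)
            out[t] = frame
            continue
        # displacement of `frame` relative to the reference; means are
        # removed so the luminance pedestal cannot bias the subpixel fit
        disp, _, _ = phase_cross_correlation(
            ref - ref.mean(),
            frame - frame.mean(),
            upsample_factor=upsample_factor,
            normalization=None,
        )
        shifts[t] = disp
        if np.any(disp):
            out[t] = ndimage.shift(frame, disp, order=1, mode="nearest")
        else:
            out[t] = frame
    registered = Movie(out, movie.pixel_um, movie.frame_rate_hz, kind="raw")
    return registered, shifts


@njit(cache=True)
def _sliding_median(data, half):  # pragma: no cover - exercised via wrapper
    """Centered running median with truncated (shrinking) edge windows.

    data: (T, P) float32.  Window at frame t is [t-half, t+half] clipped to
    the movie; a sorted buffer is maintained per pixel with binary-search
    insertion and deletion.
    """
    t_len, p_len = data.shape
    out = np.empty_like(data)
    buf = np.empty(2 * half + 1, dtype=data.dtype)
    for p in range(p_len):
        # initial truncated window [0, half]
        m = half + 1 if half + 1 <= t_len else t_len
        buf[:m] = np.sort(data[:m, p].copy())
        for t in range(t_len):
            # emit median of current buffer of size m
            if m % 2 == 1:
                out[t, p] = buf[m // 2]
            else:
                out[t, p] = 0.5 * (buf[m // 2 - 1] + buf[m // 2])
            # slide: add frame t + half + 1, drop frame t - half
            add = t + half + 1
            drop = t - half
            if add < t_len:
                v = data[add, p]
                lo = np.searchsorted(buf[:m], v)
                for i in range(m, lo, -1):
                    buf[i] = buf[i - 1]
                buf[lo] = v
                m += 1
            if drop >= 0:
                v = data[drop, p]
                lo = np.searchsorted(buf[:m], v)
                while buf[lo] != v:
                    lo += 1
                for i in range(lo, m - 1):
                    buf[i] = buf[i + 1]
                m -= 1
    return out


def compute_baseline(movie: Movie, window_s: float = 30.0) -> BaselineTrace:
    """Per-pixel running median of the raw trace.

    ``window_s`` must lie in the 10–64 s range appropriate for separating
    second-scale calcium transients from the slow baseline trend.  Edge
    frames use truncated (shrinking) windows rather than reflected data.
    """
    if not (MIN_WINDOW_S <= window_s <= MAX_WINDOW_S):
        raise ValueError(
            f"window_s={window_s} outside the allowed range "
            f"[{MIN_WINDOW_S}, {MAX_WINDOW_S}] s"
        )
    w = int(round(window_s * movie.frame_rate_hz))
    if w >= movie.n_frames:
        raise ValueError(
            f"baseline window ({w} frames) is not shorter than the movie "
            f"({movie.n_frames} frames)"
        )
    half = max(1, w // 2)
    t_len = movie.n_frames
    data = np.ascontiguousarray(movie.data.reshape(t_len, -1), dtype=np.float32)
    f0 = _sliding_median(data, half)
    return BaselineTrace(f0=f0.reshape(movie.data.shape), window_s=window_s)


def compute_dff(movie: Movie, baseline: BaselineTrace, roi: RoiMask | None = None) -> Movie:
    """Baseline-normalised activity ``(F - F0) / F0``.

    Raises if any baseline value inside the ROI is nonpositive (the ratio
    would be meaningless there); outside the ROI such pixels are set to 0.
    """
    f0 = baseline.f0
    if f0.shape != movie.data.shape:
        raise ValueError("baseline shape does not match movie")
    inside = roi.mask if roi is not None else np.ones(movie.frame_shape, dtype=bool)
    bad = (f0 <= 0) & inside[None, :, :]
    if np.any(bad):
        t, y, x = np.argwhere(bad)[0]
        raise ValueError(f"nonpositive baseline at frame {t}, pixel ({y}, {x}) inside ROI")
    with np.errstate(divide="ignore", invalid="ignore"):
        dff = (movie.data - f0) / f0
    dff = np.where(np.isfinite(dff), dff, 0.0)
    return Movie(dff.astype(np.float32), movie.pixel_um, movie.frame_rate_hz, kind="dff")


def preprocess_movie(
    movie: Movie,
    roi: RoiMask | None = None,
    window_s: float = 30.0,
    register: bool = False,
) -> Movie:
    """Full preprocessing chain: (optional) registration, baseline, ΔF/F."""
    if movie.kind == "dff":
        warnings.warn("movie is already ΔF/F; preprocessing skipped")
        return movie
    if register:
        movie, _ = register_rigid(movie)
    baseline = compute_baseline(movie, window_s)
    return compute_dff(movie, baseline, roi)
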