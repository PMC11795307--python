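"""Spatial band-pass filtering, downsampling, seed-point correlation fields
and rotation/reflection surrogate ensembles.

Event frames are filtered with a Gaussian difference-of-Gaussians band-pass
(SDs ``s_low`` and ``s_high`` in micrometres) computed with masked
normalisation — each Gaussian blur is applied to the ROI-masked frame and
divided by the blur of the mask itself, so pixels near the ROI border are
not diluted by outside values — then block-averaged down to a coarser grid.
Correlation fields are the across-pattern Pearson correlations between a
seed pixel and every other ROI pixel.  The surrogate ensemble destroys the
systematic spatial relationships between patterns by independently rotating
(multiples of 10°) and reflecting each pattern about the ROI center; values
whose pre-image falls outside the original ROI become NaN and are excluded
from downstream statistics rather than zero-filled.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .containers import CorrelationField, PatternSet, RoiMask, SurrogateEnsemble

__all__ = [
    "bandpass_and_downsample",
    "build_pattern_set",
    "correlation_field",
    "correlation_matrix",
    "roi_coordinates_mm",
    "make_surrogate_ensemble",
    "apply_pattern_transform",
    "surrogate_pattern_set",
]

DEFAULT_S_LOW_UM = 30.0
DEFAULT_S_HIGH_UM = 195.0
SURROGATE_ANGLES_DEG = np.arange(0, 360, 10)


def _masked_blur(frame: np.ndarray, mask: np.ndarray, sigma_px: float) -> np.ndarray:
    if sigma_px <= 0:
        return np.where(mask, frame, 0.0)
    fm = ndimage.gaussian_filter(np.where(mask, frame, 0.0), sigma_px)
    mm = ndimage.gaussian_filter(mask.astype(float), sigma_px)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = fm / mm
    return np.where(mask & (mm > 1e-12), out, 0.0)


def _block_mean(frame: np.ndarray, factor: int) -> np.ndarray:
    h, w = frame.shape
    return frame.reshape(h // factor, factor, w // factor, factor).mean(axis=(1, 3))


def _ds_factor(src: tuple[int, int], target_dims: tuple[int, int] | None, factor: int | None) -> int:
    if factor is not None:
        f = int(factor)
    elif target_dims is not None:
        fy, ry = divmod(src[0], target_dims[0])
        fx, rx = divmod(src[1], target_dims[1])
        if ry or rx or fy != fx or fy < 1:
            raise ValueError(
                f"target dims {target_dims} must divide source dims {src} by a "
                "common integer factor"
            )
        f = fy
    else:
        f = 1
    if src[0] % f or src[1] % f:
        raise ValueError(f"downsampling factor {f} does not divide frame shape {src}")
    return f


def bandpass_and_downsample(
    frame: np.ndarray,
    roi: RoiMask,
    s_low_um: float = DEFAULT_S_LOW_UM,
    s_high_um: float = DEFAULT_S_HIGH_UM,
    target_dims: tuple[int, int] | None = None,
    ds_factor: int | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Band-pass one event frame and downsample it.

    Returns ``(pattern, roi_ds, pixel_um_ds)``.  The pattern is NaN outside
    the downsampled ROI.
    """
    if s_low_um >= s_high_um:
        raise ValueError("s_low_um must be smaller than s_high_um")
    if frame.shape != roi.mask.shape:
        raise ValueError("frame and ROI grids differ")
    mask = roi.mask
    ys, xs = np.nonzero(mask)
    extent_um = (np.ptp(ys) + 1) * roi.pixel_um, (np.ptp(xs) + 1) * roi.pixel_um
    if min(extent_um) < 2.0 * s_high_um:
        warnings.warn(
            "ROI extent is below twice s_high; band-pass output may be unreliable"
        )
    lo = _masked_blur(frame, mask, s_low_um / roi.pixel_um)
    hi = _masked_blur(frame, mask, s_high_um / roi.pixel_um)
    band = np.where(mask, lo - hi, 0.0)
    f = _ds_factor(frame.shape, target_dims, ds_factor)
    if f > 1:
        pat = _block_mean(band, f)
        roi_ds = _block_mean(mask.astype(float), f) >= 0.5
    else:
        pat, roi_ds = band, mask.copy()
    pat = np.where(roi_ds, pat, np.nan)
    return pat, roi_ds, roi.pixel_um * f


def build_pattern_set(
    frames: np.ndarray,
    roi: RoiMask,
    s_low_um: float = DEFAULT_S_LOW_UM,
    s_high_um: float = DEFAULT_S_HIGH_UM,
    target_dims: tuple[int, int] | None = None,
    ds_factor: int | None = None,
) -> PatternSet:
    """Filter and downsample a stack of event frames into a :class:`PatternSet`."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError("frames must be (N, H, W)")
    pats = []
    with warnings.catch_warnings():
        warnings.simplefilter("once")
        for fr in frames:
            pat, roi_ds, px_ds = bandpass_and_downsample(
                fr, roi, s_low_um, s_high_um, target_dims, ds_factor
            )
            pats.append(pat)
    return PatternSet(
        patterns=np.asarray(pats),
        roi_ds=roi_ds,
        pixel_um_ds=px_ds,
        s_low_um=s_low_um,
        s_high_um=s_high_um,
    )


def correlation_field(pset: PatternSet, seed: tuple[int, int]) -> CorrelationField:
    """Pearson correlation, across patterns, of the seed pixel with every pixel.

    Pixels with zero across-pattern variance (or too few defined values) are
    NaN in the output.
    """
    if pset.n_patterns < 2:
        raise ValueError("at least 2 patterns are required for correlation")
    sy, sx = seed
    if not pset.roi_ds[sy, sx]:
        raise ValueError(f"seed {seed} lies outside the downsampled ROI")
    a = pset.patterns.reshape(pset.n_patterns, -1)
    s_col = a[:, sy * pset.shape_ds[1] + sx]
    if np.all(np.isnan(s_col)) or np.nanstd(s_col) == 0:
        raise ValueError("seed pixel has zero variance across patterns")
    cmat_col = _pairwise_pearson(a, s_col[:, None])[:, 0]
    values = cmat_col.reshape(pset.shape_ds)
    values = np.where(pset.roi_ds, values, np.nan)
    return CorrelationField(seed=(sy, sx), values=values, n_patterns=pset.n_patterns)


def _pairwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation between columns of ``a`` and columns of ``b``
    across rows, pairwise-complete over NaNs.  Returns (Pa, Pb)."""
    ma = np.isfinite(a)
    mb = np.isfinite(b)
    a0 = np.where(ma, a, 0.0)
    b0 = np.where(mb, b, 0.0)
    fa, fb = ma.astype(np.float64), mb.astype(np.float64)
    n = fa.T @ fb
    sa = a0.T @ fb
    sb = fa.T @ b0
    saa = (a0 * a0).T @ fb
    sbb = fa.T @ (b0 * b0)
    sab = a0.T @ b0
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = n * sab - sa * sb
        va = n * saa - sa * sa
        vb = n * sbb - sb * sb
        r = cov / np.sqrt(va * vb)
    r[(n < 2) | (va <= 0) | (vb <= 0)] = np.nan
    return np.clip(r, -1.0, 1.0)


def correlation_matrix(pset: PatternSet) -> tuple[np.ndarray, np.ndarray]:
    """Full seed-by-pixel correlation matrix over ROI pixels.

    Returns ``(C, roi_indices)`` where ``C[i, j]`` is the across-pattern
    Pearson correlation between ROI pixels ``i`` and ``j`` (flat indices in
    ``roi_indices``), computed pairwise-complete over NaN entries (needed
    for surrogate ensembles whose transforms invalidate different pixels in
    different patterns).
    """
    if pset.n_patterns < 2:
        raise ValueError("at least 2 patterns are required for correlation")
    idx = np.flatnonzero(pset.roi_ds.ravel())
    a = pset.patterns.reshape(pset.n_patterns, -1)[:, idx].astype(np.float32)
    c = _pairwise_pearson(a, a)
    return c, idx


def roi_coordinates_mm(pset: PatternSet) -> np.ndarray:
    """(P, 2) physical coordinates (mm) of the ROI pixels, matching
    :func:`correlation_matrix` ordering."""
    idx = np.flatnonzero(pset.roi_ds.ravel())
    h, w = pset.shape_ds
    yy, xx = np.divmod(idx, w)
    return np.stack([yy, xx], axis=1) * (pset.pixel_um_ds / 1000.0)


def _transform_center(roi_ds: np.ndarray) -> tuple[float, float]:
    """Center of the ROI bounding box (used for rotations and reflections)."""
    ys, xs = np.nonzero(roi_ds)
    return (ys.min() + ys.max()) / 2.0, (xs.min() + xs.max()) / 2.0


def apply_pattern_transform(
    pattern: np.ndarray,
    roi_ds: np.ndarray,
    angle_deg: float,
    flip_x: bool,
    flip_y: bool,
) -> np.ndarray:
    """Rotate/reflect one pattern about the ROI center.

    Output pixels whose pre-image lies outside the original ROI are NaN.
    Reflection ``flip_x`` mirrors across the vertical axis (x -> -x),
    ``flip_y`` across the horizontal axis; both are applied before the
    rotation.
    """
    cy, cx = _transform_center(roi_ds)
    th = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    refl = np.diag([-1.0 if flip_y else 1.0, -1.0 if flip_x else 1.0])
    # output = R . S . input  =>  input = S^-1 . R^-1 . output (inverse map)
    fwd = rot @ refl
    inv = np.linalg.inv(fwd)
    center = np.array([cy, cx])
    offset = center - inv @ center
    # snap numerical fuzz (sin(pi) ~ 1e-16) so exact transforms stay exact
    # and edge coordinates are not pushed infinitesimally outside the grid
    inv = np.where(np.abs(inv - np.round(inv)) < 1e-9, np.round(inv), inv)
    offset = np.where(np.abs(offset - np.round(offset * 2) / 2) < 1e-9,
                      np.round(offset * 2) / 2, offset)
    src = np.where(roi_ds, np.where(np.isfinite(pattern), pattern, 0.0), 0.0)
    out = ndimage.affine_transform(src, inv, offset=offset, order=1, mode="constant", cval=0.0)
    valid_src = roi_ds & np.isfinite(pattern)
    valid = ndimage.affine_transform(
        valid_src.astype(np.uint8), inv, offset=offset, order=0, mode="constant", cval=0
    ).astype(bool)
    valid &= roi_ds
    return np.where(valid, out, np.nan)


def make_surrogate_ensemble(
    pset: PatternSet, rng_seed: int | np.random.Generator = 0
) -> SurrogateEnsemble:
    """Rotation/reflection-shuffled control ensemble.

    Each pattern is independently rotated by an angle uniform on
    {0°, 10°, ..., 350°} and reflected about the x- and y-axes each with
    probability 0.5, all about the ROI center.
    """
    if pset.n_patterns < 2:
        raise ValueError("need at least 2 patterns")
    rng = np.random.default_rng(rng_seed)
    n = pset.n_patterns
    angles = SURROGATE_ANGLES_DEG[rng.integers(0, len(SURROGATE_ANGLES_DEG), size=n)]
    flips_x = rng.random(n) < 0.5
    flips_y = rng.random(n) < 0.5
    out = np.empty_like(pset.patterns, dtype=float)
    for i in range(n):
        out[i] = apply_pattern_transform(
            pset.patterns[i], pset.roi_ds, angles[i], flips_x[i], flips_y[i]
        )
    seed_val = rng_seed if isinstance(rng_seed, (int, np.integer)) else None
    return SurrogateEnsemble(
        patterns_surrogate=out,
        angles_deg=angles,
        flip_x=flips_x,
        flip_y=flips_y,
        rng_seed=seed_val,
    )


def surrogate_pattern_set(pset: PatternSet, ens: SurrogateEnsemble) -> PatternSet:
    """Wrap a surrogate ensemble as a :class:`PatternSet` on the same grid."""
    return PatternSet(
        patterns=ens.patterns_surrogate,
        roi_ds=pset.roi_ds,
        pixel_um_ds=pset.pixel_um_ds,
        s_low_um=pset.s_low_um,
        s_high_um=pset.s_high_um,
    )
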