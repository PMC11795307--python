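"""Experiment-level network metrics.

Long-range correlation strength is the variance of pixel-wise correlation
values in a 1.8–2.2 mm ring around each seed, averaged over seeds.  High
variance at distance means the correlation field still swings between
strongly positive and strongly negative values millimetres away from the
seed.  To remove the spurious variance contributed by the finite number of
events, the same quantity is computed on rotation/reflection surrogate
ensembles of matched size; the corrected strength is the difference, and
significance is the fraction of surrogate variances at or above the real
one.

Effective dimensionality is the cross-validated participation ratio
``(sum lambda)^2 / sum lambda^2`` of the variances of held-out patterns
projected on principal axes learned from a disjoint half of the events,
computed over a circular region of area ``0.5 * wavelength^2`` and averaged
over random event subsets.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import CorrelationStrength, DimensionalityResult, PatternSet
from .filtering import (
    correlation_matrix,
    make_surrogate_ensemble,
    roi_coordinates_mm,
    surrogate_pattern_set,
)

__all__ = [
    "participation_ratio",
    "correlation_variance_at_distance",
    "ring_variance",
    "corrected_long_range_strength",
    "cross_validated_dimensionality",
]

log = logging.getLogger(__name__)

DEFAULT_RING_MM = (1.8, 2.2)


def participation_ratio(lambdas: np.ndarray) -> float:
    """Effective dimensionality of a variance spectrum: (Σλ)² / Σλ²."""
    lam = np.asarray(lambdas, dtype=float)
    denom = np.sum(lam**2)
    if denom == 0:
        raise ValueError("all-zero spectrum has no defined dimensionality")
    return float(np.sum(lam) ** 2 / denom)


def ring_variance(
    cmat: np.ndarray,
    coords_mm: np.ndarray,
    ring_mm: tuple[float, float] = DEFAULT_RING_MM,
    min_ring_px: int = 2,
) -> float:
    """Mean (over seeds) variance of correlation values at ring distance.

    ``cmat`` is the seed-by-pixel correlation matrix over ROI pixels and
    ``coords_mm`` their physical coordinates.  For each seed the variance is
    taken over ROI pixels whose distance from the seed lies within the ring
    (NaN correlations excluded); seeds with fewer than ``min_ring_px``
    defined ring values are skipped.  Raises if no seed has any ring pixel.
    """
    lo, hi = ring_mm
    if not (0 < lo < hi):
        raise ValueError("ring_mm must satisfy 0 < lo < hi")
    d2 = (
        (coords_mm[:, None, 0] - coords_mm[None, :, 0]) ** 2
        + (coords_mm[:, None, 1] - coords_mm[None, :, 1]) ** 2
    )
    in_ring = (d2 >= lo**2) & (d2 <= hi**2)
    if not in_ring.any():
        raise ValueError(
            "no seed has ring pixels inside the ROI; the field of view is too "
            "small for this ring distance"
        )
    defined = np.isfinite(cmat) & in_ring
    n = defined.sum(axis=0)
    c0 = np.where(defined, cmat, 0.0)
    s1 = c0.sum(axis=0)
    s2 = (c0 * c0).sum(axis=0)
    usable = n >= min_ring_px
    if not usable.any():
        raise ValueError("no seed has enough defined ring correlations")
    nn = n[usable].astype(float)
    var = s2[usable] / nn - (s1[usable] / nn) ** 2
    return float(np.mean(np.maximum(var, 0.0)))


def correlation_variance_at_distance(
    pset: PatternSet,
    ring_mm: tuple[float, float] = DEFAULT_RING_MM,
    min_ring_px: int = 2,
) -> float:
    """Ring variance computed directly from a pattern set."""
    cmat, _ = correlation_matrix(pset)
    coords = roi_coordinates_mm(pset)
    return ring_variance(cmat, coords, ring_mm, min_ring_px)


def _subsample_patterns(
    pset: PatternSet, n_use: int, rng: np.random.Generator
) -> tuple[PatternSet, bool]:
    n = pset.n_patterns
    replace = n < n_use
    if replace:
        log.warning(
            "only %d patterns available; subsampling %d with replacement", n, n_use
        )
    sel = rng.choice(n, size=n_use, replace=replace)
    sub = PatternSet(
        patterns=pset.patterns[sel],
        roi_ds=pset.roi_ds,
        pixel_um_ds=pset.pixel_um_ds,
        s_low_um=pset.s_low_um,
        s_high_um=pset.s_high_um,
    )
    return sub, replace


def corrected_long_range_strength(
    pset: PatternSet,
    n_use: int = 100,
    n_surrogates: int = 100,
    ring_mm: tuple[float, float] = DEFAULT_RING_MM,
    rng_seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
) -> CorrelationStrength:
    """Long-range correlation strength with surrogate correction.

    ``n_use`` patterns are drawn (without replacement when possible) to fix
    the event count across experiments; the ring variance of their
    correlation fields is compared with ``n_surrogates`` rotation/reflection
    surrogate ensembles of the same size.  The p-value carries a +1
    continuity correction so it is never exactly zero.
    """
    rng = np.random.default_rng(rng_seed)
    sub, replaced = _subsample_patterns(pset, n_use, rng)
    var_real = correlation_variance_at_distance(sub, ring_mm)
    surr_vars = np.empty(n_surrogates)
    for k in range(n_surrogates):
        ens = make_surrogate_ensemble(sub, rng)
        surr_vars[k] = correlation_variance_at_distance(
            surrogate_pattern_set(sub, ens), ring_mm
        )
    p = (1 + int(np.sum(surr_vars >= var_real))) / (n_surrogates + 1)
    return CorrelationStrength(
        variance_real=var_real,
        variance_surrogate=float(surr_vars.mean()),
        n_events_used=n_use,
        ring_mm=tuple(ring_mm),
        p_value=p,
        significant=p < alpha,
        surrogate_variances=surr_vars,
        subsampled_with_replacement=replaced,
    )


def _region_pixels(
    pset: PatternSet, wavelength_mm: float, center: tuple[int, int] | None
) -> tuple[np.ndarray, tuple[int, int], float]:
    """Flat indices of ROI pixels in the circular analysis region."""
    h, w = pset.shape_ds
    if center is None:
        ys, xs = np.nonzero(pset.roi_ds)
        center = (int(round(ys.mean())), int(round(xs.mean())))
    radius_mm = np.sqrt(0.5 / np.pi) * wavelength_mm
    radius_px = radius_mm * 1000.0 / pset.pixel_um_ds
    if radius_px < 2:
        raise ValueError(
            f"analysis region radius ({radius_px:.2f} px) is below 2 pixels; "
            "grid too coarse for this wavelength"
        )
    yy, xx = np.mgrid[0:h, 0:w]
    circle = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius_px**2
    region = circle & pset.roi_ds & np.all(np.isfinite(pset.patterns), axis=0)
    area_mm2 = 0.5 * wavelength_mm**2
    return np.flatnonzero(region.ravel()), center, area_mm2


def cross_validated_dimensionality(
    pset: PatternSet,
    wavelength_mm: float,
    n_subsets: int = 10,
    subset_size: int = 100,
    rng_seed: int | np.random.Generator = 0,
    region_center: tuple[int, int] | None = None,
) -> DimensionalityResult:
    """Cross-validated participation-ratio dimensionality of event patterns.

    Per subset: ``subset_size`` events are drawn and split into disjoint
    halves X1/X2; principal axes are learned from X1 restricted to a
    circular region of area ``0.5 * wavelength^2``; ``lambda_i`` is the
    variance of X2 projected on axis i; the subset dimensionality is the
    participation ratio of that spectrum.  The result is the mean over
    ``n_subsets`` random subsets.
    """
    idx, center, area = _region_pixels(pset, wavelength_mm, region_center)
    if len(idx) < 4:
        raise ValueError("analysis region contains fewer than 4 usable pixels")
    flat = pset.patterns.reshape(pset.n_patterns, -1)[:, idx]
    rng = np.random.default_rng(rng_seed)
    n = pset.n_patterns
    replace = n < subset_size
    if replace:
        log.warning(
            "only %d patterns for subsets of %d; sampling with replacement", n, subset_size
        )
    per_subset = np.empty(n_subsets)
    spectra = []
    for k in range(n_subsets):
        sel = rng.choice(n, size=subset_size, replace=replace)
        half = subset_size // 2
        x1 = flat[sel[:half]]
        x2 = flat[sel[half : 2 * half]]
        x1c = x1 - x1.mean(axis=0, keepdims=True)
        _, _, vt = np.linalg.svd(x1c, full_matrices=False)
        x2c = x2 - x2.mean(axis=0, keepdims=True)
        proj = x2c @ vt.T
        lam = proj.var(axis=0, ddof=0)
        spectra.append(lam)
        per_subset[k] = participation_ratio(lam)
    return DimensionalityResult(
        d_eff=float(per_subset.mean()),
        per_subset=per_subset,
        lambda_spectra=spectra,
        region_center=center,
        region_area_mm2=area,
        subsampled_with_replacement=replace,
    )
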