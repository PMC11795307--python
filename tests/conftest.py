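import numpy as np
import pytest

from modmap import synthetic
from modmap.containers import PatternSet, RoiMask
from modmap.detection import detect_events


@pytest.fixture(scope="session")
def modular_movie():
    """Small modular ΔF/F movie with 20 known events (96x96 @ 22 um, 15 Hz)."""
    truth = synthetic.modular_ground_truth(
        shape=(96, 96),
        pixel_um=22.0,
        wavelength_mm=1.0,
        n_components=8,
        n_events=20,
        noise_sd=0.02,
        rng_seed=101,
    )
    movie, info = synthetic.synthesize_movie(truth, kind="dff")
    roi = RoiMask.full((96, 96), 22.0)
    return movie, info, roi, truth


@pytest.fixture(scope="session")
def modular_catalog(modular_movie):
    movie, info, roi, truth = modular_movie
    return detect_events(movie, roi, method="gaussian3sd")


def circle_roi(n: int) -> np.ndarray:
    yy, xx = np.mgrid[0:n, 0:n]
    c = (n - 1) / 2
    return (yy - c) ** 2 + (xx - c) ** 2 <= (n / 2 - 0.5) ** 2


def structured_pattern_set(
    n: int, k: int, seed: int, grid: int = 40, pixel_um: float = 88.0, noise_sd: float = 0.0
) -> PatternSet:
    """Patterns sharing k global modular components on a circular ROI."""
    roi = circle_roi(grid)
    comps = synthetic.generate_modular_components((grid, grid), pixel_um, 1.0, k, rng_seed=seed)
    rng = np.random.default_rng(seed + 10_000)
    w = rng.standard_normal((n, k))
    pats = np.tensordot(w, comps, axes=(1, 0))
    if noise_sd:
        pats = pats + noise_sd * rng.standard_normal(pats.shape)
    return PatternSet(np.where(roi, pats, np.nan), roi, pixel_um, 30.0, 195.0)


def unstructured_pattern_set(
    n: int, seed: int, grid: int = 40, pixel_um: float = 88.0
) -> PatternSet:
    """Mutually independent modular patterns (no shared components)."""
    roi = circle_roi(grid)
    pats = synthetic.independent_modular_patterns((grid, grid), pixel_um, 1.0, n, rng_seed=seed)
    return PatternSet(np.where(roi, pats, np.nan), roi, pixel_um, 30.0, 195.0)
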