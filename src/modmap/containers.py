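"""Core in-memory containers shared across the analysis stages.

Conventions
-----------
Movies are ``(T, H, W)`` arrays (time first).  Spatial scales are carried as a
pixel pitch in micrometres; all metric distances (wavelength, correlation
rings) are expressed in millimetres.  A ``Movie`` is either ``raw``
fluorescence (arbitrary camera units) or ``dff`` (baseline-normalised
:math:`\\Delta F/F_0`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Movie",
    "RoiMask",
    "BaselineTrace",
    "EventCatalog",
    "PatternSet",
    "CorrelationField",
    "SurrogateEnsemble",
    "RadialProfile",
    "EventMetrics",
    "ModularitySignificance",
    "CorrelationStrength",
    "DimensionalityResult",
]


@dataclass
class Movie:
    """A fluorescence image stack with its acquisition geometry.

    Parameters
    ----------
    data : ndarray, shape (T, H, W)
        Frame stack.  Raw fluorescence or ΔF/F depending on ``kind``.
    pixel_um : float
        Pixel pitch in micrometres per pixel.
    frame_rate_hz : float
        Acquisition rate in Hz.
    kind : {"raw", "dff"}
    """

    data: np.ndarray
    pixel_um: float
    frame_rate_hz: float
    kind: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ValueError("movie data must be a (T, H, W) stack with T >= 1")
        if self.pixel_um <= 0:
            raise ValueError("pixel_um must be positive")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.kind not in ("raw", "dff"):
            raise ValueError(f"unknown movie kind {self.kind!r}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz


@dataclass
class RoiMask:
    """Boolean region-of-interest on the movie grid (True = analysed)."""

    mask: np.ndarray
    pixel_um: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2-D")
        if not self.mask.any():
            raise ValueError("ROI mask must contain at least one pixel")
        if self.pixel_um <= 0:
            raise ValueError("pixel_um must be positive")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @classmethod
    def full(cls, shape: tuple[int, int], pixel_um: float) -> "RoiMask":
        return cls(np.ones(shape, dtype=bool), pixel_um)


@dataclass
class BaselineTrace:
    """Per-pixel running-median baseline F0 and the window used to build it."""

    f0: np.ndarray
    window_s: float


@dataclass
class EventCatalog:
    """Detected spontaneous events.

    ``intervals`` is an ``(N, 3)`` integer array of
    ``(start_frame, end_frame, event_frame)`` with inclusive ends; the event
    frame is the frame of highest ROI-mean activity within the event and is
    the frame used as the event's spatial pattern.
    """

    intervals: np.ndarray
    event_frames_raw: np.ndarray | None = None
    n_active_frames: int = 0

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=int).reshape(-1, 3)
        iv = self.intervals
        if len(iv):
            if np.any(iv[:, 0] > iv[:, 1]):
                raise ValueError("event start after end")
            if np.any((iv[:, 2] < iv[:, 0]) | (iv[:, 2] > iv[:, 1])):
                raise ValueError("event frame outside its interval")
            if np.any(iv[1:, 0] <= iv[:-1, 1]):
                raise ValueError("event intervals overlap or are unordered")

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def starts(self) -> np.ndarray:
        return self.intervals[:, 0]

    @property
    def ends(self) -> np.ndarray:
        return self.intervals[:, 1]

    @property
    def event_frames(self) -> np.ndarray:
        return self.intervals[:, 2]


@dataclass
class PatternSet:
    """Band-passed, downsampled event patterns A_i used for correlations.

    ``patterns`` has shape ``(N, h, w)``; values outside ``roi_ds`` (or
    invalidated by a surrogate transform) are NaN and are excluded from all
    downstream statistics.
    """

    patterns: np.ndarray
    roi_ds: np.ndarray
    pixel_um_ds: float
    s_low_um: float
    s_high_um: float

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns)
        self.roi_ds = np.asarray(self.roi_ds, dtype=bool)
        if self.patterns.ndim != 3:
            raise ValueError("patterns must be (N, h, w)")
        if self.patterns.shape[1:] != self.roi_ds.shape:
            raise ValueError("pattern grid does not match downsampled ROI")
        if self.s_low_um >= self.s_high_um:
            raise ValueError("s_low_um must be smaller than s_high_um")

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[0]

    @property
    def shape_ds(self) -> tuple[int, int]:
        return self.roi_ds.shape


@dataclass
class CorrelationField:
    """Seed-point correlation map C(x, s) over the downsampled ROI."""

    seed: tuple[int, int]
    values: np.ndarray
    n_patterns: int


@dataclass
class SurrogateEnsemble:
    """Rotation/reflection-shuffled copy of a :class:`PatternSet`."""

    patterns_surrogate: np.ndarray
    angles_deg: np.ndarray
    flip_x: np.ndarray
    flip_y: np.ndarray
    rng_seed: int | None = None


@dataclass
class RadialProfile:
    """Radially averaged spatial autocorrelation of one pattern."""

    radii_mm: np.ndarray
    values: np.ndarray
    bin_width_mm: float

    def __post_init__(self) -> None:
        self.radii_mm = np.asarray(self.radii_mm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.radii_mm[0] != 0:
            raise ValueError("radial profile must start at r = 0")


@dataclass
class EventMetrics:
    """Wavelength, modularity and module amplitude of a single event."""

    wavelength_mm: float
    modularity: float
    module_amplitude: float = np.nan
    valid: bool = True


@dataclass
class ModularitySignificance:
    """Observed median event modularity versus low-activity control frames."""

    observed_median: float
    control_medians: np.ndarray
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


@dataclass
class CorrelationStrength:
    """Long-range correlation strength in a distance ring, surrogate-corrected.

    ``variance_real`` is the mean (over seeds) variance of correlation values
    at ring distance; ``variance_surrogate`` the same for the shuffled
    ensembles.  The headline corrected strength is their difference.
    """

    variance_real: float
    variance_surrogate: float
    n_events_used: int
    ring_mm: tuple[float, float]
    p_value: float
    significant: bool
    surrogate_variances: np.ndarray | None = None
    subsampled_with_replacement: bool = False

    @property
    def corrected(self) -> float:
        return self.variance_real - self.variance_surrogate


@dataclass
class DimensionalityResult:
    """Cross-validated effective dimensionality (participation ratio)."""

    d_eff: float
    per_subset: np.ndarray
    lambda_spectra: list = field(default_factory=list)
    region_center: tuple[int, int] = (0, 0)
    region_area_mm2: float = np.nan
    subsampled_with_replacement: bool = False
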