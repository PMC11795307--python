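"""Synthetic wide-field movies with known modular structure.

This module generates ground-truth fluorescence movies that mimic the
statistics the analysis stages assume: sparse large events whose spatial
patterns are weighted combinations of a small number of quasi-periodic
("modular") spatial components, riding on a slowly drifting baseline with
i.i.d. pixel noise.  Because every generated quantity (wavelength, component
count, event times, module contrast) is known, each downstream stage has a
parameter-recovery test without any external data.

Spatial components are Gaussian random fields with power concentrated in a
narrow isotropic ring of spatial frequencies.  For such a field the radial
autocorrelation is close to :math:`J_0(2\\pi f_0 r)` times a bandwidth
envelope.  The analysis defines the wavelength :math:`\\Lambda` as twice
the radius of the autocorrelation's first minimum, so the carrier frequency
is calibrated numerically such that this first minimum falls exactly at
:math:`\\Lambda/2` — the generator's nominal wavelength thereby agrees with
the estimator's definition rather than with the (different) location of the
spectral peak.  The default relative bandwidth (0.2) makes the spatial
coherence of a single pattern decay over a few modules, vanishing by
~2 mm, as in real spontaneous events; much narrower bands would give every
single pattern millimetre-range self-correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import Movie

__all__ = [
    "GroundTruth",
    "generate_modular_components",
    "generate_white_components",
    "synthesize_movie",
    "modular_ground_truth",
    "noise_event_ground_truth",
    "event_pattern",
    "independent_modular_patterns",
]

# First minimum of the Bessel function J0 (narrow-band limit of the ACF).
_J0_FIRST_MIN = 3.8317059702075125

DEFAULT_REL_BANDWIDTH = 0.2

_ACF_MIN_CACHE: dict[float, float] = {}


def _ring_acf_first_min(rel_bandwidth: float) -> float:
    """First minimum x* of the radial ACF of a Gaussian-ring spectrum.

    The amplitude filter is exp(-(u-1)^2 / (2 bw^2)) on relative radial
    frequency u (carrier at u = 1), so the power spectral density is its
    square; the field autocorrelation is g(x) = ∫ S(u) u J0(2π u x) du with
    x = f0 * r.  The finite bandwidth pulls the first minimum slightly
    inside the narrow-band (J0) location 3.8317 / (2π); computing it
    numerically keeps the generator's nominal wavelength exact for any
    bandwidth.
    """
    bw = round(float(rel_bandwidth), 6)
    if bw not in _ACF_MIN_CACHE:
        from scipy.special import j0

        u = np.linspace(max(1e-3, 1 - 5 * bw), 1 + 5 * bw, 2001)
        s = np.exp(-(((u - 1.0) / bw) ** 2)) * u
        x = np.linspace(0.3, 1.2, 4001)
        g = (s[None, :] * j0(2 * np.pi * u[None, :] * x[:, None])).sum(axis=1)
        i = int(np.argmin(g))
        # parabolic sub-sample refinement
        if 0 < i < len(x) - 1:
            y0, y1, y2 = g[i - 1], g[i], g[i + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            _ACF_MIN_CACHE[bw] = float(x[i] + delta * (x[1] - x[0]))
        else:  # pragma: no cover - pathological bandwidth
            _ACF_MIN_CACHE[bw] = _J0_FIRST_MIN / (2 * np.pi)
    return _ACF_MIN_CACHE[bw]


@dataclass
class GroundTruth:
    """Complete description of a synthetic movie.

    Parameters
    ----------
    true_wavelength_mm : float
        Nominal module spacing of the spatial components.
    component_maps : ndarray, shape (K, H, W)
        Zero-mean, unit-SD, mutually uncorrelated spatial components.
    event_times : ndarray of int
        Peak frame index of each event (strictly increasing).
    event_weights : ndarray, shape (n_events, K)
        Component weights per event.
    event_amplitude : float
        Peak ΔF/F of each event.
    module_floor : float
        Fraction of the peak amplitude present in the troughs of an event
        pattern (0 < floor < 1).  The generator's ground-truth module
        amplitude (peak over background at half-wavelength distance) is
        ``1 / module_floor``.
    noise_sd : float
        SD of i.i.d. Gaussian pixel noise, in ΔF/F units.
    drift_amplitude : float
        Peak amplitude of the slow multiplicative baseline drift.
    """

    true_wavelength_mm: float
    pixel_um: float
    component_maps: np.ndarray
    event_times: np.ndarray
    event_weights: np.ndarray
    n_frames: int
    event_amplitude: float = 0.2
    module_floor: float = 0.5
    noise_sd: float = 0.02
    drift_amplitude: float = 0.05
    decay_tau_s: float = 1.0
    rise_frames: int = 2
    baseline_level: float = 100.0
    rng_seed: int = 0
    drift_periods_s: tuple[float, ...] = (37.0, 53.0, 97.0)

    def __post_init__(self) -> None:
        self.component_maps = np.asarray(self.component_maps, dtype=float)
        self.event_times = np.asarray(self.event_times, dtype=int)
        self.event_weights = np.atleast_2d(np.asarray(self.event_weights, dtype=float))
        if self.component_maps.ndim != 3 or self.n_components < 1:
            raise ValueError("component_maps must be (K, H, W) with K >= 1")
        if self.true_wavelength_mm <= 0:
            raise ValueError("true_wavelength_mm must be positive")
        if len(self.event_times) and np.any(np.diff(self.event_times) <= 0):
            raise ValueError("event_times must be strictly increasing")
        if self.event_weights.shape != (len(self.event_times), self.n_components):
            raise ValueError("event_weights must be (n_events, K)")
        if not (0.0 < self.module_floor < 1.0):
            raise ValueError("module_floor must lie in (0, 1)")
        if min(self.drift_periods_s) < 30.0:
            raise ValueError("drift periods must be >= 30 s to stay below the baseline band")

    @property
    def n_components(self) -> int:
        return self.component_maps.shape[0]

    @property
    def n_events(self) -> int:
        return len(self.event_times)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.component_maps.shape[1:]

    @property
    def true_module_amplitude(self) -> float:
        return 1.0 / self.module_floor


def _ring_bandpass_noise(
    shape: tuple[int, int],
    pixel_um: float,
    wavelength_mm: float,
    n: int,
    rng: np.random.Generator,
    rel_bandwidth: float = DEFAULT_REL_BANDWIDTH,
) -> np.ndarray:
    """n independent GRFs with an isotropic Gaussian ring spectrum."""
    h, w = shape
    fy = np.fft.fftfreq(h, d=pixel_um / 1000.0)  # cycles per mm
    fx = np.fft.fftfreq(w, d=pixel_um / 1000.0)
    f = np.hypot(fy[:, None], fx[None, :])
    # carrier chosen so the radial ACF's first minimum sits at wavelength/2
    f0 = 2.0 * _ring_acf_first_min(rel_bandwidth) / wavelength_mm
    filt = np.exp(-0.5 * ((f - f0) / (rel_bandwidth * f0)) ** 2)
    filt[0, 0] = 0.0  # no DC
    white = rng.standard_normal((n, h, w))
    fields = np.fft.ifft2(np.fft.fft2(white, axes=(1, 2)) * filt, axes=(1, 2)).real
    return fields


def _orthonormalize(fields: np.ndarray) -> np.ndarray:
    """Center, orthogonalize and z-score a stack of fields (pairwise r = 0)."""
    k = fields.shape[0]
    flat = fields.reshape(k, -1).T  # (P, k)
    flat = flat - flat.mean(axis=0, keepdims=True)
    q, r = np.linalg.qr(flat)
    # fix sign so each output correlates positively with its source field
    q = q * np.sign(np.diag(r))
    # columns of q are combinations of zero-mean vectors, hence zero-mean
    q = q / q.std(axis=0, ddof=0, keepdims=True)
    return q.T.reshape(fields.shape)


def generate_modular_components(
    shape: tuple[int, int],
    pixel_um: float,
    wavelength_mm: float,
    k: int,
    rng_seed: int | np.random.Generator = 0,
    rel_bandwidth: float = DEFAULT_REL_BANDWIDTH,
) -> np.ndarray:
    """Generate ``k`` mutually uncorrelated modular spatial components.

    Each component is a zero-mean, unit-SD Gaussian random field whose
    radial autocorrelation has its first minimum at ``wavelength_mm / 2``.
    Components are exactly decorrelated (pairwise Pearson r = 0 over the
    full grid) by QR orthogonalization of the filtered noise fields.

    Raises
    ------
    ValueError
        If the wavelength is not resolvable on the pixel grid (fewer than
        8 pixels per wavelength).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if wavelength_mm * 1000.0 < 8.0 * pixel_um:
        raise ValueError(
            f"wavelength {wavelength_mm} mm spans fewer than 8 pixels at "
            f"{pixel_um} um/px and cannot be represented"
        )
    rng = np.random.default_rng(rng_seed)
    fields = _ring_bandpass_noise(shape, pixel_um, wavelength_mm, k, rng, rel_bandwidth)
    return _orthonormalize(fields)


def generate_white_components(
    shape: tuple[int, int], k: int, rng_seed: int | np.random.Generator = 0
) -> np.ndarray:
    """k spatially unstructured (white-noise) components, zero-mean, unit SD."""
    rng = np.random.default_rng(rng_seed)
    return _orthonormalize(rng.standard_normal((k, *shape)))


def event_pattern(truth: GroundTruth, index: int) -> np.ndarray:
    """Nonnegative ΔF/F spatial pattern of one event.

    The weighted component sum is rectified by mapping its range onto
    ``[floor, 1] * event_amplitude``, so troughs sit at
    ``event_amplitude * module_floor`` and peaks at ``event_amplitude``.
    """
    m = np.tensordot(truth.event_weights[index], truth.component_maps, axes=(0, 0))
    lo, hi = m.min(), m.max()
    if hi - lo <= 0:
        raise ValueError("degenerate (constant) event pattern")
    shape01 = (m - lo) / (hi - lo)
    return truth.event_amplitude * (truth.module_floor + (1.0 - truth.module_floor) * shape01)


def temporal_kernel(truth: GroundTruth, frame_rate_hz: float) -> np.ndarray:
    """Event time course: linear rise, exponential decay, peak value 1."""
    tau_frames = truth.decay_tau_s * frame_rate_hz
    n_decay = max(1, int(np.ceil(3.0 * tau_frames)))
    rise = np.linspace(0.0, 1.0, truth.rise_frames + 1)[1:-1]  # strictly rising
    decay = np.exp(-np.arange(n_decay + 1) / tau_frames)
    return np.concatenate([rise, decay])


def synthesize_movie(
    truth: GroundTruth,
    frame_rate_hz: float = 15.0,
    kind: str = "raw",
) -> tuple[Movie, dict]:
    """Render a ground-truth movie.

    Raw movies follow ``F = B(1 + drift)(1 + sum_events) + B*noise`` where B
    is a flat baseline level; with ``kind='dff'`` the baseline and drift are
    omitted and the movie is the noisy ΔF/F signal directly (useful when a
    test targets the stages downstream of baseline estimation).

    Returns the movie plus a ground-truth dictionary with per-frame event
    labels (``-1`` outside events), the noise-free frame-mean ΔF/F trace and
    the per-event peak frames.
    """
    if kind not in ("raw", "dff"):
        raise ValueError("kind must be 'raw' or 'dff'")
    t_total = truth.n_frames
    h, w = truth.frame_shape
    kernel = temporal_kernel(truth, frame_rate_hz)
    n_rise = truth.rise_frames - 1
    if len(truth.event_times):
        if truth.event_times[0] - n_rise < 0 or truth.event_times[-1] - n_rise + len(kernel) > t_total:
            raise ValueError("event support extends outside the movie")
        starts = truth.event_times - n_rise
        if np.any(starts[1:] < starts[:-1] + len(kernel)):
            raise ValueError("event supports overlap")
        if np.any(np.diff(truth.event_times) < 3):
            raise ValueError("events must be separated by at least 3 frames")

    rng = np.random.default_rng(truth.rng_seed)
    signal = np.zeros((t_total, h, w), dtype=np.float32)
    labels = np.full(t_total, -1, dtype=int)
    clean_trace = np.zeros(t_total)
    for e in range(truth.n_events):
        pat = event_pattern(truth, e)
        t0 = truth.event_times[e] - n_rise
        sl = slice(t0, t0 + len(kernel))
        signal[sl] += kernel[:, None, None].astype(np.float32) * pat.astype(np.float32)
        labels[sl] = e
        clean_trace[sl] += kernel * pat.mean()

    noise = rng.standard_normal((t_total, h, w)).astype(np.float32) * np.float32(truth.noise_sd)
    if kind == "dff":
        data = signal + noise
    else:
        t_s = np.arange(t_total) / frame_rate_hz
        phases = rng.uniform(0, 2 * np.pi, size=len(truth.drift_periods_s))
        drift = np.zeros(t_total)
        for p, ph in zip(truth.drift_periods_s, phases):
            drift += np.sin(2 * np.pi * t_s / p + ph)
        drift *= truth.drift_amplitude / len(truth.drift_periods_s)
        b = truth.baseline_level
        data = b * (1.0 + drift[:, None, None].astype(np.float32)) * (1.0 + signal) + b * noise

    movie = Movie(data=data, pixel_um=truth.pixel_um, frame_rate_hz=frame_rate_hz, kind=kind)
    info = {
        "frame_labels": labels,
        "clean_mean_trace": clean_trace,
        "event_peak_frames": truth.event_times.copy(),
        "true_wavelength_mm": truth.true_wavelength_mm,
        "true_module_amplitude": truth.true_module_amplitude,
        "n_components": truth.n_components,
    }
    return movie, info


def _place_event_times(
    n_events: int,
    support_len: int,
    rise_lead: int,
    min_gap: int,
    max_gap: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Sequentially placed peak frames with random inter-event gaps."""
    times = np.empty(n_events, dtype=int)
    t = rise_lead + int(rng.integers(min_gap, max_gap + 1))
    for i in range(n_events):
        times[i] = t
        t += support_len + int(rng.integers(min_gap, max_gap + 1))
    n_frames = times[-1] - rise_lead + support_len + max_gap if n_events else 10 * min_gap
    return times, int(n_frames)


def modular_ground_truth(
    shape: tuple[int, int] = (540, 640),
    pixel_um: float = 5.5,
    wavelength_mm: float = 1.0,
    n_components: int = 10,
    n_events: int = 50,
    frame_rate_hz: float = 15.0,
    event_amplitude: float = 0.2,
    module_floor: float = 0.5,
    noise_sd: float = 0.02,
    drift_amplitude: float = 0.05,
    min_gap_frames: int = 5,
    max_gap_frames: int = 30,
    rng_seed: int = 0,
) -> GroundTruth:
    """Assemble a :class:`GroundTruth` for a modular spontaneous-activity movie.

    Defaults emulate the acquisition the analysis targets: 15 Hz movies of a
    ~3.5 x 3 mm field of view with events of ~1 mm wavelength drawn from a
    low-dimensional component set.  Pass a smaller ``shape`` (with a
    correspondingly larger ``pixel_um``) for cheap tests.
    """
    ss = np.random.SeedSequence(rng_seed)
    s_comp, s_ev, s_movie = [np.random.default_rng(c) for c in ss.spawn(3)]
    comps = generate_modular_components(shape, pixel_um, wavelength_mm, n_components, s_comp)
    proto = GroundTruth(
        true_wavelength_mm=wavelength_mm,
        pixel_um=pixel_um,
        component_maps=comps,
        event_times=np.array([], dtype=int),
        event_weights=np.empty((0, n_components)),
        n_frames=1,
        decay_tau_s=1.0,
    )
    kernel_len = len(temporal_kernel(proto, frame_rate_hz))
    rise_lead = proto.rise_frames - 1
    times, n_frames = _place_event_times(
        n_events, kernel_len, rise_lead, min_gap_frames, max_gap_frames, s_ev
    )
    weights = s_ev.standard_normal((n_events, n_components))
    seed_movie = int(s_movie.integers(0, 2**31 - 1))
    return GroundTruth(
        true_wavelength_mm=wavelength_mm,
        pixel_um=pixel_um,
        component_maps=comps,
        event_times=times,
        event_weights=weights,
        n_frames=n_frames,
        event_amplitude=event_amplitude,
        module_floor=module_floor,
        noise_sd=noise_sd,
        drift_amplitude=drift_amplitude,
        rng_seed=seed_movie,
    )


def noise_event_ground_truth(
    shape: tuple[int, int] = (96, 96),
    pixel_um: float = 22.0,
    n_events: int = 20,
    frame_rate_hz: float = 15.0,
    event_amplitude: float = 0.2,
    module_floor: float = 0.5,
    noise_sd: float = 0.02,
    rng_seed: int = 0,
) -> GroundTruth:
    """Ground truth whose "events" are spatially unstructured white noise.

    Each event gets its own independent white-noise pattern (identity
    weights over ``n_events`` white components), so detected events carry no
    modular structure — the null case for modularity significance.
    """
    ss = np.random.SeedSequence(rng_seed)
    s_comp, s_ev, s_movie = [np.random.default_rng(c) for c in ss.spawn(3)]
    comps = generate_white_components(shape, n_events, s_comp)
    proto = GroundTruth(
        true_wavelength_mm=1.0,
        pixel_um=pixel_um,
        component_maps=comps,
        event_times=np.array([], dtype=int),
        event_weights=np.empty((0, n_events)),
        n_frames=1,
    )
    kernel_len = len(temporal_kernel(proto, frame_rate_hz))
    times, n_frames = _place_event_times(n_events, kernel_len, proto.rise_frames - 1, 5, 30, s_ev)
    return GroundTruth(
        true_wavelength_mm=1.0,
        pixel_um=pixel_um,
        component_maps=comps,
        event_times=times,
        event_weights=np.eye(n_events),
        n_frames=n_frames,
        event_amplitude=event_amplitude,
        module_floor=module_floor,
        noise_sd=noise_sd,
        rng_seed=int(s_movie.integers(0, 2**31 - 1)),
    )


def independent_modular_patterns(
    shape: tuple[int, int],
    pixel_um: float,
    wavelength_mm: float,
    n: int,
    rng_seed: int | np.random.Generator = 0,
    rel_bandwidth: float = DEFAULT_REL_BANDWIDTH,
) -> np.ndarray:
    """n mutually independent modular fields (no shared components).

    Unlike :func:`generate_modular_components` the fields are not
    orthogonalized: each is an independent draw, so across-pattern
    correlations at any pixel pair are O(1/sqrt(n)).  This is the
    unstructured control for long-range correlation strength: every pattern
    is modular, but patterns share no systematic spatial relationship.
    """
    if wavelength_mm * 1000.0 < 8.0 * pixel_um:
        raise ValueError("wavelength not resolvable on this grid")
    rng = np.random.default_rng(rng_seed)
    fields = _ring_bandpass_noise(shape, pixel_um, wavelength_mm, n, rng, rel_bandwidth)
    flat = fields.reshape(n, -1)
    flat = flat - flat.mean(axis=1, keepdims=True)
    flat /= flat.std(axis=1, ddof=0, keepdims=True)
    return flat.reshape(fields.shape)
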