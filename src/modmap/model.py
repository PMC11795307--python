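"""Statsmodels-style front end: a model bound to one experiment's movie,
whose :meth:`SpontaneousActivityModel.fit` runs the full analysis and
returns a results object with the estimates, their spreads, the p-values
and a printable summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig, stage_rng
from .containers import (
    CorrelationStrength,
    DimensionalityResult,
    EventCatalog,
    ModularitySignificance,
    Movie,
    PatternSet,
    RoiMask,
)
from .detection import detect_events
from .filtering import build_pattern_set, correlation_field
from .metrics import event_metrics_table, modularity_significance
from .network import corrected_long_range_strength, cross_validated_dimensionality
from .preprocess import preprocess_movie

__all__ = ["SpontaneousActivityModel", "SpontaneousActivityResults"]

log = logging.getLogger(__name__)


class SpontaneousActivityModel:
    """Modular spontaneous-activity analysis of one wide-field experiment.

    Parameters
    ----------
    movie : Movie
        Raw fluorescence or ΔF/F movie.
    roi : RoiMask, optional
        Region of interest; defaults to the full frame.
    config : AnalysisConfig, optional
        Analysis parameters; validated on construction.

    Examples
    --------
    >>> from modmap import synthetic, SpontaneousActivityModel
    >>> truth = synthetic.modular_ground_truth(shape=(136, 160), pixel_um=22.0,
    ...                                        n_events=30, rng_seed=1)
    >>> movie, info = synthetic.synthesize_movie(truth)
    >>> res = SpontaneousActivityModel(movie).fit()
    >>> print(res.summary())                       # doctest: +SKIP
    """

    def __init__(
        self,
        movie: Movie,
        roi: RoiMask | None = None,
        config: AnalysisConfig | None = None,
    ) -> None:
        self.movie = movie
        self.roi = roi if roi is not None else RoiMask.full(movie.frame_shape, movie.pixel_um)
        if self.roi.mask.shape != movie.frame_shape:
            raise ValueError("ROI grid does not match the movie")
        self.config = (config or AnalysisConfig()).validate()

    @classmethod
    def from_hdf5(cls, path, roi: RoiMask | None = None, config: AnalysisConfig | None = None):
        from .io import load_movie_h5

        return cls(load_movie_h5(path), roi=roi, config=config)

    def fit(self, skip_network: bool = False) -> "SpontaneousActivityResults":
        """Run detection, pattern metrics, significance and network metrics.

        ``skip_network`` stops after the per-event metrics (useful when the
        field of view cannot support the long-range ring).
        """
        cfg = self.config
        movie, roi = self.movie, self.roi
        if movie.kind == "raw":
            log.info("preprocessing: baseline window %.1f s", cfg.window_s)
            dff = preprocess_movie(movie, roi, window_s=cfg.window_s, register=cfg.register)
        else:
            dff = movie
        log.info("detecting events (%s)", cfg.detection_method)
        catalog = detect_events(
            dff,
            roi,
            method=cfg.detection_method,
            min_area_mm2=cfg.min_area_mm2,
            min_active_fraction=cfg.min_active_fraction,
        )
        if len(catalog) == 0:
            raise RuntimeError("no events detected; nothing to analyse")
        pset = build_pattern_set(
            catalog.event_frames_raw, roi, cfg.s_low_um, cfg.s_high_um, ds_factor=cfg.ds_factor
        )
        metrics = event_metrics_table(
            pset, catalog, roi, bin_width_mm=cfg.bin_width_mm
        )
        signif = modularity_significance(
            metrics["modularity"].to_numpy(),
            dff,
            catalog,
            roi,
            cfg.s_low_um,
            cfg.s_high_um,
            ds_factor=cfg.ds_factor,
            bin_width_mm=cfg.bin_width_mm,
            n_sets=cfg.n_control_sets,
            rng_seed=stage_rng(cfg.rng_seed, "significance"),
        )
        strength = None
        dim = None
        median_wl = float(np.nanmedian(metrics.loc[metrics["valid"], "wavelength_mm"]))
        if not skip_network and len(catalog) >= 2:
            try:
                strength = corrected_long_range_strength(
                    pset,
                    n_use=cfg.n_events_use,
                    n_surrogates=cfg.n_surrogates,
                    ring_mm=cfg.ring_mm,
                    rng_seed=stage_rng(cfg.rng_seed, "strength"),
                )
            except ValueError as exc:
                log.warning("long-range strength unavailable: %s", exc)
            try:
                dim = cross_validated_dimensionality(
                    pset,
                    median_wl,
                    n_subsets=cfg.n_subsets,
                    subset_size=cfg.subset_size,
                    rng_seed=stage_rng(cfg.rng_seed, "dimensionality"),
                )
            except ValueError as exc:
                log.warning("dimensionality unavailable: %s", exc)
        return SpontaneousActivityResults(
            model=self,
            dff=dff,
            catalog=catalog,
            pattern_set=pset,
            metrics=metrics,
            significance=signif,
            strength=strength,
            dimensionality=dim,
        )


@dataclass
class SpontaneousActivityResults:
    """Results of :meth:`SpontaneousActivityModel.fit`.

    Attributes
    ----------
    metrics : pandas.DataFrame
        Per-event wavelength (mm), modularity, module amplitude, validity.
    significance : ModularitySignificance
        Median event modularity versus 100 control-frame sets.
    strength : CorrelationStrength or None
        Long-range (1.8–2.2 mm) correlation variance, surrogate-corrected.
    dimensionality : DimensionalityResult or None
        Cross-validated participation-ratio dimensionality.
    """

    model: SpontaneousActivityModel
    dff: Movie
    catalog: EventCatalog
    pattern_set: PatternSet
    metrics: pd.DataFrame
    significance: ModularitySignificance
    strength: CorrelationStrength | None = None
    dimensionality: DimensionalityResult | None = None

    @property
    def n_events(self) -> int:
        return len(self.catalog)

    @property
    def median_wavelength_mm(self) -> float:
        valid = self.metrics["valid"]
        return float(np.nanmedian(self.metrics.loc[valid, "wavelength_mm"]))

    @property
    def median_modularity(self) -> float:
        valid = self.metrics["valid"]
        return float(np.nanmedian(self.metrics.loc[valid, "modularity"]))

    @property
    def mean_module_amplitude(self) -> float:
        if "module_amplitude" not in self.metrics:
            return float("nan")
        return float(np.nanmean(self.metrics["module_amplitude"]))

    @property
    def d_eff(self) -> float:
        return self.dimensionality.d_eff if self.dimensionality is not None else float("nan")

    def correlation_field(self, seed: tuple[int, int]):
        """Seed-point correlation field on the downsampled grid (display)."""
        return correlation_field(self.pattern_set, seed)

    def experiment_row(self) -> dict:
        """Flat per-experiment record (one row of an aggregate table)."""
        iqr = lambda col: (
            float(np.nanpercentile(col, 75) - np.nanpercentile(col, 25)) if len(col) else np.nan
        )
        wl = self.metrics.loc[self.metrics["valid"], "wavelength_mm"].to_numpy()
        mod = self.metrics.loc[self.metrics["valid"], "modularity"].to_numpy()
        row = {
            "n_events": self.n_events,
            "n_valid_events": int(self.metrics["valid"].sum()),
            "median_wavelength_mm": self.median_wavelength_mm,
            "iqr_wavelength_mm": iqr(wl),
            "median_modularity": self.median_modularity,
            "iqr_modularity": iqr(mod),
            "mean_module_amplitude": self.mean_module_amplitude,
            "modularity_p": self.significance.p_value,
            "modularity_significant": self.significance.significant,
        }
        if self.strength is not None:
            row.update(
                variance_real=self.strength.variance_real,
                variance_surrogate=self.strength.variance_surrogate,
                corrected_strength=self.strength.corrected,
                strength_p=self.strength.p_value,
                strength_significant=self.strength.significant,
            )
        if self.dimensionality is not None:
            row.update(
                d_eff=self.dimensionality.d_eff,
                d_eff_sd=float(np.std(self.dimensionality.per_subset, ddof=1))
                if len(self.dimensionality.per_subset) > 1
                else np.nan,
            )
        return row

    def summary(self) -> str:
        """Human-readable summary of the experiment-level estimates."""
        cfg = self.model.config
        lines = []
        add = lines.append
        bar = "=" * 64
        add(bar)
        add("Spontaneous activity analysis".center(64))
        add(bar)
        add(f"{'Movie':<28}{self.model.movie.n_frames} frames @ {self.model.movie.frame_rate_hz:g} Hz")
        add(f"{'ROI pixels':<28}{self.model.roi.n_pixels}")
        add(f"{'Detection method':<28}{cfg.detection_method}")
        add(f"{'Events detected':<28}{self.n_events} ({int(self.metrics['valid'].sum())} with valid metrics)")
        add("-" * 64)
        add(f"{'Median wavelength (mm)':<32}{self.median_wavelength_mm:8.3f}")
        add(f"{'Median modularity':<32}{self.median_modularity:8.4f}")
        if np.isfinite(self.mean_module_amplitude):
            add(f"{'Mean module amplitude':<32}{self.mean_module_amplitude:8.3f}")
        add(
            f"{'Modularity vs controls':<32}p = {self.significance.p_value:.4g}"
            f"{'  *' if self.significance.significant else ''}"
        )
        if self.strength is not None:
            s = self.strength
            add(
                f"{'Long-range ring (mm)':<32}{s.ring_mm[0]:.1f}-{s.ring_mm[1]:.1f}"
                f"  (n_events = {s.n_events_used})"
            )
            add(f"{'Ring variance (real)':<32}{s.variance_real:8.5f}")
            add(f"{'Ring variance (surrogate)':<32}{s.variance_surrogate:8.5f}")
            add(f"{'Corrected strength':<32}{s.corrected:8.5f}")
            add(f"{'Strength vs surrogates':<32}p = {s.p_value:.4g}{'  *' if s.significant else ''}")
        if self.dimensionality is not None:
            d = self.dimensionality
            sd = np.std(d.per_subset, ddof=1) if len(d.per_subset) > 1 else np.nan
            add(f"{'Dimensionality d_eff':<32}{d.d_eff:8.3f} +/- {sd:.3f} (SD over subsets)")
            add(f"{'Analysis region (mm^2)':<32}{d.region_area_mm2:8.3f}")
        add(bar)
        return "\n".join(lines)

    def plot_event(self, i: int, ax=None):
        """QC image: raw event frame and its band-passed pattern."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(1, 2, figsize=(8, 3.5))
        raw = self.catalog.event_frames_raw[i]
        ax[0].imshow(np.where(self.model.roi.mask, raw, np.nan), cmap="gray")
        ax[0].set_title(f"event {i} raw ΔF/F")
        ax[1].imshow(self.pattern_set.patterns[i], cmap="RdBu_r")
        ax[1].set_title("band-passed pattern")
        for a in ax:
            a.axis("off")
        return ax

    def plot_correlation(self, seed: tuple[int, int], ax=None):
        """QC image: seed-point correlation field."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 3.5))
        fld = self.correlation_field(seed)
        im = ax.imshow(fld.values, cmap="RdBu_r", vmin=-1, vmax=1)
        ax.plot(seed[1], seed[0], "k+", ms=10)
        ax.set_title(f"C(x, s), seed {seed}")
        ax.axis("off")
        plt.colorbar(im, ax=ax, label="Pearson r")
        return ax
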