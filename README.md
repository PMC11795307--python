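# modmap

Analysis of modular spontaneous activity in wide-field calcium imaging of
developing cortex.

In the developing cortex of carnivores, spontaneous activity is organised
into *modular* patterns: distributed patches of co-active neurons with a
characteristic spacing (wavelength) near 1 mm, correlated over several
millimetres, and drawn from a low-dimensional repertoire of spatial modes.
`modmap` implements the full measurement chain used to quantify these
properties in ΔF/F movies from wide-field imaging:

1. **Preprocessing** — rigid registration, per-pixel running-median baseline
   F₀ (window 10–64 s), and ΔF/F = (F − F₀)/F₀.
2. **Event detection** — per-pixel activity thresholds (a Gaussian fitted to
   the sub-event bulk of each pixel's histogram, threshold μ + 3σ, or the
   80th percentile of the pixel's trace), followed by two spatial criteria:
   active pixels must form contiguous regions ≥ 0.01 mm², and an active
   frame needs > 40% of ROI pixels active.  Runs of active frames become
   events, split at local minima of the ROI-mean trace; each event is
   represented by its maximally active frame.
3. **Pattern metrics** — each event frame is band-pass filtered
   (difference of Gaussians, SDs s_low ≈ 30 μm and s_high = 195 μm) and
   downsampled; the wavelength Λ is twice the radius of the first minimum
   of the radially averaged spatial autocorrelation, the *modularity* is
   the trough-to-peak amplitude of that profile, and the *module amplitude*
   is the raw-frame peak ΔF/F divided by the median ΔF/F half a wavelength
   away.  Event modularity is tested against 100 sets of low-activity
   control frames.
4. **Correlation structure** — seed-point correlation fields
   C(**x**, **s**) = ⟨(Aᵢ(**x**) − ⟨Aᵢ(**x**)⟩)(Aᵢ(**s**) − ⟨Aᵢ(**s**)⟩)⟩ / (σ_x σ_s)
   across the band-passed event patterns Aᵢ; long-range correlation strength
   is the variance of C in a 1.8–2.2 mm ring around each seed, corrected by
   comparison with rotation/reflection surrogate ensembles that destroy the
   spatial relationships between patterns while preserving each pattern's
   own statistics.
5. **Dimensionality** — the cross-validated participation ratio
   d_eff = (Σλᵢ)² / Σλᵢ², where λᵢ is the variance of held-out event
   patterns projected on principal axes learned from a disjoint half of the
   events, inside a circular region of area 0.5 Λ².

Because raw recordings of this kind are rarely public, the package ships a
first-class **synthetic-movie generator** with fully known ground truth
(wavelength, component count, event times, module contrast, noise), so every
stage has a parameter-recovery test.

## Worked example

```python
from modmap import synthetic, SpontaneousActivityModel, AnalysisConfig

truth = synthetic.modular_ground_truth(
    shape=(136, 160), pixel_um=22.0, wavelength_mm=1.0,
    n_components=8, n_events=30, noise_sd=0.02, rng_seed=7,
)
movie, info = synthetic.synthesize_movie(truth)   # raw fluorescence, 15 Hz
cfg = AnalysisConfig(ds_factor=4, n_events_use=30, n_surrogates=20,
                     subset_size=30, rng_seed=1)
res = SpontaneousActivityModel(movie, config=cfg).fit()
print(res.summary())
```

prints

```
================================================================
                 Spontaneous activity analysis
================================================================
Movie                       1890 frames @ 15 Hz
ROI pixels                  21760
Detection method            gaussian3sd
Events detected             30 (30 with valid metrics)
----------------------------------------------------------------
Median wavelength (mm)             0.949
Median modularity                 0.4269
Mean module amplitude              1.666
Modularity vs controls          p = 0.009901  *
Long-range ring (mm)            1.8-2.2  (n_events = 30)
Ring variance (real)             0.10787
Ring variance (surrogate)        0.08634
Corrected strength               0.02153
Strength vs surrogates          p = 0.09524
Dimensionality d_eff               4.739 +/- 0.427 (SD over subsets)
Analysis region (mm^2)             0.451
================================================================
```

All 30 generated events are detected; the estimated wavelength (0.949 mm)
recovers the generated 1 mm spacing within ~5%, and event modularity is
highly significant against quiet control frames (p ≈ 0.01, the continuity
floor of a 100-set bootstrap).  The surrogate-corrected long-range strength
is positive but, with only 30 events on a 3.5 × 3 mm field of view, does not
reach significance at α = 0.05 here — at 100 events (the count the analysis
normally fixes) shared-component movies are flagged significant in
essentially every run (see the acceptance report).  The dimensionality
d_eff ≈ 4.7 reflects the eight generating components as seen through the
small 0.5 Λ² analysis region; `res.metrics` holds the per-event table, and
`res.plot_event(i)` / `res.plot_correlation(seed)` give QC images.

## Command line

Each stage is also a CLI subcommand over the same library:

```bash
modmap simulate --out movie.h5 --shape 136 160 --pixel-um 22 --n-events 30
modmap preprocess --movie movie.h5 --window-s 30 --out dff.h5
modmap detect --dff dff.h5 --method gaussian3sd --out events.h5
modmap metrics --events events.h5 --pixel-um 22 --out metrics.csv
modmap network --events events.h5 --pixel-um 22 --out network.csv
modmap run --config run.yaml          # the whole chain, seeded + manifested
modmap aggregate run1 run2 --out experiments.csv
```

`modmap run` consumes a YAML config (see `modmap.config.RunConfig`), writes
events (HDF5), per-event metrics and a per-experiment network table (CSV),
plus a JSON manifest with versions and the seed; identical configs reproduce
byte-identical tables.

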