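"""Tests of radial autocorrelation, wavelength/modularity, module amplitude
and the modularity-significance bootstrap."""

import numpy as np
import pytest
from scipy import ndimage

from modmap import synthetic
from modmap.containers import RadialProfile, RoiMask
from modmap.filtering import build_pattern_set
from modmap.metrics import (
    event_metrics_table,
    modularity_significance,
    module_amplitude,
    pattern_modularity,
    radial_autocorrelation,
    wavelength_and_modularity,
)


def brute_force_masked_radial_ac(pattern, roi, pixel_um, bin_width_mm):
    """Independent oracle: all-pairs masked autocorrelation, annulus-binned."""
    p = np.where(roi, pattern, np.nan)
    p = p - np.nanmean(p)
    h, w = p.shape
    acc, cnt = {}, {}
    for dy in range(-(h - 1), h):
        for dx in range(-(w - 1), w):
            a = p[max(0, dy) : h + min(0, dy), max(0, dx) : w + min(0, dx)]
            b = p[max(0, -dy) : h + min(0, -dy), max(0, -dx) : w + min(0, -dx)]
            both = np.isfinite(a) & np.isfinite(b)
            if not both.any():
                continue
            val = np.mean(a[both] * b[both])
            k = int(round(np.hypot(dy, dx) * pixel_um / 1000.0 / bin_width_mm))
            acc[k] = acc.get(k, 0.0) + val
            cnt[k] = cnt.get(k, 0) + 1
    var = acc[0] / cnt[0]
    ks = sorted(acc)
    return np.array([acc[k] / cnt[k] / var for k in ks]), ks


class TestRadialAutocorrelation:
    def test_matches_brute_force_on_masked_crop(self):
        rng = np.random.default_rng(0)
        pat = ndimage.gaussian_filter(rng.standard_normal((32, 32)), 2)
        yy, xx = np.mgrid[0:32, 0:32]
        roi = (yy - 15.5) ** 2 + (xx - 15.5) ** 2 <= 15**2
        prof = radial_autocorrelation(pat, roi, 22.0)
        expected, ks = brute_force_masked_radial_ac(pat, roi, 22.0, prof.bin_width_mm)
        n = min(len(prof.values), len(expected))
        np.testing.assert_allclose(prof.values[:n], expected[:n], atol=1e-8)

    def test_zero_lag_value_is_one(self):
        pat = np.random.default_rng(1).standard_normal((24, 24))
        prof = radial_autocorrelation(pat, np.ones((24, 24), bool), 22.0)
        assert prof.values[0] == pytest.approx(1.0, abs=1e-12)
        assert prof.radii_mm[0] == 0.0

    def test_white_noise_decorrelates_immediately(self):
        pat = np.random.default_rng(2).standard_normal((64, 64))
        prof = radial_autocorrelation(pat, np.ones((64, 64), bool), 22.0)
        far = prof.radii_mm > 3 * 22.0 / 1000.0
        assert np.nanmax(np.abs(prof.values[far])) < 0.05

    def test_constant_pattern_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            radial_autocorrelation(np.ones((16, 16)), np.ones((16, 16), bool), 22.0)

    def test_amplitude_scaling_invariance(self):
        pat = np.random.default_rng(3).standard_normal((32, 32))
        p1 = radial_autocorrelation(pat, np.ones((32, 32), bool), 22.0)
        p2 = radial_autocorrelation(5.0 * pat, np.ones((32, 32), bool), 22.0)
        np.testing.assert_allclose(p1.values, p2.values, atol=1e-10)


class TestWavelengthAndModularity:
    def _damped_cosine_profile(self, wavelength=1.0, bin_mm=0.022):
        r = np.arange(0, 1.6, bin_mm)
        vals = np.exp(-r / (2 * wavelength)) * np.cos(2 * np.pi * r / wavelength)
        return RadialProfile(radii_mm=r, values=vals, bin_width_mm=bin_mm)

    def test_damped_cosine_profile_recovered(self):
        prof = self._damped_cosine_profile()
        wl, mod, valid = wavelength_and_modularity(prof)
        assert valid
        assert wl == pytest.approx(1.0, abs=2 * prof.bin_width_mm * 2)
        # modularity ~ difference between value at the minimum (~ -e^{-1/4})
        # and at the following maximum (~ +e^{-1/2})
        expected = np.exp(-0.5) + np.exp(-0.25)
        assert mod == pytest.approx(expected, rel=0.10)

    def test_monotonic_profile_flagged_invalid(self):
        r = np.arange(0, 1.0, 0.02)
        prof = RadialProfile(r, np.exp(-r / 0.3), 0.02)
        wl, mod, valid = wavelength_and_modularity(prof)
        assert not valid and np.isnan(wl)

    def test_too_short_profile_rejected(self):
        with pytest.raises(ValueError, match="3 bins"):
            wavelength_and_modularity(RadialProfile(np.array([0.0, 0.1]), np.array([1.0, 0.5]), 0.1))

    def test_synthetic_events_recover_wavelength(self):
        truth = synthetic.modular_ground_truth(
            shape=(128, 128), pixel_um=22.0, wavelength_mm=0.8,
            n_components=8, n_events=40, rng_seed=21,
        )
        frames = np.stack([synthetic.event_pattern(truth, i) for i in range(truth.n_events)])
        roi = RoiMask.full((128, 128), 22.0)
        pset = build_pattern_set(frames, roi, 30.0, 195.0, ds_factor=1)
        wls = [pattern_modularity(p, pset.roi_ds, pset.pixel_um_ds)[0] for p in pset.patterns]
        assert 0.72 <= np.nanmedian(wls) <= 0.88

    def test_noise_patterns_less_modular_than_modular_patterns(self):
        # paired comparison at matched power: band-passed white noise vs
        # ring-spectrum modular fields
        rng = np.random.default_rng(5)
        roi = np.ones((96, 96), bool)
        mods_noise, mods_mod = [], []
        fields = synthetic.independent_modular_patterns((96, 96), 22.0, 1.0, 40, rng_seed=6)
        roi_m = RoiMask.full((96, 96), 22.0)
        noise_frames = rng.standard_normal((40, 96, 96))
        pset_n = build_pattern_set(noise_frames, roi_m, 30.0, 195.0, ds_factor=1)
        for i in range(40):
            _, m_n, v_n = pattern_modularity(pset_n.patterns[i], roi, 22.0)
            _, m_m, v_m = pattern_modularity(fields[i], roi, 22.0)
            mods_noise.append(m_n if v_n else 0.0)
            mods_mod.append(m_m if v_m else 0.0)
        assert np.all(np.array(mods_mod) > np.array(mods_noise))


class TestModuleAmplitude:
    def _concentric_cosine(self, offset=0.10, amp=0.05, wavelength=1.0):
        h = w = 121
        px = 22.0
        yy, xx = np.mgrid[0:h, 0:w]
        r_mm = np.hypot(yy - (h - 1) / 2, xx - (w - 1) / 2) * px / 1000.0
        frame = offset + amp * np.cos(2 * np.pi * r_mm / wavelength)
        roi = RoiMask(r_mm <= 0.7, px)
        return frame, roi

    def test_closed_form_cosine_amplitude(self):
        # peak 0.15 over background 0.05 at half-wavelength -> ratio 3
        frame, roi = self._concentric_cosine()
        amp, valid = module_amplitude(frame, roi, 1.0, noise_sd=0.001)
        assert valid
        assert amp == pytest.approx(3.0, rel=0.05)

    def test_uniform_frame_has_no_peaks(self):
        frame = np.full((64, 64), 0.1)
        amp, valid = module_amplitude(frame, RoiMask.full((64, 64), 22.0), 1.0, noise_sd=0.01)
        assert not valid and np.isnan(amp)

    def test_recovery_matches_brute_force_oracle_on_noiseless_patterns(self):
        truth = synthetic.modular_ground_truth(
            shape=(136, 160), pixel_um=22.0, wavelength_mm=1.0,
            n_components=8, n_events=12, rng_seed=31,
        )
        roi = RoiMask.full((136, 160), 22.0)
        est, oracle = [], []
        for i in range(truth.n_events):
            pat = synthetic.event_pattern(truth, i)
            a, v = module_amplitude(pat, roi, 1.0, noise_sd=0.002)
            if v:
                est.append(a)
            oracle.append(self._oracle_amplitude(pat, 22.0, 1.0))
        assert np.mean(est) == pytest.approx(np.mean(oracle), rel=0.10)

    @staticmethod
    def _oracle_amplitude(pat, pixel_um, wavelength_mm):
        """Brute-force peak/annulus-median on the noiseless pattern."""
        h, w = pat.shape
        r = int(round(0.25 * wavelength_mm * 1000 / pixel_um))
        gy, gx = np.mgrid[0:h, 0:w]
        vals = []
        for py in range(r, h - r):
            for px_ in range(r, w - r):
                win = pat[py - r : py + r + 1, px_ - r : px_ + r + 1]
                if pat[py, px_] < win.max() or pat[py, px_] <= np.median(pat):
                    continue
                d_um = np.hypot(gy - py, gx - px_) * pixel_um
                ring = np.abs(d_um - 0.5 * wavelength_mm * 1000) <= max(pixel_um, 22.0)
                bg = np.median(pat[ring])
                if bg > 0:
                    vals.append(pat[py, px_] / bg)
        return np.mean(vals)

    def test_contrast_monotonicity(self):
        # lower module_floor (higher contrast) must give larger amplitude
        amps = {}
        for floor in (0.4, 0.7):
            truth = synthetic.modular_ground_truth(
                shape=(128, 128), pixel_um=22.0, wavelength_mm=1.0,
                n_components=6, n_events=8, module_floor=floor, rng_seed=33,
            )
            roi = RoiMask.full((128, 128), 22.0)
            vals = [
                module_amplitude(synthetic.event_pattern(truth, i), roi, 1.0, noise_sd=0.002)[0]
                for i in range(truth.n_events)
            ]
            amps[floor] = np.nanmean(vals)
        assert amps[0.4] > amps[0.7]

    def test_invalid_wavelength_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            module_amplitude(np.zeros((16, 16)), RoiMask.full((16, 16), 22.0), np.nan)


class TestModularitySignificance:
    def test_modular_movie_significant(self, modular_movie, modular_catalog):
        movie, info, roi, truth = modular_movie
        pset = build_pattern_set(modular_catalog.event_frames_raw, roi, 30.0, 195.0, ds_factor=4)
        df = event_metrics_table(pset)
        sig = modularity_significance(
            df["modularity"].to_numpy(), movie, modular_catalog, roi,
            30.0, 195.0, ds_factor=4, rng_seed=0,
        )
        assert sig.p_value < 0.05
        assert len(sig.control_medians) == 100
        assert sig.observed_median > np.median(sig.control_medians)

    def test_too_few_nonevent_frames_rejected(self, modular_movie, modular_catalog):
        movie, info, roi, truth = modular_movie
        from modmap.containers import EventCatalog

        cat = EventCatalog(intervals=np.array([[0, movie.n_frames - 3, 1]]))
        with pytest.raises(ValueError, match="non-event"):
            modularity_significance(
                np.array([0.5]), movie, cat, roi, 30.0, 195.0, ds_factor=4
            )

    def test_events_drawn_from_control_pool_not_significant(self, modular_movie):
        # exchangeability: when "events" are plain quiet frames, the observed
        # median is a typical control median
        movie, info, roi, truth = modular_movie
        from modmap.containers import EventCatalog

        rejections = 0
        n_seeds = 8
        quiet = np.flatnonzero(info["frame_labels"] < 0)
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            fake = np.sort(rng.choice(quiet[: len(quiet) // 2], size=10, replace=False))
            fake = fake[np.insert(np.diff(fake) > 1, 0, True)]
            cat = EventCatalog(intervals=np.stack([fake, fake, fake], axis=1))
            pset = build_pattern_set(movie.data[fake], roi, 30.0, 195.0, ds_factor=4)
            df = event_metrics_table(pset)
            mods = np.where(df["valid"], df["modularity"], 0.0)
            sig = modularity_significance(
                mods, movie, cat, roi, 30.0, 195.0, ds_factor=4, rng_seed=seed
            )
            rejections += sig.p_value < 0.05
        assert rejections <= 1
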