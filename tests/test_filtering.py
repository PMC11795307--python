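"""Tests of band-pass filtering, correlation fields and surrogate ensembles."""

import numpy as np
import pytest
from scipy import stats

from modmap.containers import PatternSet, RoiMask
from modmap.filtering import (
    SURROGATE_ANGLES_DEG,
    apply_pattern_transform,
    bandpass_and_downsample,
    build_pattern_set,
    correlation_field,
    correlation_matrix,
    make_surrogate_ensemble,
    roi_coordinates_mm,
    surrogate_pattern_set,
)


def random_pattern_set(n=7, shape=(8, 8), seed=1):
    rng = np.random.default_rng(seed)
    return PatternSet(rng.standard_normal((n, *shape)), np.ones(shape, bool), 100.0, 30.0, 195.0)


class TestBandpass:
    def test_constant_frame_maps_to_zero(self):
        roi = RoiMask.full((64, 64), 22.0)
        pat, _, _ = bandpass_and_downsample(np.full((64, 64), 3.0), roi, 30.0, 195.0)
        np.testing.assert_allclose(pat[roi.mask], 0.0, atol=1e-10)

    def test_sinusoid_attenuation_matches_analytic_transfer(self):
        # difference-of-Gaussians amplitude response at 1 cycle/mm
        h, w, px = 128, 128, 22.0
        x_mm = np.arange(w) * px / 1000.0
        frame = np.sin(2 * np.pi * x_mm)[None, :].repeat(h, axis=0)
        roi = RoiMask.full((h, w), px)
        pat, _, _ = bandpass_and_downsample(frame, roi, 30.0, 195.0, ds_factor=1)
        s_low, s_high = 0.030, 0.195
        analytic = np.exp(-2 * np.pi**2 * s_low**2) - np.exp(-2 * np.pi**2 * s_high**2)
        measured = np.nanmax(np.abs(pat[h // 2, 20:-20]))
        assert measured == pytest.approx(analytic, rel=0.05)

    def test_downsampling_geometry(self):
        roi = RoiMask.full((160, 136), 22.0)
        frame = np.random.default_rng(0).standard_normal((160, 136))
        pat, roi_ds, px_ds = bandpass_and_downsample(
            frame, roi, 30.0, 195.0, target_dims=(40, 34)
        )
        assert pat.shape == (40, 34)
        assert px_ds == pytest.approx(4 * 22.0)
        assert roi_ds.all()

    def test_non_integer_target_rejected(self):
        roi = RoiMask.full((64, 64), 22.0)
        with pytest.raises(ValueError, match="factor"):
            bandpass_and_downsample(np.zeros((64, 64)), roi, 30.0, 195.0, target_dims=(30, 30))

    def test_filter_order_validated(self):
        roi = RoiMask.full((32, 32), 22.0)
        with pytest.raises(ValueError, match="s_low"):
            bandpass_and_downsample(np.zeros((32, 32)), roi, 200.0, 100.0)

    def test_small_roi_warns(self):
        roi = RoiMask.full((12, 12), 22.0)  # 264 um extent < 2 * 195 um
        with pytest.warns(UserWarning, match="s_high"):
            bandpass_and_downsample(np.ones((12, 12)), roi, 30.0, 195.0)


class TestCorrelationField:
    def test_self_correlation_is_one(self):
        pset = random_pattern_set()
        fld = correlation_field(pset, (3, 4))
        assert fld.values[3, 4] == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_pearson(self):
        pset = random_pattern_set(n=9, shape=(8, 8), seed=5)
        fld = correlation_field(pset, (2, 6))
        for i in range(8):
            for j in range(8):
                expected = np.corrcoef(pset.patterns[:, i, j], pset.patterns[:, 2, 6])[0, 1]
                assert fld.values[i, j] == pytest.approx(expected, abs=1e-10)

    def test_rank_one_patterns_give_unit_magnitude(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal((6, 6))
        w = rng.standard_normal(5) + 2.0
        pset = PatternSet(w[:, None, None] * base, np.ones((6, 6), bool), 100.0, 30.0, 195.0)
        fld = correlation_field(pset, (1, 1))
        finite = np.isfinite(fld.values)
        np.testing.assert_allclose(np.abs(fld.values[finite]), 1.0, atol=1e-8)

    def test_affine_rescaling_invariance(self):
        # a common affine map a*A + b (a > 0) leaves every Pearson field unchanged
        pset = random_pattern_set(seed=7)
        scaled = PatternSet(
            2.7 * pset.patterns - 1.3,
            pset.roi_ds, pset.pixel_um_ds, pset.s_low_um, pset.s_high_um,
        )
        f1 = correlation_field(pset, (4, 4))
        f2 = correlation_field(scaled, (4, 4))
        np.testing.assert_allclose(f1.values, f2.values, atol=1e-6)

    def test_too_few_patterns_rejected(self):
        pset = random_pattern_set(n=1)
        with pytest.raises(ValueError, match="2 patterns"):
            correlation_field(pset, (0, 0))

    def test_zero_variance_seed_rejected(self):
        pats = np.random.default_rng(0).standard_normal((5, 4, 4))
        pats[:, 2, 2] = 1.0
        pset = PatternSet(pats, np.ones((4, 4), bool), 100.0, 30.0, 195.0)
        with pytest.raises(ValueError, match="variance"):
            correlation_field(pset, (2, 2))

    def test_matrix_consistent_with_single_seed_fields(self):
        pset = random_pattern_set(n=6, shape=(5, 5), seed=11)
        cmat, idx = correlation_matrix(pset)
        fld = correlation_field(pset, (2, 3))
        col = np.full(25, np.nan)
        col[idx] = cmat[:, np.flatnonzero(idx == 2 * 5 + 3)[0]]
        np.testing.assert_allclose(col.reshape(5, 5), fld.values, atol=1e-5)

    def test_roi_coordinates_in_mm(self):
        pset = random_pattern_set(shape=(4, 4))
        coords = roi_coordinates_mm(pset)
        assert coords.shape == (16, 2)
        assert coords.max() == pytest.approx(3 * 0.1)  # 100 um pixels


class TestSurrogates:
    def test_identity_transform_is_exact(self):
        pset = random_pattern_set()
        out = apply_pattern_transform(pset.patterns[0], pset.roi_ds, 0.0, False, False)
        np.testing.assert_allclose(out, pset.patterns[0], atol=1e-12)

    def test_flip_is_involution(self):
        pset = random_pattern_set(shape=(8, 8))
        once = apply_pattern_transform(pset.patterns[0], pset.roi_ds, 0.0, True, False)
        twice = apply_pattern_transform(once, pset.roi_ds, 0.0, True, False)
        np.testing.assert_allclose(twice, pset.patterns[0], atol=1e-10)

    def test_exact_transforms_preserve_value_histogram(self):
        pset = random_pattern_set(shape=(10, 10), seed=4)
        out = apply_pattern_transform(pset.patterns[0], pset.roi_ds, 180.0, True, True)
        np.testing.assert_allclose(
            np.sort(out[np.isfinite(out)]), np.sort(pset.patterns[0].ravel()), atol=1e-10
        )

    def test_rotation_confined_to_roi(self):
        yy, xx = np.mgrid[0:21, 0:21]
        roi = (yy - 10) ** 2 + (xx - 10) ** 2 <= 100
        pat = np.where(roi, np.random.default_rng(0).standard_normal((21, 21)), np.nan)
        out = apply_pattern_transform(pat, roi, 30.0, False, False)
        assert np.all(np.isnan(out[~roi]))

    def test_angles_uniform_over_36_values(self):
        pset = random_pattern_set(n=10_000, shape=(2, 2), seed=0)
        ens = make_surrogate_ensemble(pset, rng_seed=123)
        counts = np.array([(ens.angles_deg == a).sum() for a in SURROGATE_ANGLES_DEG])
        freqs = counts / counts.sum()
        assert np.all(np.abs(freqs - 1 / 36) <= 0.01)
        chi2, p = stats.chisquare(counts)
        assert p > 1e-4

    def test_deterministic_given_seed(self):
        pset = random_pattern_set(n=12)
        e1 = make_surrogate_ensemble(pset, rng_seed=9)
        e2 = make_surrogate_ensemble(pset, rng_seed=9)
        np.testing.assert_array_equal(e1.angles_deg, e2.angles_deg)
        np.testing.assert_array_equal(
            np.isnan(e1.patterns_surrogate), np.isnan(e2.patterns_surrogate)
        )
        finite = np.isfinite(e1.patterns_surrogate)
        np.testing.assert_array_equal(
            e1.patterns_surrogate[finite], e2.patterns_surrogate[finite]
        )

    def test_surrogate_pattern_set_roundtrip(self):
        pset = random_pattern_set(n=5)
        ens = make_surrogate_ensemble(pset, rng_seed=2)
        sset = surrogate_pattern_set(pset, ens)
        assert sset.n_patterns == pset.n_patterns
        assert sset.pixel_um_ds == pset.pixel_um_ds


class TestBuildPatternSet:
    def test_event_frames_to_patterns(self, modular_movie, modular_catalog):
        movie, info, roi, truth = modular_movie
        pset = build_pattern_set(
            modular_catalog.event_frames_raw, roi, 30.0, 195.0, ds_factor=4
        )
        assert pset.shape_ds == (24, 24)
        assert pset.pixel_um_ds == pytest.approx(88.0)
        inside = pset.patterns[:, pset.roi_ds]
        assert np.isfinite(inside).all()
        # band-pass removes the spatial mean
        assert np.abs(inside.mean(axis=1)).max() < 0.01 * np.abs(inside).max()
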