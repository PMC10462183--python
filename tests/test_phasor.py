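"""Phasor transform, calibration, segmentation, and bound-fraction mapping."""

import numpy as np
import pytest

from glycoscope.exceptions import InvalidInputError
from glycoscope.phasor import (
    CalibrationReference,
    DecayImage,
    PhasorImage,
    bound_fraction,
    calibrate,
    export_phasor_csv,
    mono_exponential_phasor,
    phasor_transform,
    segment_compartments,
)
from glycoscope.simulate import simulate_decay_image

REP_80MHZ_NS = 12.5  # 80 MHz repetition


def _decay_cube(bin_probs, total=10000):
    counts = np.round(total * np.asarray(bin_probs)).astype(int)
    return counts[:, None, None] * np.ones((1, 1), dtype=int)


class TestPhasorTransform:
    def test_delta_at_time_zero_approaches_unit_phasor(self):
        n_bins = 4096
        counts = np.zeros((n_bins, 1, 1), dtype=int)
        counts[0, 0, 0] = 10000
        decay = DecayImage(counts, bin_width_ns=REP_80MHZ_NS / n_bins,
                           rep_period_ns=REP_80MHZ_NS)
        img = phasor_transform(decay)
        assert img.g[0, 0] == pytest.approx(1.0, abs=1e-5)
        assert img.s[0, 0] == pytest.approx(0.0, abs=1e-2)

    def test_uniform_decay_is_origin(self):
        n_bins = 64
        counts = np.full((n_bins, 2, 2), 100, dtype=int)
        decay = DecayImage(counts, bin_width_ns=REP_80MHZ_NS / n_bins,
                           rep_period_ns=REP_80MHZ_NS)
        img = phasor_transform(decay)
        np.testing.assert_allclose(img.g, 0.0, atol=1e-12)
        np.testing.assert_allclose(img.s, 0.0, atol=1e-12)

    def test_mono_exponential_matches_closed_form(self):
        """Finely binned tau = 2.5 ns decay lands on the semicircle point."""
        n_bins = 256
        tau = 2.5
        edges = np.linspace(0, REP_80MHZ_NS, n_bins + 1)
        probs = np.diff(-np.expm1(-edges / tau))
        counts = np.round(1e9 * probs / probs.sum()).astype(int)[:, None, None]
        decay = DecayImage(counts, bin_width_ns=REP_80MHZ_NS / n_bins,
                           rep_period_ns=REP_80MHZ_NS)
        img = phasor_transform(decay)
        g_th, s_th = mono_exponential_phasor(tau, img.omega)
        assert img.g[0, 0] == pytest.approx(g_th, abs=1e-3)
        assert img.s[0, 0] == pytest.approx(s_th, abs=1e-3)

    def test_zero_count_pixel_is_sentinel(self):
        counts = np.zeros((8, 1, 2), dtype=int)
        counts[0, 0, 0] = 5
        decay = DecayImage(counts, bin_width_ns=1.0, rep_period_ns=12.5)
        img = phasor_transform(decay)
        assert np.isfinite(img.g[0, 0])
        assert np.isnan(img.g[0, 1]) and np.isnan(img.s[0, 1])

    def test_phasor_linearity_of_mixtures(self):
        """Phasor of a decay sum is the intensity-weighted phasor combination."""
        n_bins = 512
        bw = REP_80MHZ_NS / n_bins
        edges = np.linspace(0, REP_80MHZ_NS, n_bins + 1)

        def probs(tau):
            p = np.diff(-np.expm1(-edges / tau))
            return p / p.sum()

        i1, i2 = 3e8, 7e8
        c1 = np.round(i1 * probs(0.4)).astype(int)
        c2 = np.round(i2 * probs(3.4)).astype(int)

        def pix(counts):
            return phasor_transform(
                DecayImage(counts[:, None, None], bin_width_ns=bw,
                           rep_period_ns=REP_80MHZ_NS))

        pm = pix(c1 + c2)
        p1, p2 = pix(c1), pix(c2)
        n1, n2 = p1.intensity[0, 0], p2.intensity[0, 0]
        w1 = n1 / (n1 + n2)
        assert pm.g[0, 0] == pytest.approx(w1 * p1.g[0, 0] + (1 - w1) * p2.g[0, 0], abs=1e-10)
        assert pm.s[0, 0] == pytest.approx(w1 * p1.s[0, 0] + (1 - w1) * p2.s[0, 0], abs=1e-10)

    def test_random_exponential_mixtures_stay_inside_semicircle(self, rng):
        """Mixtures of exponential decays never leave the universal semicircle."""
        n_bins = 512
        edges = np.linspace(0, REP_80MHZ_NS, n_bins + 1)
        cubes = []
        for _ in range(16):
            taus = rng.uniform(0.05, 20.0, size=3)
            weights = rng.dirichlet(np.ones(3))
            probs = sum(
                w * np.diff(-np.expm1(-edges / tau)) / -np.expm1(-REP_80MHZ_NS / tau)
                for w, tau in zip(weights, taus)
            )
            cubes.append(np.round(1e7 * probs).astype(int))
        counts = np.array(cubes).T.reshape(n_bins, 4, 4)
        decay = DecayImage(counts, bin_width_ns=REP_80MHZ_NS / n_bins,
                           rep_period_ns=REP_80MHZ_NS)
        img = phasor_transform(decay)
        radius2 = (img.g - 0.5) ** 2 + img.s**2
        assert np.all(radius2 <= 0.25 + 1e-6)


class TestMonoExponentialPhasor:
    def test_zero_lifetime_is_unit_phasor(self):
        assert mono_exponential_phasor(0.0, 0.5) == (1.0, 0.0)

    @pytest.mark.parametrize("tau", [0.1, 0.4, 2.5, 3.4, 10.0])
    def test_on_universal_semicircle(self, tau):
        g, s = mono_exponential_phasor(tau, 2 * np.pi / REP_80MHZ_NS)
        assert (g - 0.5) ** 2 + s**2 == pytest.approx(0.25, abs=1e-12)

    def test_long_lifetime_limit(self):
        g, s = mono_exponential_phasor(1e9, 0.5)
        assert g == pytest.approx(0.0, abs=1e-12)
        assert s == pytest.approx(0.0, abs=1e-6)

    def test_negative_lifetime_rejected(self):
        with pytest.raises(InvalidInputError):
            mono_exponential_phasor(-1.0, 0.5)


class TestCalibration:
    def _image(self, g, s, omega):
        arr = lambda v: np.full((2, 2), float(v))
        return PhasorImage(g=arr(g), s=arr(s), harmonic=1, omega=omega,
                           intensity=arr(100.0))

    def test_perfect_reference_is_identity(self):
        omega = 2 * np.pi / REP_80MHZ_NS
        g_th, s_th = mono_exponential_phasor(2.5, omega)
        ref = CalibrationReference(2.5, g_th, s_th)
        img = self._image(0.3, 0.4, omega)
        out = calibrate(img, ref)
        np.testing.assert_allclose(out.g, 0.3, atol=1e-12)
        np.testing.assert_allclose(out.s, 0.4, atol=1e-12)

    def test_reference_lands_on_its_own_theory_point(self):
        omega = 2 * np.pi / REP_80MHZ_NS
        ref = CalibrationReference(2.5, 0.21, 0.55)  # arbitrary measured phasor
        out = calibrate(self._image(0.21, 0.55, omega), ref)
        g_th, s_th = mono_exponential_phasor(2.5, omega)
        np.testing.assert_allclose(out.g, g_th, atol=1e-12)
        np.testing.assert_allclose(out.s, s_th, atol=1e-12)

    def test_distorted_instrument_round_trip(self):
        """Simulated IRF time shift is undone by Coumarin-style calibration."""
        shift_ns = 0.8
        n_bins = 512
        tau_ref, tau_sample = 2.5, 1.0
        ref_decay = simulate_decay_image(
            np.zeros((1, 1)), tau_ref, 3.4, 1e7, REP_80MHZ_NS, n_bins,
            instrument_shift_ns=shift_ns, seed=1)
        sample_decay = simulate_decay_image(
            np.zeros((1, 1)), tau_sample, 3.4, 1e7, REP_80MHZ_NS, n_bins,
            instrument_shift_ns=shift_ns, seed=2)
        ref_img = phasor_transform(ref_decay)
        ref = CalibrationReference(tau_ref, float(ref_img.g[0, 0]), float(ref_img.s[0, 0]))
        out = calibrate(phasor_transform(sample_decay), ref)
        g_th, s_th = mono_exponential_phasor(tau_sample, out.omega)
        assert out.g[0, 0] == pytest.approx(g_th, abs=1e-3)
        assert out.s[0, 0] == pytest.approx(s_th, abs=1e-3)

    def test_zero_modulation_reference_rejected(self):
        with pytest.raises(InvalidInputError):
            CalibrationReference(2.5, 0.0, 0.0)


class TestSegmentation:
    def test_uniform_image_gives_empty_masks(self):
        with pytest.warns(UserWarning):
            masks = segment_compartments(np.full((32, 32), 7.0))
        assert not masks["mitochondrial"].any()
        assert not masks["cytosolic"].any()

    def test_blobs_on_gradient_phantom(self):
        rows, cols = 96, 96
        yy, xx = np.mgrid[0:rows, 0:cols]
        cell = 200.0 + 0.5 * xx  # smooth diffuse cytosolic signal
        blob_mask = np.zeros((rows, cols), dtype=bool)
        rng = np.random.default_rng(3)
        for _ in range(12):
            cy, cx = rng.integers(10, rows - 10), rng.integers(10, cols - 10)
            blob_mask |= (yy - cy) ** 2 + (xx - cx) ** 2 < 9
        img = cell + 600.0 * blob_mask
        masks = segment_compartments(img, background_sigma=16.0, cell_threshold=10.0)
        mito = masks["mitochondrial"]
        assert mito[blob_mask].mean() >= 0.95
        assert mito[~blob_mask].mean() < 0.05

    def test_masks_disjoint_and_within_cell(self):
        rng = np.random.default_rng(5)
        img = rng.uniform(0, 100, size=(48, 48))
        img[10:30, 10:30] += 300
        masks = segment_compartments(img)
        assert not (masks["mitochondrial"] & masks["cytosolic"]).any()


class TestBoundFraction:
    def _image(self, pts, omega=0.5):
        pts = np.asarray(pts, dtype=float)
        g = pts[:, 0][None, :]
        s = pts[:, 1][None, :]
        return PhasorImage(g=g, s=s, harmonic=1, omega=omega,
                           intensity=np.ones_like(g))

    def test_endpoints_and_midpoint(self):
        free, bound = (0.8, 0.35), (0.25, 0.4)
        mid = (0.5 * (free[0] + bound[0]), 0.5 * (free[1] + bound[1]))
        img = self._image([free, bound, mid])
        fb = bound_fraction(img, free, bound).fb
        np.testing.assert_allclose(fb[0], [0.0, 1.0, 0.5], atol=1e-12)

    def test_off_chord_point_projects_orthogonally(self):
        free, bound = (0.0, 0.0), (1.0, 0.0)
        img = self._image([(0.25, 0.7)])  # off the chord
        fb = bound_fraction(img, free, bound).fb
        assert fb[0, 0] == pytest.approx(0.25, abs=1e-12)

    def test_clipped_to_unit_interval(self):
        free, bound = (0.0, 0.0), (1.0, 0.0)
        img = self._image([(-0.4, 0.0), (1.7, 0.0)])
        fb = bound_fraction(img, free, bound).fb
        np.testing.assert_allclose(fb[0], [0.0, 1.0])

    def test_coincident_references_rejected(self):
        img = self._image([(0.5, 0.3)])
        with pytest.raises(InvalidInputError):
            bound_fraction(img, (0.4, 0.4), (0.4, 0.4))


class TestExport:
    def test_mask_means_and_counts(self, tmp_path):
        g = np.array([[0.2, 0.6], [0.4, 0.8]])
        s = np.zeros_like(g)
        img = PhasorImage(g=g, s=s, harmonic=1, omega=0.5, intensity=np.ones_like(g))
        fbmap = bound_fraction(img, (0.0, 0.0), (1.0, 0.0))
        masks = {
            "left": np.array([[True, False], [True, False]]),
            "empty": np.zeros((2, 2), dtype=bool),
        }
        out = tmp_path / "summary.csv"
        df = export_phasor_csv(img, fbmap, masks, out)
        assert out.exists()
        left = df.set_index("mask").loc["left"]
        assert left["mean_fb"] == pytest.approx(0.3)
        assert left["n_pixels"] == 2
        empty = df.set_index("mask").loc["empty"]
        assert empty["n_pixels"] == 0
        assert np.isnan(empty["mean_fb"])

    def test_shape_mismatch_rejected(self, tmp_path):
        img = PhasorImage(g=np.zeros((2, 2)), s=np.zeros((2, 2)), harmonic=1,
                          omega=0.5, intensity=np.ones((2, 2)))
        fbmap = bound_fraction(img, (0.0, 0.0), (1.0, 0.0))
        with pytest.raises(InvalidInputError):
            export_phasor_csv(img, fbmap, {"bad": np.ones((3, 3), bool)}, tmp_path / "x.csv")


class TestFBRecovery:
    def test_two_component_image_recovers_true_fb(self):
        """Mean |FB_fit - FB_true| < 0.02 at >= 1e4 photons/pixel, calibrated."""
        rng = np.random.default_rng(42)
        shape = (24, 24)
        fb_true = rng.uniform(0, 1, size=shape)
        tau_free, tau_bound = 0.4, 3.4
        n_bins = 256
        shift = 0.5
        decay = simulate_decay_image(fb_true, tau_free, tau_bound, 2e4,
                                     REP_80MHZ_NS, n_bins,
                                     instrument_shift_ns=shift, seed=7)
        ref_decay = simulate_decay_image(np.zeros((1, 1)), 2.5, tau_bound, 1e7,
                                         REP_80MHZ_NS, n_bins,
                                         instrument_shift_ns=shift, seed=8)
        ref_img = phasor_transform(ref_decay)
        ref = CalibrationReference(2.5, float(ref_img.g[0, 0]), float(ref_img.s[0, 0]))
        img = calibrate(phasor_transform(decay), ref)
        free = mono_exponential_phasor(tau_free, img.omega)
        bound = mono_exponential_phasor(tau_bound, img.omega)
        fb = bound_fraction(img, free, bound).fb
        assert np.mean(np.abs(fb - fb_true)) < 0.02
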