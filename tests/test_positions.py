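"""Continuum removal and edge-parameter extraction."""

import numpy as np
import pytest
from scipy.integrate import simpson

from lncspec import (SimConfig, Spectrum, absorption_features, continuum_line,
                     edge_parameters, position_features, reflection_features,
                     simulate_spectrum)
from lncspec.positions import SpectralRegion, feature_names
from lncspec.spectra import SpectrumSet, apply_mask, first_derivative

from conftest import make_flat_spectrum


def _toy_region(kind):
    return SpectralRegion("toy", kind, 0.0, 10.0, 1)


def _vee(peak_value, endpoint_value):
    """Piecewise-linear spectrum on [0,10] with an extremum at 5."""
    wl = np.arange(0.0, 11.0)
    r = np.interp(wl, [0.0, 5.0, 10.0], [endpoint_value, peak_value, endpoint_value])
    return Spectrum(wl, r, "toy")


class TestContinuumLine:
    def test_flat_spectrum_chord_is_flat(self, flat_spectrum):
        reg = SpectralRegion("A1", "absorption", 560, 760, 1)
        cl = continuum_line(flat_spectrum, reg)
        assert np.allclose(cl.values, 0.4)

    def test_chord_is_linear_between_endpoints(self):
        wl = np.arange(560.0, 761.0)
        r = 0.2 + (wl - 560) / 200.0 * 0.2 + 0.05 * np.sin(wl / 10)
        r[0], r[-1] = 0.2, 0.4
        s = Spectrum(wl, r, "x")
        cl = continuum_line(s, SpectralRegion("A1", "absorption", 560, 760, 1))
        mid = np.searchsorted(cl.wavelengths, 660)
        assert cl.values[mid] == pytest.approx(0.3)
        assert cl.values[0] == pytest.approx(r[0])
        assert cl.values[-1] == pytest.approx(r[-1])

    def test_region_outside_grid_errors(self, flat_spectrum):
        with pytest.raises(ValueError):
            continuum_line(flat_spectrum, SpectralRegion("x", "absorption", 3000, 3200, 1))


class TestAbsorptionReflection:
    def test_flat_spectrum_gives_zero_features(self, flat_spectrum):
        reg = SpectralRegion("A1", "absorption", 560, 760, 1)
        assert absorption_features(flat_spectrum, reg) == (0.0, 0.0, 0.0)
        reg = SpectralRegion("R1", "reflection", 500, 670, 1)
        assert reflection_features(flat_spectrum, reg) == (0.0, 0.0, 0.0)

    def test_triangle_dip_hand_values(self):
        # V-shaped dip to 0.3 from endpoints 0.5: depth 1-0.3/0.5, area = the
        # closed-form triangle area, normalized depth = depth/area
        d, a, nd = absorption_features(_vee(0.3, 0.5), _toy_region("absorption"))
        assert d == pytest.approx(0.4)
        assert a == pytest.approx(1.0)
        assert nd == pytest.approx(0.4)

    def test_triangle_peak_hand_values(self):
        d, a, nd = reflection_features(_vee(0.5, 0.3), _toy_region("reflection"))
        assert d == pytest.approx(0.4)
        assert a == pytest.approx(1.0)
        assert nd == pytest.approx(0.4)

    def test_scaling_invariance_of_depth(self):
        s = _vee(0.3, 0.5)
        scaled = Spectrum(s.wavelengths, 3.0 * s.reflectance, "scaled")
        d1, a1, _ = absorption_features(s, _toy_region("absorption"))
        d2, a2, _ = absorption_features(scaled, _toy_region("absorption"))
        assert d2 == pytest.approx(d1)          # depth is a ratio: scale-free
        assert a2 == pytest.approx(3.0 * a1)    # area scales with reflectance

    def test_peak_below_chord_gives_negative_depth(self):
        wl = np.arange(0.0, 11.0)
        r = np.interp(wl, [0, 5, 10], [0.5, 0.3, 0.5])  # sags below its chord
        d, a, _ = reflection_features(Spectrum(wl, r, "sag"),
                                      _toy_region("reflection"))
        assert d <= 0 and a < 0

    def test_trapezoid_area_matches_oversampled_simpson(self):
        # smooth synthetic well, 1 nm trapezoid vs 0.1 nm Simpson within 1%
        wl = np.arange(560.0, 761.0)
        r = 0.4 - 0.25 * np.exp(-0.5 * ((wl - 660) / 30) ** 2)
        s = Spectrum(wl, r, "smooth")
        reg = SpectralRegion("A1", "absorption", 560, 760, 1)
        _, area, _ = absorption_features(s, reg)
        fine = np.arange(560.0, 760.01, 0.1)
        rf = 0.4 - 0.25 * np.exp(-0.5 * ((fine - 660) / 30) ** 2)
        chord = np.interp(fine, [560, 760], [r[0], r[-1]])
        oracle = simpson(chord - rf, x=fine)
        assert area == pytest.approx(oracle, rel=0.01)


class TestEdgeParameters:
    def test_linear_ramp_constant_derivative(self):
        wl = np.arange(400.0, 801.0)
        c = 5e-4
        s = Spectrum(wl, 0.05 + c * (wl - 400), "ramp")
        sset = SpectrumSet(wl, s.reflectance[None, :], ["ramp"])
        fd = first_derivative(sset)
        out = edge_parameters(s, Spectrum(fd.wavelengths, fd.matrix[0], "ramp"))
        assert out["Db"] == pytest.approx(c)
        assert out["Dy"] == pytest.approx(c)
        assert out["Dr"] == pytest.approx(c)
        # the FD grid holds midpoints 490.5..529.5, so the 40 retained samples
        # of the blue-edge window span 39 nm
        assert out["SDb"] == pytest.approx(c * 39, rel=1e-6)

    def test_sigmoid_red_edge_position(self):
        wl = np.arange(400.0, 901.0)
        r = 0.05 + 0.45 / (1.0 + np.exp(-(wl - 715.0) / 12.0))
        sset = SpectrumSet(wl, r[None, :], ["sig"])
        fd = first_derivative(sset)
        out = edge_parameters(Spectrum(wl, r, "sig"),
                              Spectrum(fd.wavelengths, fd.matrix[0], "sig"))
        assert abs(out["lambda_r"] - 715.0) <= 1.0

    def test_argmax_tie_takes_lowest_wavelength(self):
        wl = np.arange(480.0, 801.0)
        fd_vals = np.zeros(wl.size)  # all ties
        out = edge_parameters(Spectrum(wl, np.full(wl.size, 0.2), "t"),
                              Spectrum(wl, fd_vals, "t"))
        assert out["lambda_b"] == 490.0
        assert out["lambda_g"] == 510.0

    def test_empty_window_errors(self):
        wl = np.arange(800.0, 901.0)
        s = Spectrum(wl, np.full(wl.size, 0.3), "x")
        with pytest.raises(ValueError):
            edge_parameters(s, s)


class TestFeatureVector:
    def test_forty_named_features_in_canonical_order(self, default_dataset):
        names = feature_names()
        assert len(names) == 40
        masked = apply_mask(default_dataset.spectra)
        fd = first_derivative(masked)
        feats = position_features(next(iter(masked)),
                                  Spectrum(fd.wavelengths, fd.matrix[0], "s"))
        assert list(feats) == names

    def test_wavelength_features_inside_their_windows(self, default_dataset):
        masked = apply_mask(default_dataset.spectra)
        fd = first_derivative(masked)
        for i, s in enumerate(masked):
            feats = position_features(s, Spectrum(fd.wavelengths, fd.matrix[i], "s"))
            assert 490 <= feats["lambda_b"] <= 530
            assert 560 <= feats["lambda_y"] <= 640
            assert 680 <= feats["lambda_r"] <= 760
            assert 510 <= feats["lambda_g"] <= 560
            assert 650 <= feats["lambda_o"] <= 690

    def test_per_sample_computation_no_cross_sample_leakage(self, default_dataset):
        from lncspec.positions import position_feature_table
        masked = apply_mask(default_dataset.spectra)
        fd = first_derivative(masked)
        full = position_feature_table(masked, fd)
        sub_ids = masked.sample_ids[:5]
        sub = position_feature_table(masked.subset(sub_ids), fd.subset(sub_ids))
        assert np.allclose(full.loc[sub_ids].to_numpy(), sub.to_numpy())
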