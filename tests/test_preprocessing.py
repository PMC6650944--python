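"""Reading, smoothing, derivatives and water-vapour masking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lncspec import (Spectrum, SpectrumSet, WavelengthMask, apply_mask,
                     first_derivative, read_spectra, sg_smooth)


def _set_from(wl, rows, ids=None):
    rows = np.atleast_2d(rows)
    ids = ids or [f"s{i}" for i in range(rows.shape[0])]
    return SpectrumSet(wl, rows, ids)


class TestReadSpectra:
    def test_toy_roundtrip_shapes(self, toy_csv):
        sset, lnc = read_spectra(*toy_csv)
        assert sset.matrix.shape == (3, 501)
        assert list(lnc.index) == ["a", "b", "c"]
        assert np.allclose(sset.wavelengths, np.arange(400, 901))

    def test_unmatched_sample_dropped(self, toy_csv, tmp_path):
        spath, _ = toy_csv
        lpath = tmp_path / "lnc2.csv"
        pd.DataFrame({"sample_id": ["a", "c"], "lnc": [1.2, 2.5]}).to_csv(
            lpath, index=False)
        sset, lnc = read_spectra(spath, lpath)
        assert sset.sample_ids == ["a", "c"] and len(lnc) == 2

    def test_descending_wavelengths_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        pd.DataFrame({"wavelength": [700, 600, 500], "x": [0.1, 0.2, 0.3]}).to_csv(
            p, index=False)
        lp = tmp_path / "l.csv"
        pd.DataFrame({"sample_id": ["x"], "lnc": [1.0]}).to_csv(lp, index=False)
        with pytest.raises(ValueError, match="increasing"):
            read_spectra(p, lp)

    def test_percent_scale_autodetected(self, tmp_path):
        p = tmp_path / "pct.csv"
        pd.DataFrame({"wavelength": np.arange(400, 500),
                      "x": np.full(100, 35.0)}).to_csv(p, index=False)
        lp = tmp_path / "l.csv"
        pd.DataFrame({"sample_id": ["x"], "lnc": [1.0]}).to_csv(lp, index=False)
        sset, _ = read_spectra(p, lp)
        assert np.allclose(sset.matrix, 0.35)


class TestSavitzkyGolay:
    def test_defaults(self):
        import inspect
        sig = inspect.signature(sg_smooth)
        assert sig.parameters["window"].default == 17
        assert sig.parameters["polyorder"].default == 2

    @pytest.mark.parametrize("coef", [(0.3, 0, 0), (0.1, 2e-4, 0), (0.05, 1e-4, 3e-7)])
    def test_polynomials_reproduced_everywhere(self, coef):
        # SG with polyorder 2 is exact on polynomials of degree <= 2,
        # including the ends thanks to truncated-window edge refits
        wl = np.arange(500.0, 700.0)
        a, b, c = coef
        x = wl - wl[0]
        r = a + b * x + c * x**2
        out = sg_smooth(_set_from(wl, r))
        assert np.allclose(out.matrix[0], r, atol=1e-10)

    def test_window_validation(self):
        wl = np.arange(400.0, 420.0)
        s = _set_from(wl, np.full(wl.size, 0.3))
        with pytest.raises(ValueError):
            sg_smooth(s, window=16)
        with pytest.raises(ValueError):
            sg_smooth(s, window=21)  # window >= grid length

    def test_noise_is_attenuated(self):
        rng = np.random.default_rng(0)
        wl = np.arange(400.0, 900.0)
        clean = 0.3 + 0.1 * np.sin(wl / 50)
        noisy = clean + rng.normal(0, 0.01, wl.size)
        out = sg_smooth(_set_from(wl, noisy)).matrix[0]
        assert np.std(out - clean) < 0.5 * np.std(noisy - clean)


class TestFirstDerivative:
    def test_forward_difference_at_midpoint(self):
        s = _set_from(np.array([700.0, 701.0]), np.array([0.2, 0.3]))
        fd = first_derivative(s)
        assert fd.wavelengths[0] == pytest.approx(700.5)
        assert fd.matrix[0, 0] == pytest.approx(0.1)

    def test_linear_and_constant(self):
        wl = np.arange(400.0, 500.0)
        lin = first_derivative(_set_from(wl, 0.1 + 2e-3 * wl))
        assert np.allclose(lin.matrix, 2e-3)
        const = first_derivative(_set_from(wl, np.full(wl.size, 0.4)))
        assert np.allclose(const.matrix, 0.0)
        assert lin.matrix.shape[1] == wl.size - 1

    def test_too_short_grid(self):
        with pytest.raises(ValueError):
            first_derivative(_set_from(np.array([500.0]), np.array([0.2])))

    def test_integral_roundtrip_recovers_slope(self):
        # trapezoid integral of FD recovers a linear spectrum's rise exactly
        wl = np.arange(600.0, 700.0)
        slope = 4e-4
        fd = first_derivative(_set_from(wl, 0.05 + slope * wl))
        assert np.allclose(fd.matrix[0], slope)
        rise = np.trapezoid(fd.matrix[0], fd.wavelengths)
        assert rise == pytest.approx(slope * (fd.wavelengths[-1] - fd.wavelengths[0]))

    def test_gap_pairs_dropped(self):
        wl = np.array([500.0, 501.0, 502.0, 600.0, 601.0])
        fd = first_derivative(_set_from(wl, np.array([0.1, 0.2, 0.3, 0.4, 0.5])))
        assert 551.0 not in fd.wavelengths  # no difference across the gap
        assert fd.matrix.shape[1] == 3


class TestMask:
    def test_default_mask_retains_1680_columns(self):
        wl = np.arange(350.0, 2501.0)
        s = _set_from(wl, np.full(wl.size, 0.3))
        out = apply_mask(s)
        assert out.matrix.shape[1] == 954 + 363 + 363 == 1680

    def test_single_point_interval(self):
        wl = np.arange(350.0, 2501.0)
        s = _set_from(wl, np.full(wl.size, 0.3))
        out = apply_mask(s, WavelengthMask(((400.0, 400.0),)))
        assert out.wavelengths.tolist() == [400.0]

    def test_disjoint_mask_errors(self):
        wl = np.arange(500.0, 600.0)
        s = _set_from(wl, np.full(wl.size, 0.3))
        with pytest.raises(ValueError):
            apply_mask(s, WavelengthMask(((3000.0, 3100.0),)))

    def test_invalid_intervals_rejected(self):
        with pytest.raises(ValueError):
            WavelengthMask(((500.0, 400.0),))
        with pytest.raises(ValueError):
            WavelengthMask(((400.0, 600.0), (500.0, 700.0)))

    @given(st.lists(st.tuples(st.integers(350, 2400), st.integers(0, 80)),
                    min_size=1, max_size=4))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_membership_matches_bruteforce(self, raw):
        intervals = sorted((lo, lo + width) for lo, width in raw)
        merged = []
        for lo, hi in intervals:  # make disjoint
            if merged and lo <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(hi, merged[-1][1]))
            else:
                merged.append((lo, hi))
        mask = WavelengthMask(tuple((float(a), float(b)) for a, b in merged))
        wl = np.arange(350.0, 2501.0, 7.0)
        s = _set_from(wl, np.linspace(0.1, 0.5, wl.size))
        expected = [w for w in wl if any(a <= w <= b for a, b in merged)]
        if not expected:
            with pytest.raises(ValueError):
                apply_mask(s, mask)
        else:
            out = apply_mask(s, mask)
            assert out.wavelengths.tolist() == expected
            assert np.all(np.diff(out.wavelengths) > 0)
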