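"""Spectral containers and preprocessing.

Canopy reflectance spectra live on a shared nanometre wavelength grid.
This module reads the CSV interchange format, resamples everything onto a
common 1 nm grid, applies Savitzky-Golay smoothing, computes first-derivative
spectra, and masks the atmospheric water-vapour windows that field
spectroradiometer data cannot be trusted in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

logger = logging.getLogger(__name__)

#: Wavelength windows (nm, closed intervals) kept after removing the
#: atmospheric water-vapour absorption bands around 1400 and 1900 nm.
DEFAULT_KEPT_WINDOWS: tuple[tuple[float, float], ...] = (
    (400.0, 1353.0),
    (1437.0, 1799.0),
    (1992.0, 2354.0),
)


@dataclass(frozen=True)
class Spectrum:
    """A single reflectance spectrum.

    Parameters
    ----------
    wavelengths : ndarray
        Strictly increasing wavelength grid in nm.
    reflectance : ndarray
        Reflectance as a unitless fraction, one value per wavelength.
    sample_id : str
        Opaque sample label.
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    sample_id: str = ""

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        rf = np.asarray(self.reflectance, dtype=float)
        if wl.shape != rf.shape or wl.ndim != 1:
            raise ValueError("wavelengths and reflectance must be 1-D and equal length")
        if len(wl) >= 2 and not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(rf)):
            raise ValueError("reflectance must be finite")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "reflectance", rf)

    def value_at(self, wavelength: float) -> float:
        """Reflectance at the grid point nearest *wavelength*."""
        i = int(np.argmin(np.abs(self.wavelengths - wavelength)))
        return float(self.reflectance[i])


class SpectrumSet:
    """A collection of spectra on one shared wavelength grid.

    Stored as a samples x wavelengths matrix; rows are addressable by
    sample id.
    """

    def __init__(self, wavelengths, matrix, sample_ids):
        self.wavelengths = np.asarray(wavelengths, dtype=float)
        self.matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
        self.sample_ids = list(map(str, sample_ids))
        if self.matrix.shape != (len(self.sample_ids), len(self.wavelengths)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.wavelengths)} wavelengths"
            )
        if len(self.wavelengths) >= 2 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("reflectance matrix must be finite")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    def __len__(self) -> int:
        return self.n_samples

    def __iter__(self):
        for i, sid in enumerate(self.sample_ids):
            yield Spectrum(self.wavelengths, self.matrix[i], sid)

    def spectrum(self, sample_id: str) -> Spectrum:
        i = self.sample_ids.index(str(sample_id))
        return Spectrum(self.wavelengths, self.matrix[i], sample_id)

    def subset(self, sample_ids) -> "SpectrumSet":
        idx = [self.sample_ids.index(str(s)) for s in sample_ids]
        return SpectrumSet(self.wavelengths, self.matrix[idx], [self.sample_ids[i] for i in idx])

    def to_frame(self) -> pd.DataFrame:
        """Wavelength-by-sample frame in the CSV interchange layout."""
        return pd.DataFrame(self.matrix.T, index=pd.Index(self.wavelengths, name="wavelength"),
                            columns=self.sample_ids)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


@dataclass(frozen=True)
class WavelengthMask:
    """Closed wavelength intervals (nm) to keep; everything else is dropped."""

    kept_intervals: tuple = DEFAULT_KEPT_WINDOWS

    def __post_init__(self):
        ivs = tuple((float(lo), float(hi)) for lo, hi in self.kept_intervals)
        if any(lo > hi for lo, hi in ivs):
            raise ValueError("interval lo must be <= hi")
        if sorted(ivs) != list(ivs):
            raise ValueError("intervals must be sorted")
        for (_, hi), (lo2, _) in zip(ivs, ivs[1:]):
            if lo2 <= hi:
                raise ValueError("intervals must be disjoint")
        object.__setattr__(self, "kept_intervals", ivs)

    def contains(self, wavelengths) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=float)
        keep = np.zeros(wl.shape, dtype=bool)
        for lo, hi in self.kept_intervals:
            keep |= (wl >= lo) & (wl <= hi)
        return keep


def _resample_1nm(wavelengths, values):
    """Linear interpolation onto an integer 1 nm grid spanning the input."""
    lo = int(np.ceil(wavelengths[0]))
    hi = int(np.floor(wavelengths[-1]))
    grid = np.arange(lo, hi + 1, dtype=float)
    return grid, np.interp(grid, wavelengths, values)


def read_spectra(path, lnc_path) -> tuple[SpectrumSet, pd.Series]:
    """Read and align a spectra CSV and an LNC CSV.

    The spectra file has a ``wavelength`` column followed by one column per
    sample; the LNC file has columns ``sample_id,lnc`` (LNC in % dry mass).
    Spectra are linearly resampled onto a common 1 nm grid.  Samples present
    in only one of the files are logged and dropped.  Reflectance given in
    percent (values above 1.5) is auto-detected and divided by 100.
    """
    spec_df = pd.read_csv(path)
    lnc_df = pd.read_csv(lnc_path)
    if spec_df.shape[1] < 2:
        raise ValueError("spectra CSV needs a wavelength column and at least one sample")
    wl = spec_df.iloc[:, 0].to_numpy(dtype=float)
    if len(wl) < 2 or not np.all(np.diff(wl) > 0):
        raise ValueError("wavelength column must be strictly increasing")

    mat = spec_df.iloc[:, 1:].to_numpy(dtype=float).T  # samples x wavelengths
    ids = [str(c) for c in spec_df.columns[1:]]
    if np.nanmax(mat) > 1.5:
        logger.warning("reflectance looks like percent (max %.3g); dividing by 100",
                       np.nanmax(mat))
        mat = mat / 100.0
    out_of_range = (mat < -0.05) | (mat > 1.5)
    if out_of_range.any():
        logger.warning("clamping %d reflectance values outside [-0.05, 1.5]",
                       int(out_of_range.sum()))
        mat = np.clip(mat, -0.05, 1.5)

    grid, _ = _resample_1nm(wl, mat[0])
    mat = np.vstack([_resample_1nm(wl, row)[1] for row in mat])

    lnc = lnc_df.set_index(lnc_df.columns[0])[lnc_df.columns[1]].astype(float)
    lnc.index = lnc.index.map(str)
    common = [s for s in ids if s in lnc.index]
    dropped = sorted(set(ids).symmetric_difference(lnc.index))
    if dropped:
        logger.warning("dropping samples present in only one file: %s", dropped)
    if not common:
        raise ValueError("no sample ids shared between spectra and LNC files")
    keep_idx = [ids.index(s) for s in common]
    sset = SpectrumSet(grid, mat[keep_idx], common)
    return sset, lnc.loc[common].rename("lnc")


def sg_smooth(s: SpectrumSet, window: int = 17, polyorder: int = 2) -> SpectrumSet:
    """Savitzky-Golay smooth each spectrum.

    Interior points use the standard centred filter; at each end the local
    polynomial is refit on the truncated one-sided window (no padding), so
    edge deviations stay confined to ``window // 2`` points per end.
    """
    window = int(window)
    polyorder = int(polyorder)
    if window % 2 != 1:
        raise ValueError("window must be odd")
    if window <= polyorder:
        raise ValueError("window must exceed polyorder")
    n = len(s.wavelengths)
    if window >= n:
        raise ValueError(f"window {window} must be smaller than grid length {n}")

    half = window // 2
    out = savgol_filter(s.matrix, window, polyorder, axis=1, mode="interp")
    x = s.wavelengths
    for i in list(range(half)) + list(range(n - half, n)):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        xi = x[lo:hi] - x[i]  # centre for conditioning
        deg = min(polyorder, len(xi) - 1)
        coef = np.polynomial.polynomial.polyfit(xi, s.matrix[:, lo:hi].T, deg)
        out[:, i] = coef[0]
    return SpectrumSet(s.wavelengths, out, s.sample_ids)


def first_derivative(s: SpectrumSet, max_gap: float | None = None) -> SpectrumSet:
    """First-derivative spectra by forward difference.

    FD(i) = (R(j+1) - R(j)) / (lambda(j+1) - lambda(j)), in nm^-1, assigned
    to the midpoint wavelength between bands j and j+1; the output grid has
    one point fewer.  On a masked (gappy) grid, pairs straddling a gap wider
    than *max_gap* (default 1.5x the median step) are dropped rather than
    differenced across the gap.
    """
    wl = s.wavelengths
    if len(wl) < 2:
        raise ValueError("need at least 2 wavelengths for a derivative")
    dw = np.diff(wl)
    if max_gap is None:
        max_gap = 1.5 * float(np.median(dw))
    keep = dw <= max_gap
    if not keep.any():
        raise ValueError("no adjacent wavelength pairs within max_gap")
    fd = np.diff(s.matrix, axis=1) / dw
    mid = (wl[:-1] + wl[1:]) / 2.0
    return SpectrumSet(mid[keep], fd[:, keep], s.sample_ids)


def apply_mask(s: SpectrumSet, mask: WavelengthMask | None = None) -> SpectrumSet:
    """Drop wavelengths outside the mask's kept intervals (order preserved)."""
    if mask is None:
        mask = WavelengthMask()
    keep = mask.contains(s.wavelengths)
    if not keep.any():
        raise ValueError("mask is disjoint from the wavelength grid")
    return SpectrumSet(s.wavelengths[keep], s.matrix[:, keep], s.sample_ids)
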