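"""Spectral position features: continuum removal and edge parameters.

Forty features per spectrum:

* depth / area / normalized depth for 3 absorption regions (560-760,
  920-1080, 1120-1280 nm) and 6 reflection regions (500-670, 780-970,
  980-1200, 1200-1350, 1480-1720, 2000-2300 nm), computed against the
  straight continuum chord joining the spectrum's values at the region
  endpoints;
* 13 edge/peak parameters from the first-derivative and reflectance curves
  (blue, yellow and red edges; green peak; red well).

Depth is defined on the continuum-removed ratio R/Rc: an absorption's
lambda_min minimizes R/Rc and depth = 1 - R(lmin)/Rc(lmin); a reflection's
lambda_max maximizes R/Rc and depth = 1 - Rc(lmax)/R(lmax).  Areas are
trapezoid integrals of the chord-spectrum gap over the region (nm units);
normalized depth = depth / area (nm^-1).  Ties in argmin/argmax break to the
smallest wavelength so outputs are deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra import Spectrum, SpectrumSet

logger = logging.getLogger(__name__)

ABSORPTION_REGIONS: tuple[tuple[float, float], ...] = (
    (560.0, 760.0),
    (920.0, 1080.0),
    (1120.0, 1280.0),
)
REFLECTION_REGIONS: tuple[tuple[float, float], ...] = (
    (500.0, 670.0),
    (780.0, 970.0),
    (980.0, 1200.0),
    (1200.0, 1350.0),
    (1480.0, 1720.0),
    (2000.0, 2300.0),
)

# Table-2 style edge/peak windows (nm)
BLUE_EDGE = (490.0, 530.0)
YELLOW_EDGE = (560.0, 640.0)
RED_EDGE = (680.0, 760.0)
GREEN_PEAK = (510.0, 560.0)
RED_WELL = (650.0, 690.0)

EDGE_PARAM_NAMES = ["Db", "lambda_b", "Dy", "lambda_y", "Dr", "lambda_r",
                    "Rg", "lambda_g", "Ro", "lambda_o", "SDb", "SDy", "SDr"]


def feature_names() -> list[str]:
    """Canonical order of the 40 position-feature names."""
    names = []
    for i in range(1, 4):
        names += [f"A_Depth_{i}", f"A_Area_{i}", f"A_ND_{i}"]
    for i in range(1, 7):
        names += [f"R_Depth_{i}", f"R_Area_{i}", f"R_ND_{i}"]
    return names + list(EDGE_PARAM_NAMES)


@dataclass(frozen=True)
class SpectralRegion:
    """A named absorption or reflection interval [lo, hi] nm."""

    name: str
    kind: str  # "absorption" | "reflection"
    lo: float
    hi: float
    index: int

    def __post_init__(self):
        if self.kind not in ("absorption", "reflection"):
            raise ValueError(f"unknown region kind {self.kind!r}")
        if not self.lo < self.hi:
            raise ValueError("region lo must be < hi")


def default_regions() -> list[SpectralRegion]:
    regs = [SpectralRegion(f"A{i}", "absorption", lo, hi, i)
            for i, (lo, hi) in enumerate(ABSORPTION_REGIONS, 1)]
    regs += [SpectralRegion(f"R{i}", "reflection", lo, hi, i)
             for i, (lo, hi) in enumerate(REFLECTION_REGIONS, 1)]
    return regs


@dataclass(frozen=True)
class ContinuumLine:
    """The straight chord joining a spectrum's values at a region's endpoints."""

    region: SpectralRegion
    wavelengths: np.ndarray
    values: np.ndarray


def _region_slice(s: Spectrum, region: SpectralRegion):
    wl = s.wavelengths
    inside = (wl >= region.lo) & (wl <= region.hi)
    if inside.sum() < 3:
        raise ValueError(
            f"region {region.name} [{region.lo}, {region.hi}] overlaps the grid "
            f"by {int(inside.sum())} points; need at least 3")
    span = region.hi - region.lo
    got = wl[inside][-1] - wl[inside][0]
    if got < 0.9 * span:
        logger.warning("region %s truncated to [%g, %g] (>10%% of span lost)",
                       region.name, wl[inside][0], wl[inside][-1])
    return wl[inside], s.reflectance[inside]


def continuum_line(s: Spectrum, region: SpectralRegion) -> ContinuumLine:
    """Chord between (lo, R(lo)) and (hi, R(hi)) on the in-region grid."""
    wl, r = _region_slice(s, region)
    chord = np.interp(wl, [wl[0], wl[-1]], [r[0], r[-1]])
    return ContinuumLine(region, wl, chord)


def absorption_features(s: Spectrum, region: SpectralRegion):
    """(A_Depth, A_Area, A_ND) for an absorption region."""
    if region.kind != "absorption":
        raise ValueError("absorption_features requires an absorption region")
    wl, r = _region_slice(s, region)
    chord = continuum_line(s, region).values
    if np.any(chord <= 0):
        raise ValueError(f"continuum line non-positive in region {region.name}")
    ratio = r / chord
    imin = int(np.argmin(ratio))  # argmin returns first (lowest-wavelength) tie
    depth = 1.0 - ratio[imin]
    area = float(np.trapezoid(chord - r, wl))
    nd = _normalized_depth(depth, area, region)
    return float(depth), area, nd


def reflection_features(s: Spectrum, region: SpectralRegion):
    """(R_Depth, R_Area, R_ND) for a reflection region."""
    if region.kind != "reflection":
        raise ValueError("reflection_features requires a reflection region")
    wl, r = _region_slice(s, region)
    chord = continuum_line(s, region).values
    if np.any(r <= 0):
        raise ValueError(f"reflectance non-positive in region {region.name}")
    ratio = r / np.where(chord == 0, np.finfo(float).tiny, chord)
    imax = int(np.argmax(ratio))
    depth = 1.0 - chord[imax] / r[imax]
    if depth < 0:
        logger.info("region %s: spectrum below its chord (degenerate reflection)",
                    region.name)
    area = float(np.trapezoid(r - chord, wl))
    nd = _normalized_depth(depth, area, region)
    return float(depth), area, nd


def _normalized_depth(depth, area, region):
    if area == 0.0:
        if depth == 0.0:
            logger.info("region %s: zero area and depth; ND defined as 0", region.name)
            return 0.0
        raise ValueError(f"region {region.name}: zero area with nonzero depth")
    return float(depth / area)


def _window(s: Spectrum, lo, hi):
    m = (s.wavelengths >= lo) & (s.wavelengths <= hi)
    if not m.any():
        raise ValueError(f"window [{lo}, {hi}] empty on this grid")
    return s.wavelengths[m], s.reflectance[m]


def edge_parameters(s_raw: Spectrum, s_fd: Spectrum,
                    sdr_window: tuple[float, float] = RED_EDGE) -> dict[str, float]:
    """The 13 edge/peak parameters.

    Db/Dy/Dr are the first-derivative maxima over the blue, yellow and red
    edges with their wavelengths lambda_b/y/r; Rg (lambda_g) is the green-peak
    reflectance maximum and Ro (lambda_o) the red-well minimum; SDb/SDy/SDr
    are trapezoid integrals of the first derivative over the blue edge,
    yellow edge and *sdr_window* (red edge by default; pass ``RED_WELL`` to
    integrate over 650-690 nm instead).
    """
    out: dict[str, float] = {}
    for d_name, l_name, win in (("Db", "lambda_b", BLUE_EDGE),
                                ("Dy", "lambda_y", YELLOW_EDGE),
                                ("Dr", "lambda_r", RED_EDGE)):
        wl, fd = _window(s_fd, *win)
        i = int(np.argmax(fd))
        out[d_name], out[l_name] = float(fd[i]), float(wl[i])
    wl, r = _window(s_raw, *GREEN_PEAK)
    i = int(np.argmax(r))
    out["Rg"], out["lambda_g"] = float(r[i]), float(wl[i])
    wl, r = _window(s_raw, *RED_WELL)
    i = int(np.argmin(r))
    out["Ro"], out["lambda_o"] = float(r[i]), float(wl[i])
    for name, win in (("SDb", BLUE_EDGE), ("SDy", YELLOW_EDGE), ("SDr", sdr_window)):
        wl, fd = _window(s_fd, *win)
        out[name] = float(np.trapezoid(fd, wl))
    return out


def position_features(s_raw: Spectrum, s_fd: Spectrum,
                      sdr_window: tuple[float, float] = RED_EDGE) -> dict[str, float]:
    """All 40 position features for one spectrum, in canonical order."""
    out: dict[str, float] = {}
    for region in default_regions():
        if region.kind == "absorption":
            d, a, nd = absorption_features(s_raw, region)
            out[f"A_Depth_{region.index}"] = d
            out[f"A_Area_{region.index}"] = a
            out[f"A_ND_{region.index}"] = nd
        else:
            d, a, nd = reflection_features(s_raw, region)
            out[f"R_Depth_{region.index}"] = d
            out[f"R_Area_{region.index}"] = a
            out[f"R_ND_{region.index}"] = nd
    out.update(edge_parameters(s_raw, s_fd, sdr_window=sdr_window))
    return {name: out[name] for name in feature_names()}


def position_feature_table(raw: SpectrumSet, fd: SpectrumSet,
                           sdr_window: tuple[float, float] = RED_EDGE) -> pd.DataFrame:
    """Samples x 40 position-feature table (per-sample computation)."""
    rows = [position_features(s_raw, s_fd, sdr_window=sdr_window)
            for s_raw, s_fd in zip(raw, fd)]
    return pd.DataFrame(rows, index=pd.Index(raw.sample_ids, name="sample_id"))
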