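"""Vegetation index registry: 34 canopy indices computed from a spectrum.

Narrowband reflectances R_lambda are looked up at the nearest point of the
1 nm grid; broadband reflectances (blue, green, red, red-edge, NIR) are
unweighted means over configurable wavelength intervals standing in for
sensor spectral response functions.

Three registry rows are degenerate as printed in the source table (GNDVI
written with the red band, a red-edge NDVI whose numerator and denominator
are identical, and an MTCI that reduces to the constant -1).  The default
mode evaluates the standard literature forms of those three; passing
``paper_literal=True`` evaluates the printed forms verbatim.  All other
rows are evaluated exactly as printed.

Zero denominators yield NaN for that sample (logged), never an exception.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .spectra import Spectrum, SpectrumSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BroadbandConfig:
    """Wavelength intervals (nm) of the broadband surrogates."""

    B: tuple[float, float] = (450.0, 520.0)
    G: tuple[float, float] = (520.0, 600.0)
    R: tuple[float, float] = (630.0, 690.0)
    RedEdge: tuple[float, float] = (705.0, 745.0)
    NIR: tuple[float, float] = (760.0, 900.0)


def narrowband(s: Spectrum, wavelength: float, tol: float = 1.0) -> float:
    """Reflectance at the grid point nearest *wavelength*.

    Raises if no grid point lies within *tol* nm (i.e. the wavelength falls
    in a masked window or outside the grid).
    """
    i = int(np.argmin(np.abs(s.wavelengths - wavelength)))
    if abs(s.wavelengths[i] - wavelength) > tol:
        raise ValueError(f"wavelength {wavelength} nm not on the (masked) grid")
    return float(s.reflectance[i])


def broadband(s: Spectrum, band: str, cfg: BroadbandConfig | None = None) -> float:
    """Unweighted mean reflectance over the configured band interval."""
    cfg = cfg or BroadbandConfig()
    try:
        lo, hi = getattr(cfg, band)
    except AttributeError:
        raise ValueError(f"unknown band {band!r}") from None
    m = (s.wavelengths >= lo) & (s.wavelengths <= hi)
    if not m.any():
        raise ValueError(f"band {band} [{lo}, {hi}] has no overlap with the grid")
    return float(np.mean(s.reflectance[m]))


class _Bands:
    """Reflectance accessor passed to index formulas."""

    def __init__(self, s: Spectrum, cfg: BroadbandConfig):
        self._s = s
        self._cfg = cfg

    def nb(self, wavelength: float) -> np.float64:
        return np.float64(narrowband(self._s, wavelength))

    def bb(self, band: str) -> np.float64:
        return np.float64(broadband(self._s, band, self._cfg))


# helper sub-formulas used by the combined index (narrowband forms, as printed)
def mcari(b: _Bands):
    return (b.nb(700) - b.nb(670) - 0.2 * (b.nb(700) - b.nb(550))) * (b.nb(700) / b.nb(670))


def mtvi2_narrowband(b: _Bands):
    return (1.5 * (1.2 * (b.nb(800) - b.nb(550)))
            / np.sqrt((2 * b.nb(800) + 1) ** 2 - (6 * b.nb(800) - 5 * np.sqrt(b.nb(670))) - 0.5))


@dataclass(frozen=True)
class VIDefinition:
    """One registry row: name, printed formula text, and evaluators."""

    name: str
    formula: str
    func: Callable[[_Bands], float]
    form: str = "other"  # "nd" | "ratio" | "other" (constant-spectrum symmetry class)
    literal_func: Callable[[_Bands], float] | None = None
    literal_formula: str | None = None

    @property
    def has_literal_variant(self) -> bool:
        return self.literal_func is not None


def _registry() -> list[VIDefinition]:
    d = VIDefinition
    return [
        d("Vi_opt", "(1 + 0.45)((R_800)^2 + 1)/(R_670 + 0.45)",
          lambda b: (1 + 0.45) * (b.nb(800) ** 2 + 1) / (b.nb(670) + 0.45)),
        d("NDVI_g-b#", "(R_573 - R_440)/(R_573 + R_440)",
          lambda b: (b.nb(573) - b.nb(440)) / (b.nb(573) + b.nb(440)), form="nd"),
        d("RVI I#", "R_810/R_660", lambda b: b.nb(810) / b.nb(660), form="ratio"),
        d("RVI II#", "R_810/R_560", lambda b: b.nb(810) / b.nb(560), form="ratio"),
        d("MCARI/MTVI2", "MCARI/MTVI2 (narrowband 550/670/700/800 forms)",
          lambda b: mcari(b) / mtvi2_narrowband(b)),
        d("DCNI#", "(R_720 - R_700)/(R_700 - R_670)/(R_720 - R_670 + 0.03)",
          lambda b: (b.nb(720) - b.nb(700)) / (b.nb(700) - b.nb(670)) / (b.nb(720) - b.nb(670) + 0.03)),
        d("NDVI I", "(R_800 - R_670)/(R_800 + R_670)",
          lambda b: (b.nb(800) - b.nb(670)) / (b.nb(800) + b.nb(670)), form="nd"),
        d("RVI III", "R_800/R_670", lambda b: b.nb(800) / b.nb(670), form="ratio"),
        d("DVI I", "R_800 - R_670", lambda b: b.nb(800) - b.nb(670)),
        d("SAVI I", "1.5(R_800 - R_670)/(R_800 + R_670 + 0.5)",
          lambda b: 1.5 * (b.nb(800) - b.nb(670)) / (b.nb(800) + b.nb(670) + 0.5)),
        d("NDRE", "(R_790 - R_720)/(R_790 + R_720)",
          lambda b: (b.nb(790) - b.nb(720)) / (b.nb(790) + b.nb(720)), form="nd"),
        d("ARVI", "(R_NIR - RB)/(R_NIR + RB), RB = R_R - (R_B - R_R)",
          lambda b: ((b.bb("NIR") - (b.bb("R") - (b.bb("B") - b.bb("R"))))
                     / (b.bb("NIR") + (b.bb("R") - (b.bb("B") - b.bb("R"))))), form="nd"),
        d("DVI II", "R_NIR - R_R", lambda b: b.bb("NIR") - b.bb("R")),
        d("EVI", "2.5(R_NIR - R_R)/(R_NIR + 6R_R - 7.5R_B + 1)",
          lambda b: 2.5 * (b.bb("NIR") - b.bb("R")) / (b.bb("NIR") + 6 * b.bb("R") - 7.5 * b.bb("B") + 1)),
        d("GNDVI", "(R_NIR - R_G)/(R_NIR + R_G)",
          lambda b: (b.bb("NIR") - b.bb("G")) / (b.bb("NIR") + b.bb("G")), form="nd",
          literal_func=lambda b: (b.bb("NIR") - b.bb("R")) / (b.bb("NIR") + b.bb("R")),
          literal_formula="(R_NIR - R_R)/(R_NIR + R_R)"),
        d("MNLI", "1.5(R_NIR^2 - R_R)/(R_NIR^2 + R_R + 0.5)",
          lambda b: 1.5 * (b.bb("NIR") ** 2 - b.bb("R")) / (b.bb("NIR") ** 2 + b.bb("R") + 0.5)),
        d("MSAVI2", "(2R_NIR + 1 - sqrt((2R_NIR + 1)^2 - 8(R_NIR - R_R)))/2",
          lambda b: (2 * b.bb("NIR") + 1
                     - np.sqrt((2 * b.bb("NIR") + 1) ** 2 - 8 * (b.bb("NIR") - b.bb("R")))) / 2),
        d("MSR", "(R_NIR/R_R - 1)/(R_NIR/R_R + 1)",
          lambda b: (b.bb("NIR") / b.bb("R") - 1) / (b.bb("NIR") / b.bb("R") + 1), form="nd"),
        d("NDVI II", "(R_NIR - R_R)/(R_NIR + R_R)",
          lambda b: (b.bb("NIR") - b.bb("R")) / (b.bb("NIR") + b.bb("R")), form="nd"),
        d("NLI", "(R_NIR^2 - R_R)/(R_NIR^2 + R_R)",
          lambda b: (b.bb("NIR") ** 2 - b.bb("R")) / (b.bb("NIR") ** 2 + b.bb("R"))),
        d("OSAVI", "(1 + 0.16)(R_NIR - R_R)/(R_NIR + R_R + 0.16)",
          lambda b: 1.16 * (b.bb("NIR") - b.bb("R")) / (b.bb("NIR") + b.bb("R") + 0.16)),
        d("RDVI", "(R_NIR - R_R)/sqrt(R_NIR + R_R)",
          lambda b: (b.bb("NIR") - b.bb("R")) / np.sqrt(b.bb("NIR") + b.bb("R"))),
        d("RVI IV", "R_NIR/R_R", lambda b: b.bb("NIR") / b.bb("R"), form="ratio"),
        d("SAVI II", "1.5(R_NIR - R_R)/(R_NIR + R_R + 0.5)",
          lambda b: 1.5 * (b.bb("NIR") - b.bb("R")) / (b.bb("NIR") + b.bb("R") + 0.5)),
        d("TVI", "60(R_NIR - R_G) - 100(R_R - R_G)",
          lambda b: 60 * (b.bb("NIR") - b.bb("G")) - 100 * (b.bb("R") - b.bb("G"))),
        d("MTVI2", "1.5(1.2(R_NIR - R_G) - 2.5(R_R - R_G))/sqrt((2R_NIR + 1)^2 - (6R_NIR - 5sqrt(R_R)) - 0.5)",
          lambda b: (1.5 * (1.2 * (b.bb("NIR") - b.bb("G")) - 2.5 * (b.bb("R") - b.bb("G")))
                     / np.sqrt((2 * b.bb("NIR") + 1) ** 2
                               - (6 * b.bb("NIR") - 5 * np.sqrt(b.bb("R"))) - 0.5))),
        d("NDVI_Red-edge", "(R_NIR - R_Red-edge)/(R_NIR + R_Red-edge)",
          lambda b: (b.bb("NIR") - b.bb("RedEdge")) / (b.bb("NIR") + b.bb("RedEdge")), form="nd",
          literal_func=lambda b: (b.bb("NIR") - b.bb("RedEdge")) / (b.bb("NIR") - b.bb("RedEdge")),
          literal_formula="(R_NIR - R_Red-edge)/(R_NIR - R_Red-edge)"),
        d("CI_Red-edge", "R_NIR/R_Red-edge - 1", lambda b: b.bb("NIR") / b.bb("RedEdge") - 1),
        d("MTCI", "(R_NIR - R_Red-edge)/(R_Red-edge - R_R)",
          lambda b: (b.bb("NIR") - b.bb("RedEdge")) / (b.bb("RedEdge") - b.bb("R")),
          literal_func=lambda b: (b.bb("NIR") - b.bb("RedEdge")) / (b.bb("RedEdge") - b.bb("NIR")),
          literal_formula="(R_NIR - R_Red-edge)/(R_Red-edge - R_NIR)"),
        d("WI", "R_900/R_970", lambda b: b.nb(900) / b.nb(970), form="ratio"),
        d("NDWI", "(R_860 - R_1240)/(R_860 + R_1240)",
          lambda b: (b.nb(860) - b.nb(1240)) / (b.nb(860) + b.nb(1240)), form="nd"),
        d("NDII", "(R_819 - R_1600)/(R_819 + R_1600)",
          lambda b: (b.nb(819) - b.nb(1600)) / (b.nb(819) + b.nb(1600)), form="nd"),
        d("DSWI", "(R_803 - R_549)/(R_1659 + R_681)",
          lambda b: (b.nb(803) - b.nb(549)) / (b.nb(1659) + b.nb(681))),
        d("sLAIDI*", "s(R_1050 - R_1250)/((R_1050 + R_1250) R_1555), s = 1",
          lambda b: 1.0 * (b.nb(1050) - b.nb(1250)) / ((b.nb(1050) + b.nb(1250)) * b.nb(1555))),
    ]


REGISTRY: tuple[VIDefinition, ...] = tuple(_registry())
INDEX_NAMES: tuple[str, ...] = tuple(d.name for d in REGISTRY)


def audit_registry() -> None:
    """Assert registry integrity: exactly 34 uniquely-named definitions."""
    if len(REGISTRY) != 34:
        raise RuntimeError(f"registry holds {len(REGISTRY)} definitions, expected 34")
    if len(set(INDEX_NAMES)) != 34:
        raise RuntimeError("duplicate index names in registry")


audit_registry()


def get_definition(name: str) -> VIDefinition:
    for d in REGISTRY:
        if d.name == name:
            return d
    raise KeyError(name)


def compute_index(s: Spectrum, definition: VIDefinition | str,
                  cfg: BroadbandConfig | None = None,
                  paper_literal: bool = False) -> float:
    """Evaluate one index on one spectrum; NaN (logged) on zero denominators."""
    if isinstance(definition, str):
        definition = get_definition(definition)
    func = definition.func
    if paper_literal and definition.literal_func is not None:
        func = definition.literal_func
    bands = _Bands(s, cfg or BroadbandConfig())
    with np.errstate(divide="ignore", invalid="ignore"):
        value = float(func(bands))
    if not np.isfinite(value):
        logger.warning("index %s undefined for sample %r (zero denominator?)",
                       definition.name, s.sample_id)
        return float("nan")
    return value


def compute_all(s: SpectrumSet, cfg: BroadbandConfig | None = None,
                paper_literal: bool = False) -> pd.DataFrame:
    """Samples x 34 index table in registry (source-table) order."""
    audit_registry()
    rows = [{d.name: compute_index(spec, d, cfg, paper_literal) for d in REGISTRY}
            for spec in s]
    return pd.DataFrame(rows, index=pd.Index(s.sample_ids, name="sample_id"),
                        columns=list(INDEX_NAMES))


def registry_manifest(paper_literal: bool = False) -> list[dict]:
    """JSON-serializable dump of the registry (name, formula, mode)."""
    out = []
    for d in REGISTRY:
        literal = paper_literal and d.has_literal_variant
        out.append({
            "name": d.name,
            "formula": d.literal_formula if literal else d.formula,
            "mode": "paper-literal" if literal else "default",
        })
    return out
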