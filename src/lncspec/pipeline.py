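"""End-to-end LNC estimation: preprocessing, feature families, SPA, models.

The entry point is :class:`LNCModel`, built from a spectrum set and an LNC
table (or a synthetic dataset).  ``fit()`` runs the whole workflow --
Savitzky-Golay smoothing, water-vapour masking, first derivatives, the four
feature families (reflectance bands, FD bands, 40 position features, 34
vegetation indices), SPA screening per family on the calibration split
only, PLS and RF fits, and a final SPA rescreen of the pooled per-family
selections (the "integrated" set) -- and returns an :class:`LNCResults`
holding the metric tables, selections and predictions.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import indices, positions
from .indices import BroadbandConfig
from .modeling import ModelSpec, fit_and_report
from .simulate import SimConfig, SyntheticDataset, make_dataset
from .spa import SelectionResult, spa_select
from .spectra import (SpectrumSet, WavelengthMask, apply_mask, first_derivative,
                      read_spectra, sg_smooth)

logger = logging.getLogger(__name__)

FAMILIES = ("bands", "fd", "positions", "vis")


@dataclass(frozen=True)
class RunConfig:
    """Workflow settings: split rule, screening depth and feature options."""

    seed: int = 0
    validation_fraction: float = 1.0 / 3.0
    cal_ids: tuple[str, ...] | None = None   # explicit split overrides the rule
    val_ids: tuple[str, ...] | None = None
    k_max: int | None = None                 # None: min(10, p, n_cal - 2)
    sg_window: int = 17
    sg_polyorder: int = 2
    mask: WavelengthMask = field(default_factory=WavelengthMask)
    broadband: BroadbandConfig = field(default_factory=BroadbandConfig)
    paper_literal: bool = False
    sdr_window: tuple[float, float] = positions.RED_EDGE
    rf_seed: int = 20120731

    def __post_init__(self):
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in (0, 1)")
        if (self.cal_ids is None) != (self.val_ids is None):
            raise ValueError("give both cal_ids and val_ids or neither")


def compute_feature_families(spectra: SpectrumSet, cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """Smoothed+masked reflectance, FD, position and VI tables (per sample)."""
    smoothed = sg_smooth(spectra, cfg.sg_window, cfg.sg_polyorder)
    masked = apply_mask(smoothed, cfg.mask)
    fd = first_derivative(masked)
    idx = pd.Index(masked.sample_ids, name="sample_id")
    bands = pd.DataFrame(masked.matrix, index=idx,
                         columns=[f"R_{w:g}" for w in masked.wavelengths])
    fd_tab = pd.DataFrame(fd.matrix, index=idx,
                          columns=[f"FD_{w:g}" for w in fd.wavelengths])
    pos = positions.position_feature_table(masked, fd, sdr_window=cfg.sdr_window)
    vis = indices.compute_all(masked, cfg.broadband, paper_literal=cfg.paper_literal)
    return {"bands": bands, "fd": fd_tab, "positions": pos, "vis": vis}


def variable_wavelength(name: str) -> float | None:
    """Wavelength (nm) encoded in a band/FD variable name, else None."""
    for prefix in ("R_", "FD_"):
        if name.startswith(prefix):
            try:
                return float(name[len(prefix):])
            except ValueError:
                return None
    return None


def _screen_and_model(family: str, table: pd.DataFrame, lnc: pd.Series,
                      cal_ids, val_ids, cfg: RunConfig):
    """SPA on calibration rows only, then PLS/RF fit + dual evaluation."""
    complete = table.dropna(axis=0, how="any")
    dropped = sorted(set(table.index) - set(complete.index))
    if dropped:
        logger.warning("family %s: dropping %d samples with missing features: %s",
                       family, len(dropped), dropped)
    cal = [s for s in cal_ids if s in complete.index]
    val = [s for s in val_ids if s in complete.index]
    if table.shape[1] < 2:
        raise ValueError(f"family {family} has fewer than 2 usable features")
    sel = spa_select(complete.loc[cal], lnc.loc[cal], k_max=cfg.k_max)
    X_cal = complete.loc[cal, sel.selected]
    X_val = complete.loc[val, sel.selected]
    reports, fitted, preds = fit_and_report(
        family, X_cal, lnc.loc[cal], X_val, lnc.loc[val],
        rf_spec=ModelSpec(kind="RF", seed=cfg.rf_seed))
    return sel, reports, fitted, preds, (cal, val)


class LNCModel:
    """Leaf-nitrogen-content estimation model over canopy spectra.

    Parameters
    ----------
    spectra : SpectrumSet
        Raw reflectance spectra on a common nm grid.
    lnc : pandas.Series
        LNC (% dry mass) indexed by sample id, aligned with *spectra*.
    config : RunConfig, optional
        Workflow settings (split, screening depth, feature options).
    """

    def __init__(self, spectra: SpectrumSet, lnc: pd.Series,
                 config: RunConfig | None = None):
        self.spectra = spectra
        self.lnc = pd.Series(lnc, dtype=float).loc[list(map(str, spectra.sample_ids))]
        self.config = config or RunConfig()
        self._source: dict = {"kind": "data"}

    @classmethod
    def from_csv(cls, spectra_path, lnc_path, config: RunConfig | None = None):
        spectra, lnc = read_spectra(spectra_path, lnc_path)
        model = cls(spectra, lnc, config)
        model._source = {"kind": "csv", "spectra_path": str(spectra_path),
                         "lnc_path": str(lnc_path)}
        return model

    @classmethod
    def from_simulation(cls, sim_config: SimConfig | None = None,
                        seed: int | None = None, config: RunConfig | None = None):
        ds = make_dataset(sim_config, seed=seed)
        config = config or RunConfig(seed=ds.config.seed)
        config = dataclasses.replace(config, cal_ids=tuple(ds.cal_ids),
                                     val_ids=tuple(ds.val_ids))
        model = cls(ds.spectra, ds.lnc, config)
        model._source = {"kind": "simulation",
                         "sim_config": dataclasses.asdict(ds.config)}
        model.dataset = ds
        return model

    @classmethod
    def from_manifest(cls, manifest: dict | str | Path):
        """Rebuild a simulation-sourced model from a run manifest."""
        if not isinstance(manifest, dict):
            manifest = json.loads(Path(manifest).read_text())
        src = manifest["source"]
        if src["kind"] == "simulation":
            sim_cfg = dict(src["sim_config"])
            sim_cfg["lnc_range"] = tuple(sim_cfg["lnc_range"])
            sim_cfg["grid"] = tuple(sim_cfg["grid"])
            model = cls.from_simulation(SimConfig(**sim_cfg))
        else:
            model = cls.from_csv(src["spectra_path"], src["lnc_path"])
        rc = manifest["run_config"]
        model.config = dataclasses.replace(
            model.config, seed=rc["seed"],
            cal_ids=tuple(rc["cal_ids"]), val_ids=tuple(rc["val_ids"]),
            k_max=rc["k_max"], paper_literal=rc["paper_literal"])
        return model

    # -- split ------------------------------------------------------------
    def split_ids(self) -> tuple[list[str], list[str]]:
        cfg = self.config
        ids = list(self.spectra.sample_ids)
        if cfg.cal_ids is not None:
            return [str(s) for s in cfg.cal_ids], [str(s) for s in cfg.val_ids]
        rng = np.random.default_rng(cfg.seed)
        n_val = int(round(len(ids) * cfg.validation_fraction))
        order = rng.permutation(len(ids))
        val = sorted(ids[i] for i in order[:n_val])
        cal = sorted(ids[i] for i in order[n_val:])
        return cal, val

    # -- fitting ----------------------------------------------------------
    def fit(self, families: tuple[str, ...] = FAMILIES,
            integrated: bool = True) -> "LNCResults":
        cal_ids, val_ids = self.split_ids()
        features = compute_feature_families(self.spectra, self.config)
        selections: dict[str, SelectionResult] = {}
        reports, fitted, pred_rows = [], {}, []
        for fam in families:
            sel, reps, fits, preds, (cal, val) = _screen_and_model(
                fam, features[fam], self.lnc, cal_ids, val_ids, self.config)
            selections[fam] = sel
            reports.extend(reps)
            fitted[fam] = fits
            pred_rows += self._prediction_rows(fam, preds, cal, val)
        if integrated:
            pooled_names = [v for fam in families for v in selections[fam].selected]
            pooled = pd.concat([features[fam][selections[fam].selected]
                                for fam in families], axis=1)
            if pooled.shape[1] < 2:
                raise ValueError("fewer than 2 pooled variables for integration")
            sel, reps, fits, preds, (cal, val) = _screen_and_model(
                "integrated", pooled, self.lnc, cal_ids, val_ids, self.config)
            selections["integrated"] = sel
            reports.extend(reps)
            fitted["integrated"] = fits
            pred_rows += self._prediction_rows("integrated", preds, cal, val)
            pooled_count = len(pooled_names)
        else:
            pooled_count = 0
        return LNCResults(model=self, selections=selections, reports=reports,
                          fitted=fitted,
                          predictions=pd.DataFrame(pred_rows),
                          cal_ids=cal_ids, val_ids=val_ids,
                          pooled_variable_count=pooled_count)

    def _prediction_rows(self, family, preds, cal, val):
        rows = []
        for algo, (yc, yv) in preds.items():
            for ids_, yhat, label in ((cal, yc, "calibration"), (val, yv, "validation")):
                for sid, v in zip(ids_, yhat):
                    rows.append({"family": family, "algorithm": algo, "set": label,
                                 "sample_id": sid, "measured": float(self.lnc[sid]),
                                 "predicted": float(v)})
        return rows


@dataclass
class LNCResults:
    """Fit results: metric tables, SPA selections, fitted learners."""

    model: LNCModel
    selections: dict[str, SelectionResult]
    reports: list
    fitted: dict
    predictions: pd.DataFrame
    cal_ids: list[str]
    val_ids: list[str]
    pooled_variable_count: int = 0

    @property
    def report_table(self) -> pd.DataFrame:
        rows = [row for rep in self.reports for row in rep.to_rows()]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable metric table mirroring the study's report layout."""
        tab = self.report_table.copy()
        tab["nrmse_pct"] = 100 * tab.pop("nrmse")
        lines = [f"LNC estimation summary (n_cal={len(self.cal_ids)}, "
                 f"n_val={len(self.val_ids)})", ""]
        lines.append(f"{'family':<12}{'algorithm':<10}{'set':<13}{'n':>4}"
                     f"{'R2':>8}{'RMSE':>8}{'NRMSE%':>9}")
        for _, r in tab.iterrows():
            lines.append(f"{r['family']:<12}{r['algorithm']:<10}{r['set']:<13}"
                         f"{r['n']:>4d}{r['r2']:>8.2f}{r['rmse']:>8.2f}"
                         f"{r['nrmse_pct']:>9.1f}")
        lines.append("")
        for fam, sel in self.selections.items():
            lines.append(f"selected[{fam}]: {', '.join(sel.selected)}")
        return "\n".join(lines)

    def manifest(self) -> dict:
        cfg = self.model.config
        return {
            "source": self.model._source,
            "run_config": {"seed": cfg.seed, "cal_ids": list(self.cal_ids),
                           "val_ids": list(self.val_ids), "k_max": cfg.k_max,
                           "paper_literal": cfg.paper_literal,
                           "sg_window": cfg.sg_window,
                           "sg_polyorder": cfg.sg_polyorder},
            "selections": {k: v.to_dict() for k, v in self.selections.items()},
            "pooled_variable_count": self.pooled_variable_count,
        }

    def write(self, outdir) -> dict[str, str]:
        """Write manifest JSON, the metrics CSV, selections JSON and the
        measured-vs-predicted scatter CSV.  NRMSE is re-checked against
        RMSE/mean(y) at write time."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tab = self.report_table
        for _, r in tab.iterrows():
            ids_ = self.cal_ids if r["set"] == "calibration" else self.val_ids
            ybar = float(self.model.lnc.loc[ids_].mean())
            assert abs(r["nrmse"] - r["rmse"] / ybar) < 1e-9, "NRMSE identity violated"
        paths = {}
        p = outdir / "manifest.json"
        p.write_text(json.dumps(self.manifest(), indent=2))
        paths["manifest"] = str(p)
        p = outdir / "reports.csv"
        tab.to_csv(p, index=False)
        paths["reports"] = str(p)
        p = outdir / "selections.json"
        p.write_text(json.dumps({k: v.to_dict() for k, v in self.selections.items()},
                                indent=2))
        paths["selections"] = str(p)
        p = outdir / "predictions.csv"
        self.predictions.to_csv(p, index=False)
        paths["predictions"] = str(p)
        return paths
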