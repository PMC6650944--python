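# lncspec

Estimation of corn **leaf nitrogen content (LNC, % dry mass)** from canopy
hyperspectral reflectance (350–2500 nm).

Nitrogen status drives chlorophyll concentration, which reshapes a canopy
spectrum in characteristic ways: the red absorption well around 670 nm
deepens, the steep "red edge" between 680 and 760 nm shifts to longer
wavelengths, and visible reflectance drops relative to the NIR plateau.
`lncspec` turns those physical signatures into a regression workflow for
agronomists and remote-sensing researchers who want to monitor crop
nitrogen non-destructively:

1. **Preprocessing** — Savitzky–Golay smoothing (window 17, order 2),
   first-derivative spectra `FD(i) = (R(λⱼ₊₁) − R(λⱼ)) / (λⱼ₊₁ − λⱼ)` on the
   midpoint grid, and masking of the atmospheric water-vapour windows
   (keeping 400–1353, 1437–1799 and 1992–2354 nm).
2. **Three families of spectral variables** — the masked reflectance and
   FD bands themselves; 40 *position features* (continuum-removal depth
   `1 − R(λ_min)/R_c(λ_min)`, area `∫(R_c − R) dλ` and normalized depth for
   3 absorption and 6 reflection regions, plus 13 edge/peak parameters such
   as the red-edge derivative maximum D_r and its wavelength λ_r); and 34
   vegetation indices (NDVI and SAVI variants, MCARI/MTVI2, DCNI, red-edge
   and water indices, …).
3. **Variable screening** — the successive projections algorithm (SPA):
   forward selection that appends, at each step, the variable with the
   largest norm after projection orthogonal to the span of the already
   selected ones, scored by leave-one-out RMSE of a multiple linear
   regression. Each family is screened separately; the pooled winners are
   screened once more into an *integrated* variable set.
4. **Modeling and evaluation** — partial least squares (PLS) and random
   forest (RF) regressions of LNC on each screened set, reported with
   R², RMSE and NRMSE = RMSE/ȳ on a 48-sample calibration and a 24-sample
   validation split.

A fully parameterized **synthetic-data generator** produces
nitrogen-parameterized canopy-like spectra (deepening chlorophyll wells,
shifting logistic red edge, NIR plateau, water-vapour wells, instrument
noise) so the entire workflow can be exercised and validated without field
data.

## Worked example

```python
from lncspec import LNCModel, SimConfig

model = LNCModel.from_simulation(SimConfig(seed=7))   # 72 samples, 48/24 split
results = model.fit()
print(results.summary())
```

```
LNC estimation summary (n_cal=48, n_val=24)

family      algorithm set             n      R2    RMSE   NRMSE%
bands       PLS       calibration    48    1.00    0.03      1.6
bands       PLS       validation     24    0.99    0.04      2.1
...
vis         PLS       validation     24    1.00    0.03      1.5
integrated  PLS       calibration    48    1.00    0.03      1.6
integrated  PLS       validation     24    0.99    0.04      2.1
integrated  RF        validation     24    0.99    0.05      2.7

selected[bands]: R_711
selected[fd]: FD_736.5
selected[positions]: Ro
selected[vis]: NDVI_Red-edge, GNDVI, NDII, WI, NDVI_g-b#, ...
selected[integrated]: R_711
```

Each row gives the coefficient of determination, root-mean-square error
(% dry mass) and normalized RMSE of one learner on one split.  The
`selected[...]` lines show the SPA screening results: on this synthetic
dataset the screened variables concentrate on the red edge (R at 711 nm,
FD at 736.5 nm, the red-well minimum Ro, red-edge indices) — exactly the
regions where nitrogen reshapes the spectrum.  Validation R² ≈ 0.99 at the
default noise level reflects the generator's clean monotone nitrogen
signal; real field spectra carry nuisances the generator does not emulate
(see `docs/methods.md`).

`results.write("outdir/")` emits the metrics CSV, selection JSON, a
measured-vs-predicted scatter CSV and a manifest that reproduces the run
bit-for-bit.  The same workflow runs from CSV inputs
(`LNCModel.from_csv("spectra.csv", "lnc.csv")`) and from the command line:

```bash
lncspec simulate --seed 7 --out synthetic/
lncspec run-all synthetic/spectra.csv synthetic/lnc.csv --out run/
lncspec run-all --simulate --seed 7 --out run/
```

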