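# Methods

This note documents the models, conventions and design choices behind
`lncspec`, in the spirit of a statistical package's methods appendix.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Signal model and preprocessing

Canopy reflectance is treated as a unitless fraction sampled on a strictly
increasing nanometre grid.  All inputs are linearly interpolated onto a
common 1 nm grid at read time (field spectroradiometers sample at ~1.4 nm
below 1000 nm), which makes band lookup exact and region integrals simple.
Values that look like percent (max > 1.5) are divided by 100; values
outside [−0.05, 1.5] are clamped with a warning.

**Savitzky–Golay smoothing** uses a 17-point window and a second-order
polynomial, the combination found adequate for canopy spectra of this kind.
Interior points use the standard centred filter.  At each end the local
polynomial is refit on the truncated one-sided window rather than padding
the data; deviations from the centred filter are therefore confined to 8
points per end, and the filter remains exact on polynomials of degree ≤ 2
everywhere (tested to 1e-10).

**First derivatives** are forward differences assigned to midpoint
wavelengths, so the FD grid has one point fewer and sits at half-integer
wavelengths.  On a masked (gappy) grid, no difference is taken across a
gap wider than 1.5× the median step.  A consequence of the midpoint
convention: a window such as the 490–530 nm blue edge retains 40 midpoint
samples spanning 39 nm, so the integral of a constant derivative c over it
is 39c, not 40c.  When a consumer asks for FD "at" a named wavelength, the
nearest midpoint is used.

**Water-vapour masking** keeps 400–1353, 1437–1799 and 1992–2354 nm
(closed intervals; 1680 columns on a 1 nm grid).  Smoothing runs before
masking so the filter never sees artificial edges at window borders; the
alternative order is defensible but would contaminate up to 8 points at
each border.

## Position features (continuum removal)

Three absorption regions (560–760, 920–1080, 1120–1280 nm) and six
reflection regions (500–670, 780–970, 980–1200, 1200–1350, 1480–1720,
2000–2300 nm) are each closed by a straight chord joining the spectrum's
values at the region endpoints (a per-region chord, not a global convex
hull).  The extremum wavelength is chosen by extremizing the
continuum-removed ratio R/R_c, not raw R, because depth is defined on the
continuum-removed scale: absorption depth = 1 − R(λ_min)/R_c(λ_min),
reflection depth = 1 − R_c(λ_max)/R(λ_max).  Areas are trapezoid integrals
of the chord–spectrum gap on the 1 nm grid (checked against a 10×
oversampled Simpson oracle to 1%); normalized depth = depth/area, defined
as 0 when both vanish (flat spectrum).  Ties in argmin/argmax go to the
smallest wavelength so outputs are deterministic.  A reflection region
whose spectrum sags below its chord yields a negative depth and is logged
as degenerate rather than rejected.

The 13 edge/peak parameters are the derivative maxima and their
wavelengths over the blue (490–530), yellow (560–640) and red (680–760)
edges, the green-peak reflectance maximum (510–560), the red-well
reflectance minimum (650–690), and the derivative integrals SDb, SDy, SDr.
SDr is integrated over the red edge 680–760 nm, consistent with SDb/SDy
over their edges; a config switch (`sdr_window`) integrates over the red
well 650–690 nm instead for users who read "red well" literally.  The full
vector is 9 absorption + 18 reflection + 13 edge values = 40 named
features in a fixed canonical order.

## Vegetation indices

The registry holds exactly 34 definitions in source-table order, evaluated
from nearest-gridpoint narrowband reflectances and broadband surrogates.
No sensor response functions are published for the broadbands, so they are
unweighted means over conventional intervals — B 450–520, G 520–600,
R 630–690, red edge 705–745, NIR 760–900 nm — and configurable.

Three printed rows are degenerate as published: GNDVI written with the red
band where the green band is expected, a red-edge NDVI whose numerator and
denominator are identical (≡ 1), and an MTCI that reduces to the constant
−1.  The default mode evaluates the standard literature forms; a
paper-literal mode evaluates the printed forms verbatim so both behaviours
stay auditable.  All other rows are evaluated exactly as printed, including
a DSWI with a minus in its numerator and a combined MCARI/MTVI2 whose
MTVI2 factor lacks the usual −2.5(R₆₇₀−R₅₅₀) term; DCNI's chained division
is read left-to-right, and sLAIDI* as s·(R₁₀₅₀−R₁₂₅₀)/((R₁₀₅₀+R₁₂₅₀)·R₁₅₅₅)
with s = 1.  Zero denominators produce NaN for that sample (logged), and
samples with missing features are dropped listwise from model fits.

## Successive projections algorithm

Columns are mean-centred and unit-variance scaled before projection —
the variable families mix units (nm, nm⁻¹, unitless) — and the scaling
record is retained.  Numerically constant columns (sd below 1e-10 relative
to the column magnitude) are dropped before screening: standardizing them
would amplify floating-point dust into spurious "variables".

A chain starts at a given column; each step projects every unselected
column onto the orthogonal complement of the selected span (maintained
incrementally against the newest residual direction) and appends the
column of maximal residual norm, ties to the lowest column index.  Chains
truncate when all residual norms fall below 1e-9 (rank deficiency).  For
wide matrices (p > 256) chains are computed in single precision — the
chain is selection bookkeeping, and halving the memory traffic roughly
halves the dominant cost — while all model evaluation stays in double
precision.  Chains from every start are built for subset sizes up to
k_max = min(10, p, n − 2) by default.

Each candidate subset is scored by the leave-one-out RMSE of an ordinary
least-squares fit (computed in closed form via the hat matrix); the
evaluator is pluggable.  The winning subset is **not** the raw RMSE
minimum: comparing raw minima across thousands of candidate subsets
systematically favours lucky noise variables.  Instead an F-test parsimony
rule in the tradition of SPA implementations is applied — among all
subsets whose RMSE is within the F(n, n) critical ratio (α = 0.25) of the
global minimum, the smallest subset wins, then the smallest RMSE, then the
lexicographically smallest start name.  Setting `parsimony_alpha=None`
restores the raw-minimum rule.  The algorithm is deterministic throughout.

## Regression models and metrics

**PLS** (scikit-learn, NIPALS) with the component count chosen by
leave-one-out CV minimizing RMSE, capped at min(p, n − 1, rank); with full
components on a full-rank matrix it coincides with OLS (tested to 1e-8).
Final coefficients are reported in the original feature space.  **RF**
uses 500 trees, max(1, p/3) variables per split, bootstrap sampling with
out-of-bag error tracking, and a fixed seed (20120731) recorded in the
model spec.

Metrics: RMSE = √(Σ(yᵢ − ŷᵢ)²/n); NRMSE = RMSE/ȳ (reported as percent in
summaries); R² is the standard coefficient of determination
1 − SS_res/SS_tot on measured-vs-predicted pairs — the printed source
formula for R² is not a valid determination coefficient and was replaced
deliberately by the conventional quantity its tables plainly report.
The NRMSE ≡ RMSE/ȳ identity is re-asserted whenever reports are written.

## Synthetic data generator

The generator is phenomenological, not radiative transfer; its job is to
give the pipeline a realistic-shaped signal with a known nitrogen link,
not to model canopy physics (a radiative-transfer hook such as PROSAIL
would slot in at `simulate_spectrum`).  The curve is

- a visible platform (0.12) with a Gaussian green peak at 550 nm,
- chlorophyll wells at 670 nm (σ = 14 nm) and 490 nm (σ = 12 nm) whose
  depths grow linearly with LNC (0.30 + 0.12·LNC and 0.22 + 0.018·LNC),
- a logistic red edge (scale 15 nm) whose inflection sits at
  700 + 8·LNC nm,
- an NIR plateau at 0.48 with a gentle SWIR decline and water-vapour
  wells at 970, 1200, 1450 and 1940 nm,
- i.i.d. Gaussian instrument noise (default sd 0.005 reflectance units,
  an ASD-like signal-to-noise regime), clipped to [0, 1].

The well-depth and red-edge gains sit in the range reported for corn
canopies across nitrogen treatments (red-well reflectance spanning roughly
0.07–0.11 and a red-edge displacement of ~16 nm over the 0.8–2.8 % LNC
range).  LNC is drawn from a truncated normal matching the field study's
pooled descriptive statistics (mean 1.88, SD 0.61, range 0.82–2.83, n = 72)
rather than resampling printed values, and the recorded 48/24
calibration/validation split is random by seed (no growth-stage
stratification — the field assignment rule is unknown).  Everything is
bit-for-bit reproducible from (config, seed).

Two nitrogen-independent nuisances are available but **off by default** so
that instrument noise is the only stochastic term: per-sample NIR-plateau
variation (`plateau_sd`, canopy structure) and a wavelength-flat
brightness factor (`brightness_sd`, illumination/background).  With them
off, passing recovery tests demonstrate the pipeline's mechanics — feature
extraction, screening and fitting recover a known monotone nitrogen signal
— but not robustness to the structural, atmospheric and background
variability of real field spectra, which is why validation R² here is far
higher than any field study should expect.

## Workflow conventions

The calibration/validation split is seeded 2:1 (48/24 at n = 72).  SPA
screening, PLS component choice and RF fitting see calibration rows only;
features are computed per sample, so no validation information can leak
into selection or fitting (asserted by a tamper test on validation rows).
Reflectance bands and FD bands are screened from their own matrices and
modeled separately; the integrated set pools each family's winners and is
screened once more.  Reports mirror the family × algorithm × split layout
with R², RMSE and NRMSE columns, and a run manifest reproduces reports
exactly.

Problem sizes in tests and the acceptance script (n = 72 samples, 20
generator seeds for the selection-frequency study, 50 random matrices for
the brute-force oracle) match the study conditions the package targets
while keeping a full run to a few minutes on one CPU.

## Known limitations

- The spectral model is a smooth one-parameter nitrogen family plus noise;
  it cannot exhibit the multi-factor confounding (water, LAI, soil,
  cultivar) of real canopies.
- Broadband reflectances are unweighted means, not sensor-response
  convolutions.
- The SPA evaluator's regression model, CV scheme and k_max are declared
  package defaults, not claims about any particular field study's
  settings.
- Only single-response regression is implemented (no multi-trait PLS, no
  classification forests, no uncertainty intervals).
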