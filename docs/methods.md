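# Methods

This note documents the models, the synthetic study conditions, the
numerical conventions, and the design choices behind `corespec`. Units are
mg C per g soil (mg g⁻¹) for SOC, nm for wavelengths, cm for depths.

## Coordinate and depth conventions

Row 0 of every raster is the soil surface; depth increases with row index.
The depth of a row centre is `depth_origin_cm + (row + 0.5) · pixel_size`.
All depth intervals (bulk slabs, profile windows, horizon split) are
half-open `[top, bottom)`. The topsoil/subsoil boundary defaults to the
plough depth (30 cm); in synthetic runs this is the generator's true
horizon boundary, with real data it is user-supplied (in the imaged study
system it was identified visually from the leading principal components).

## Synthetic core generator

The generator defines the study conditions under which the pipeline is
validated. One core is a 100 × 6 cm face rendered on a square pixel grid
(default 2 mm → 500 × 30; the emulated camera's native 53 µm resolution is
a configuration choice away and changes nothing but cost).

**SOC field.** The noise-free depth profile is a plough-horizon plateau
(9 mg g⁻¹ above 30 cm) followed by a linear decline to 2 mg g⁻¹ at 1 m.
Spatial variability is Gaussian-smoothed white noise (correlation length
2 mm — the scale of fine aggregates; the imaged system's variance is
described but not its correlation structure) rescaled to unit variance and
multiplied by a depth-dependent coefficient of variation ramping linearly
from 0.2 (plough) to 0.7 (1 m). The field is clipped to a 0.05 mg g⁻¹
floor so it stays strictly positive; at depth this truncation leaves a
realised matrix CV of ~0.55 with planted hotspots restoring window CVs to
~0.7. Consequently ~5 % of the deepest pixels sit at the floor —
essentially carbon-free mineral material, which matters for model
behaviour (below).

**Biopores.** Each planted biopore is a vertically elongated channel with
a cosine edge taper (plateau over the inner 70 % of its half-width,
rolloff to 1.3×), SOC equal to `enrichment × noise-free matrix mean` at
that depth. The default five-core set plants six subsoil biopores with
enrichments 2.2–4.5×, positioned so peak contents stay at or below
~16 mg g⁻¹, the highest ROI content measured in the imaged system; two of
them mirror the described examples at ~69–83 cm and ~53–64 cm. Overlapping
or out-of-extent biopores are rejected. Optional topsoil "speckles"
(roots/crop residues) are off by default since the source system describes
them only qualitatively.

**Forward spectral model.** True reflectance is
`r(λ) = baseline(λ) · exp(−k(λ) · SOC)` with a linear baseline rising from
0.15 (400 nm) to 0.55 (990 nm) and an absorption strength falling from
0.060 to 0.015 (g mg⁻¹) across the range: darkening is monotone in SOC,
stronger in the visible than the NIR, and nonlinear in SOC — so linear and
nonlinear regressors genuinely differ. Exact soil optics are out of scope;
only these qualitative properties are required. Recorded intensity is
`g(x)·a(px)·r(λ)·L(λ) + b(px) + ε` with a ±7.5 % linear horizontal
illumination gradient `g`, per-pixel multiplicative gain
`a ~ N(1, 0.10)`, additive offset `b ~ N(0, 0.02)`, halogen-like lamp
spectrum `L`, and band noise `ε ~ N(0, 0.005)`. The gain level is chosen
so scatter dominates the spectral signal of a ~1 mg g⁻¹ SOC difference
(making SNV matter, as observed in the imaged system); the offset is kept
a fraction of the dimmest band's signal. The target scan is
`g(x) · 0.5 · L(λ)` — scatter-free, so normalisation cancels `g` and `L`
exactly.

**Non-soil features.** Cracks/macropores are thin dark random walks
(intensity × 0.12 — below any soil pixel near 980 nm); the translation
stage/holder background is a spectrally flat gray (980/420 ratio ≈ 1
versus ≥ ~3 for soil). Feature fractions ≥ 50 % are rejected.

**Laboratory noise.** ROI and bulk SOC values are slab/region truth means
plus `N(0, 0.45)` mg g⁻¹ — half the 0.9 mg g⁻¹ limit of determination of
dry combustion; the limit is a stated property of the method, the Gaussian
half-limit noise model is this package's choice. Bulk cutting follows the
agricultural-inventory scheme: three cores at 0–30, 30–45, 45–50, 50–60,
60–70, 70–78, 78–100 cm and two cores with 30–50 cm merged, giving 33
samples per five-core set.

**What the generator does not emulate.** No radiative transfer or
mineralogy, no 3-D pore structure (the imaging is a 2-D cut face), no
inorganic carbon (truth is organic C directly), no spatially correlated
illumination drift beyond the linear gradient, and ROI heterogeneity is
purely that of the Gaussian field. Tests passing on this generator show
the chain is correct and statistically well-behaved under these
conditions; they do not certify performance on real cores with different
mineralogy, moisture or surface roughness.

## Preprocessing

Masking thresholds (reflectance at the band nearest 980 nm < 0.2; 980/420
ratio outside [2, 40]) are configuration values calibrated on the clean
synthetic distribution — the source system states the bands and ratios but
no numbers. Only the lower ratio bound separates background from soil; the
upper bound is a loose guard, kept wide because additive offset noise can
push the dim 420 nm band of a genuine soil pixel near zero. Masking is
monotone in the thresholds and never alters spectral values. SNV uses the
sample (n−1) standard deviation; flat-spectrum pixels are masked and
counted rather than divided by zero. PCA renderings are fitted per core on
unmasked normalized-reflectance spectra (mean-centred, unscaled; whether SNV or normalized-reflectance input
is the better display basis is left open — a config switch covers both), with each loading sign-fixed so its
largest-magnitude element is positive.

## ROI selection and calibration

Automated placement emulates the visual/PCA-guided manual selection:
~25 % of regions in the plough horizon, the rest in the subsoil; ~30 % of
subsoil regions are centred on pixels with extreme first-component scores
(capturing spectrally unusual material such as biopore fills, sampled with
tall narrow 2-pixel-wide regions mimicking microspatula sampling of
'pure' material); every ROI is the most spectrally homogeneous of several
candidate rectangles, reflecting the stated goal of small, pure,
homogeneous regions. Areas stay within the physically sampled 0.1–4.8 cm².
Measured SOC is truth + laboratory noise.

Per ROI, subset size is `max(1, round_half_up(0.01 · n_pixels))`; the five
subsets are drawn independently (each without replacement) — whether the
original draws were disjoint is unknown, so the simpler convention is used
and seeded. Three randomly chosen subsets train; the full-region spectrum
and remaining two validate, so the full-ROI mean never enters training.
Mean spectra are the default statistic (medians are computed and
selectable).

## Models

* **PLS** — NIPALS via scikit-learn, single response, mean-centred,
  unscaled predictors. Component count 1–20 scored by 5-fold CV MSEP on
  the training samples; ties go to fewer components; a forced count can
  override while the CV optimum is still reported.
* **Random forest** — 200 trees, each grown on a 33 % *without-replacement*
  draw of the training samples (a with-replacement bootstrap would put
  ~63 % in-bag, contradicting the 33/67 in/out split this configuration
  specifies), ⌊√p⌋ = 14 candidate predictors per split for 186 bands,
  minimum split 2, minimum leaf 1. Out-of-bag predictions average the
  trees that never saw a sample.
* **SVM** — radial-kernel ε-regression. Predictors are scaled per band to
  [0, 1] on the training set (stored; prediction spectra may leave [0, 1])
  and then standardised to zero mean/unit variance inside the estimator —
  the convention of the R implementations this module mirrors, under
  which the reference operating point (γ = 0.01, C = 8, ε = 0.1) is
  interpreted; with standardisation, γ = 0.01 yields a genuinely local kernel under which
  out-of-domain spectra revert toward the intercept instead of
  extrapolating. The response stays in mg g⁻¹. The default grid
  (γ ∈ {10⁻³…1}, C ∈ {1…32}, ε ∈ {0.05, 0.1, 0.2}) brackets that point;
  every grid point is scored by 10-fold CV RMSE and by a 1/3-train,
  2/3-test subsampling bootstrap; CV decides, ties to the first point in
  grid order.

**Range constraint (PLS).** Predictions < 0 are replaced by the
calibration minimum and predictions above the calibration maximum by that
maximum; values between 0 and the minimum are deliberately left unchanged.
The operator is idempotent and preserves the raw values.

**Bias correction.** Tree ensembles regress toward terminal-node means:
high SOC is underestimated, low SOC overestimated, which maps onto depth
as topsoil-under/subsoil-over bias. The correction is a per-horizon
additive offset, `−mean(predicted − measured)` over that horizon's
evaluation residuals (bulk slabs in the pipeline), applied with no
subsequent clipping — corrected maps may extend slightly past the
calibration limits, and in deep near-zero-SOC subsoil slightly below
zero. Residual diagnostics report the residual-vs-SOC slope, per-horizon
means and the residual-vs-column correlation (expected ≈ 0; horizontal
position carries no bias).

## Evaluation conventions

ME is `mean(predicted − measured)` (negative = underprediction). RPD uses
the population (n-denominator) standard deviation of the measured values
so the identity `R² = 1 − RPD⁻²` is exact — the convention inferred from
the internal consistency of the evaluation tables this package mirrors.
Perfect predictions report RPD = ∞. Bulk evaluation compares each measured
depth-interval value with the mean (or median) of the predicted map over
the matching slab; the ± 1 sd variants take as effective prediction the
point of `[stat − sd, stat + sd]` nearest the measurement (a measurement
inside the interval scores zero error) — the only reading under which a
huge-variance predictor attains a perfect ± 1 sd score, as the mirrored
tables show. Metrics are pooled across cores, with a per-core breakdown
available.

## Spatial analysis

Depth profiles use non-overlapping windows of equal pixel count (default
6 cm × full width); the last partial window is reported with its true
count; sd is population-denominator (consistent with RPD) and skew the
adjusted Fisher–Pearson form. Hotspot candidacy compares each pixel
against the *depth-band median* (all columns within ± 1 cm of its row): an
isotropic neighbourhood median would be contaminated ~30 % by the
vertically elongated channel itself and inflate the reference. Candidates
are grouped 8-connected; regions below the minimum size (the area of a
0.5 × 2 mm footprint) are dropped; each surviving region's enrichment is
its statistic (default: region maximum; the mean is also reported) over
the median of its own annulus (region boundary out to 1 cm — the distance
at which biopores were compared against adjacent matrix — excluding the
region, other candidates and masked pixels). Coldspots mirror the rule
with `SOC < median / threshold`. The threshold-2 annulus-median rule is
this package's operationalisation — the source system never defines
"hotspot" numerically — and every parameter is configurable.

## Pipeline determinism and problem sizes

One global seed derives all per-stage and per-core substreams. Default
problem sizes — five cores at 2 mm pixels (500 × 30 × 186 ≈ 2.8 M values
per cube), 71 ROIs, 33 bulk samples — were chosen so a full run completes
in well under a minute on one CPU while every statistical property of
interest (horizon contrast, depth-CV ramp, biopore recovery, model
ordering) is resolvable; statistical acceptance tests repeat the chain
over ten seeds.

## Known limitations

* The ε-SVR is not range-bounded: on spectra of essentially carbon-free
  deep-subsoil pixels (truth at the 0.05 mg g⁻¹ floor, far below the
  ~1 mg g⁻¹ calibration minimum) the CV-optimised model can undershoot
  zero on a ~10⁻⁴–10⁻³ fraction of pixels. Tree predictions cannot leave
  the training range, and constrained PLS is clipped, so their maps never
  go negative.
* Bias correction is a two-level step function of depth; residual bias
  that varies *within* a horizon (e.g. curvature of the tree-ensemble
  shrinkage across the subsoil gradient) is not removed.
* The depth-band median used for hotspot screening assumes enriched
  features are narrow relative to the core width; a feature spanning most
  columns at one depth would suppress its own detection.
* Detection on *predicted* (rather than truth) maps inherits model
  shrinkage: recovered enrichment factors on bias-corrected forest maps
  are systematically below planted values; quantitative recovery tests
  therefore run on the truth field, and predicted-map hotspot reports
  should be read as conservative.
* ENVI I/O covers exactly what the package writes (BSQ, byte order 0);
  vendor-specific header extensions are not parsed.
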