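# Methods

`maizelai` re-implements, as a tested pipeline on synthetic data, a
workflow for estimating maize leaf area index (LAI, m² m⁻²) from five-band
(B 450, G 560, R 650, RE 730, NIR 840 nm) plot imagery: vegetation indices
(VIs) + GLCM texture features (TFs) + 2D/3D texture indices (TIs), fused
by a stacked PLSR + machine-learning regressor. This note documents the
models, the parameters that matter, and the design choices made where the
design was genuinely open.

## Synthetic trial generator

The generator emulates a density × nitrogen field trial: 3 planting
densities (D1–D3 ↔ 42 000 / 63 000 / 84 000 plants ha⁻¹) × 4 nitrogen
rates (N0–N3 ↔ 0 / 80 / 160 / 240 kg N ha⁻¹) × 3 replicates = 36 plots,
observed on 5 dates (180 samples). An independent external scenario uses
4 dates, a darkened soil endmember (×0.8) and 1.5× pixel noise.

**LAI trajectory.** Expected LAI is a unimodal season curve (peak at
seasonal position 0.72, i.e. the fourth of five dates — early grain
filling) scaled by density and nitrogen multipliers chosen so that the
expected maximum sits at D3N2 and means rise with density, and with N up
to N2 with a slight decline at N3. The top-level scale (5.1 at the D3N2
peak) and multipliers were calibrated once so draws span ≈[0.8, 5.3];
every draw carries multiplicative lognormal plot noise (σ = 0.08 in log
space — a mean-preserving form of lognormal plot scatter) and is clipped
to [0.77, 5.28], the configured LAI domain.

**Canopy radiometry.** Each scene is a two-endmember mixture. Leaf discs
(mean radius 3 px, ~N(3, 0.6)) are stamped at random positions until the
soil-visible fraction falls to the Beer–Lambert gap fraction
g = exp(−k_ext·LAI), k_ext = 0.6 (typical for maize canopies); the
stopping overshoot is below one disc area (≤0.2 % of a 128² image, well
inside the ±0.01 tolerance). Default endmembers are a green-vegetation
leaf spectrum (0.05, 0.12, 0.06, 0.35, 0.50) and a brighter soil spectrum
(0.12, 0.18, 0.22, 0.26, 0.30) for (B, G, R, RE, NIR).

Real acquisitions are noisier than a clean two-endmember scene, so three
lognormal jitter terms are part of the default conditions: per-blob
shading (σ = 0.15; canopy self-shadowing, keeps within-canopy texture
informative even near full cover), per-sample leaf-spectrum jitter
(σ = 0.05 per band; chlorophyll/BRDF variation), and per-plot soil
brightness (σ = 0.08; moisture/roughness). A per-date illumination gain
drawn uniformly in [0.9, 1.1] emulates acquisition-time differences.
Per-pixel Gaussian noise (sd 0.01) is added and values clipped to [0, 1].
These choices matter for what the tests show: ROI-mean spectra — hence
VIs — carry irreducible radiometric error, while min–max quantisation
makes GLCM features exactly invariant to per-band affine changes, which
is the mechanism by which texture features add information here, echoing
their motivation on real imagery.

What the generator does **not** emulate: radiative transfer (no PROSAIL),
multiple scattering, tassels/reproductive organs, row structure,
orthomosaic/stitching artifacts, and view-angle effects. Passing tests
therefore demonstrate the pipeline's correctness and its statistical
behaviour under the stated generative assumptions, not field-data
accuracy.

**Determinism.** A single root seed drives everything through keyed
`SeedSequence` children (scenario, plot, date), so regeneration is
bitwise identical and the main and independent scenarios use disjoint
streams.

## Features

*ROI.* Band means and textures are computed on a centred ROI that trims
10 % of each image dimension per side (edge avoidance). Default plot
images are 128×128 px — large enough for stable GLCM statistics at desk
scale; pixel extent is a free parameter of the generator.

*VIs.* The 11 standard indices (GNDVI, NDVI, DVI, RVI, OSAVI, SAVI, EVI,
VARI, EXG, EXR, CIRE) from ROI band means. CIRE is (NIR/RE) − 1. Zero
denominators yield NaN with a warning, never infinities. EXG is computed
and reported but excluded from the default model-input set of 10 — the
excess-green signal saturates at full cover and is characteristically a
poor LAI correlate.

*TFs.* Per band, a 4×4 window slides with stride 1 over the quantised ROI
(32 gray levels, linear min–max per band per ROI; a constant band maps to
level 0); in each window a symmetric co-occurrence matrix at single
offset (dx, dy) = (1, 1) is formed and eight metrics (mean, var, hom,
con, dis, et, sem, cor) computed, then averaged over window positions —
40 features per sample. Conventions: energy ("sem") is the angular second
moment Σp² (not its square root); correlation is defined as 0 for
zero-variance windows so ROI averages stay bounded; entropy uses natural
logs with 0·ln 0 = 0. Multi-offset averaging and non-overlapping block
tiling are available via configuration. The engine is vectorised (per
symmetric matrix, every metric decomposes over window pixel pairs, with
entropy/energy recovered from per-window pair multiplicities) and is
verified against an independent brute-force pair-enumeration oracle to
1e-10.

*TIs.* Six families over texture values T1, T2(, T3):
NDTI = (T1−T2)/(T1+T2), DTI = T1−T2, RTI = T1/T2,
NDTTI = (T1−T2−T3)/(T1+T2+T3), DTTI = T1−T2−T3, RTTI = T1/(T2·T3).
Candidates are enumerated exhaustively over the selected TF pool (ordered
pairs for 2D; ordered head with unordered tail for 3D since all three 3D
formulas are T2↔T3-symmetric), rather than sampled randomly — the
reproducible superset. Samples with undefined values (zero denominators)
are excluded pairwise from that candidate's correlation.

## Selection and modeling

Features are screened by Pearson correlation with LAI at α = 0.05
(two-sided t test, n−2 df) with no multiple-testing correction — a
deliberate replication of common practice and a documented caveat. The
TF group is capped at the 10 strongest significant features; that pool
feeds the TI enumeration, from which the 10 strongest significant indices
are retained. For cross-validated performance, screening is re-run inside
every training fold; the deployed model uses screening on the full
modeling set.

The stack pairs PLSR (components searched in 1..min(15, p, n−1); PLSR
standardises internally) with one of SVR (RBF; standardised inputs), RF
or GBDT (raw inputs — trees are scale-free). Out-of-fold predictions from
k = 5 folds (k is a free choice balancing bias and variance at n = 120)
form a two-column meta-feature matrix fitted by Lasso (penalty path by
inner CV, inputs standardised); both bases are then re-tuned and refitted
on the full training set for deployment. Grid search minimises inner-CV
RMSE with ties broken by grid order. The default grids sit inside the
published ranges (GBDT learning rate 0.05–0.2, depth 3–5, min leaf 2–5,
trees 100–300; RF trees 100–300, feature ratio 0.3–0.8; SVR C 0.1–100,
ε 0.01–1); the exact published grid cardinalities are not reproducible
from the ranges alone, so the defaults approximate them, and reduced
("fast", 4-point) and single-point ("minimal") grids are provided for
desk-scale runs — the acceptance checks use the fast grids with 3 inner
folds.

Outer evaluation is repeated K-fold (10-fold default; 5-fold × 2 repeats
for PLSR-only evaluation), with screening, tuning and stacking re-run per
outer fold. The no-leakage property is enforced structurally and verified
by corruption harnesses: corrupting a fold's labels cannot change that
fold's predictions.

## Splitting, metrics, maps

The modeling/validation split sorts the 180 samples by LAI and assigns
every third rank starting at rank 2 to validation (60/120), a
rank-systematic rule that spans the LAI domain; stratified random
splitting is available via configuration. Metrics are R² = 1 −
Σ(x−y)²/Σ(x−x̄)², RMSE and MAE in LAI units; constant observed vectors
make R² NaN with a warning while RMSE/MAE are still returned. LAI maps
re-run the full feature schema per tile (default 32×32 px, stride 32) of
a peak-season plot and are written as single-band float TIFF tagged
m2/m2; TIFFs carry no georeference (synthetic scenes have none).

## Problem sizes and limitations

Default test and acceptance runs use the full design scale (36 plots ×
5 dates, 128 px images) for the signal-recovery, null-control and
transfer checks (5 generator seeds; 20 permutation replicates on a
reduced feature set with the SVR stack; fast grids), and reduced designs
(12–24 samples, 48 px) for unit-level checks — chosen as the package's
desk-scale defaults. Known limitations: the generator's VI–LAI relation
is smoother than field data (no phenology-specific spectra), absolute R²
values on synthetic scenes exceed field-reported ones and should not be
compared to them; the screening procedure's per-fold/full-data duality
means the deployed feature list can differ from any single fold's; Lasso
on two near-collinear meta-features has a non-unique population optimum —
coordinate descent's selection is deterministic but can flip between
bases across seeds.
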