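# Methods

This note documents the models implemented in `sprkit`, the defaults and why
they were chosen, what the synthetic data does and does not emulate, and the
numerical conventions. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Stopping-power ratio from the Bethe equation

The core quantity is the stopping-power ratio relative to water,

SPR = ρₑ · L(I) / L(I_w),  L(I) = ln(2mₑc²β²/(1−β²)) − ln I − β²,

with no shell, density-effect or Barkas corrections. β² is evaluated at a
fixed kinetic energy of 100 MeV per nucleon using the proton rest energy
938.272 MeV for all ion species (the β of a fully stripped ion depends only
on energy per nucleon to the accuracy relevant here; both values are
configurable through `PhysicsConstants`). The water I-value is 78.73 eV.
Energy sensitivity is negligible across the therapeutic range: the test suite
checks |SPR(70) − SPR(200)|/SPR(100) < 1% for every packaged material.
`bethe_spr` raises (rather than returning NaN) if the stopping number is
non-positive, which happens only for unphysically large I at low energy.

## Elemental I-values and the water anchor

The elemental table ships ICRU-37 gas-phase I-values (with IUPAC atomic
weights). Plain Bragg additivity over gas-phase values yields ≈69 eV for
water, which is inconsistent with the condensed-phase convention
I_w = 78.73 eV: left uncorrected, water's own SPR would come out ≈1.017.
The loader therefore applies one multiplicative factor to all elemental
I-values (a uniform shift in ln I) chosen so Bragg additivity on the packaged
water composition returns exactly 78.73 eV. This is the standard
condensed-phase anchoring trick; it preserves all I-value *ratios* and makes
both calibration chains exactly water-consistent. Pass
`anchor_water_ivalue=None` to `load_material_tables` for the raw table.

## EAN → I-value mapping (DLCT calibration)

Tissue I is predicted from the effective atomic number via a piecewise-linear
model of ln I as a function of Z_eff, least-squares fitted on the reference
human-tissue table. Defaults: two segments split at Z_eff = 8 (soft tissue
vs bone); segment slopes come from per-segment OLS and intercepts are chained
outward from the anchor segment so the mapping is continuous; with
`water_anchor=True` (default) the soft-tissue segment is shifted so water's
Z_eff maps to exactly 78.73 eV, pinning SPR(water) = 1. Z_eff uses the
electron-fraction power mean with exponent 3.3 — the same exponent as the
mass-density formula — and the same exponent must be used when synthesizing
EAN maps and when predicting from them. Inputs outside the fitted Z_eff range
are clamped to the nearest boundary; voxels with ED < 0.05 are assigned
SPR = 0.001 instead of entering the logarithms.

`exact_ivalue_mapping` builds the *self-consistent* alternative: a
piecewise-linear interpolant through a material set's own (Z_eff, ln I)
points. It exists for closed-loop verification — a noise-free synthetic
phantom pushed through it reproduces the ground-truth SPR to floating-point
precision — and for phantom studies where the materials are known exactly.

## Two-parameter CT-number model and HLUT (SECT calibration)

Relative attenuation is modeled as
u = ρₑ(k₁Z̃^3.62 + k₂Ẑ^1.86 + 1)/(water value), CTN = 1000(u−1), where Z̃ and
Ẑ are electron-fraction power means with the photoelectric (3.62) and
coherent (1.86) exponents. `fit_attenuation` calibrates (k₁, k₂) from
(composition, CTN) pairs by exact linearization and least squares; negative
solutions are re-solved under a non-negativity constraint (NNLS) with a
warning. The two regressors are strongly collinear over tissue-like
materials (r ≈ 0.99 on the packaged surrogates), so under CT-number noise
the small coherent weight k₂ is poorly identified even though the *fitted
model* remains predictive — the tests therefore check per-seed recovery of
k₁ and the refit model's CTN RMS error, not per-seed k₂.

When no measured calibration exists, `reference_attenuation_fit` supplies
representative 120 kVp weights (k₁ = 5·10⁻⁵, k₂ = 6·10⁻⁴), chosen once so
familiar materials land at familiar CT numbers (water 0 HU, air ≈ −999 HU,
PMMA ≈ +120 HU, cortical-bone surrogate ≈ +1720 HU).

The HLUT is built by computing (theoretical CTN, Bethe SPR) for each
reference tissue — with I from Bragg additivity, *not* from the EAN mapping,
keeping the two calibration chains independent — and least-squares fitting a
continuous linear spline with knots at −950, −120 and +100 HU (air/lung,
lung/soft, soft/bone joins; configurable). An air node (−1000 HU, 0.001) is
prepended and evaluation is piecewise-linear with flat extrapolation beyond
the end nodes. Per-tissue fit residuals and the HU at which the curve
crosses SPR = 1 are stored on the object; the residuals are what a
closed-loop phantom run must reproduce exactly.

## Mass density from ED and EAN

ρ = ρₑ(1 + e₀ + e₁x + e₂x²) with x = (Z_eff/Z_eff,w)^m − 1 and m = 3.3. The
published coefficient values for this formula are not shipped; the default
coefficients are refit by least squares on the packaged reference tissue
table (`fit_deedz`), and users can override them via `DeedzCoefficients`
(JSON-serializable). The convention x⁰ = 1 means a water voxel maps to
ρ = ρₑ(1 + e₀).

## Synthetic phantoms: what they emulate and what they do not

Geometry reproduces the study layout: PMMA cylinders LCT (r 5 cm, h 46 cm),
LC (8/46), SC (8/10), SCB (16/10); inserts r 1.4 cm, depth 7 cm. The
nine-bore layout (one central bore, eight on a ring at 60% body radius, bone
surrogates non-adjacent) is representative — the physical phantoms' bore
coordinates are not published. Default voxels are 0.977 × 0.977 × 1 mm³,
axis order (z, y, x), world coordinates at voxel centers, labels assigned by
voxel-center membership. Ground truth for every label is computed from the
packaged compositions at rasterization time, so all downstream comparisons
are self-consistent by construction.

The surrogate-insert and human-tissue compositions are representative
published values and are **fixtures**: accuracy statements in the tests are
about the method applied to these fixtures, never about the physical
products. Channel noise is i.i.d. Gaussian per channel with a shared seeded
generator (defaults used in the validation runs: σ_HU = 10 HU, σ_ED = 0.01,
σ_EAN = 0.1 — scanner-realistic magnitudes for a body protocol). Real
dual-layer ED/EAN noise is spatially correlated and anti-correlated between
channels, and real scans add beam hardening, scatter and metal artifacts;
none of that is modeled. Consequently, passing tests demonstrate the
correctness of the prediction/evaluation machinery and the *systematic*
component of each route's error (calibration-transfer error for DLCT,
degeneracy error for SECT), not scanner performance.

With these conditions the DLCT route shows a mean overall residual under 1%
with individual bone surrogates up to ≈1.8% (their CaCO₃-based chemistry
sits below the human-bone ln I trend), while the SECT route shows 2–3× larger
residuals — the ordering the package's acceptance ensemble quantifies over
100 seeds.

## ROI statistics

Per insert, the ROI is a circle of 70% of the insert diameter around the bore
axis with 10 mm excluded at each insert end (both configurable); in a
scanner this avoids rim gradients and partial-volume slices, and the
synthetic pipeline keeps the same rule so the analysis chain is identical.
Summary statistics are the standard formulations: mean of |relative
residual|, RMSE on the SPR scale, Pearson r and OLS slope/intercept (via
`scipy.stats.linregress`); with fewer than two pairs, or a constant
reference, the correlation/regression fields are NaN.

## WEPL and distal shift

WEPL(d) = ∫₀^d SPR ds along a straight ray, computed by trilinear
interpolation at 0.1 mm steps (must not exceed the voxel spacing) and
cumulative trapezoidal integration; the ray is clipped to the voxel-center
bounding box. The distal shift between two SPR maps is the difference of
depths at which their cumulative WEPL first crosses a target, by linear
inverse interpolation. Closed forms on uniform media (WEPL = SPR·depth;
a 1% SPR scaling moves the crossing by −1%/1.01 of depth) hold to the
integration tolerance and are asserted in the tests.

## Gamma analysis

γ(r) = min over candidate positions e of √(‖e−r‖²/δ² + (Dₑ(e)−Dᵣ(r))²/(c·D_n)²)
with δ the distance-to-agreement (default 1.5 mm), c the dose criterion
(default 3%), D_n = Dᵣ(r) for local normalization (default) or max Dᵣ for
global. Reference points below 5% of the reference maximum are excluded.
The minimization searches a cubic lattice of step δ/10 (configurable) inside
a sphere of radius 3δ, interpolating the evaluated grid trilinearly;
candidates are visited in shells of increasing distance and the search stops
once the spatial term alone exceeds the current best γ — an exact
optimization over the lattice, verified against an exhaustive brute-force
oracle to 10⁻⁶ in the tests. γ = 1 counts as a pass. The grids need not
share spacing or extent (a 2-D measurement plane is a single-slice grid).

One subtlety the tests make explicit: the textbook expectation "a pure
translation by exactly δ gives γ ≤ 1 everywhere" holds when the evaluated
field is exactly representable under trilinear interpolation. With local
normalization, interpolation error on a curved profile is amplified by 1/Dᵣ
near the low-dose cutoff and can push γ slightly above 1. The translation
checks therefore use a linear fall-off field (exact under trilinear
interpolation), with the evaluated grid padded beyond the reference so edge
points keep their perfect candidate — both provided by
`make_dose_pair(field_type="ramp", eval_pad_mm=...)`.

## Problem sizes of the shipped validation runs

Zero-noise recovery and the 100-seed ordering ensemble run the SC phantom at
2 mm isotropic voxels (≈0.5 M voxels; one full two-route cycle ≈0.1 s); the
range-shift check and the worked examples use the 1 mm-class default
spacing. Gamma oracle equivalence uses 5³ grids with a 0.5 mm search step so
the exhaustive oracle stays tractable; the engine itself is routinely run on
much larger grids.

## Known limitations

- The Bethe treatment (and the clamped I-mapping) is approximate for metals;
  implant materials are included in the tables but carry no correction.
- ED/EAN maps are inputs: no spectral decomposition from raw projections.
- The HLUT segment boundaries and the reference attenuation weights are
  documented package choices, not a reproduction of any clinic's protocol.
- The DEEDZ-style mass-density coefficients are refit on the packaged tissue
  table, not the originally published values.
- No anthropomorphic geometries; cylinders only.
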