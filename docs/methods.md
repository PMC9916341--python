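# Methods

This note records the models implemented in `aquarisk`, the defaults and
why they were chosen, the numerical details, and the limits of what the
synthetic generator (and therefore the test suite) can demonstrate.

## Survey model and data conventions

A survey is a table of wells and mine-water samples in three groups
(`mining`, `non_mining`, `mine_water`), each with bulk physicochemical
variables (pH, EC, TDS, turbidity, ORP, temperature), major ions (Na, K,
Ca, Mg, HCO₃, Cl, SO₄, NO₃, PO₄) and metals (Cr, Ni, Mn), all in mg/L.
Charge-balance arithmetic is in meq/L (mg/L × |z| / M). The ion charge
balance error

    ICBE = (ΣCat − ΣAn) / (ΣCat + ΣAn) × 100

uses cations {Na, K, Ca, Mg} and anions {HCO₃, Cl, SO₄, NO₃, PO₄} with
PO₄ as −3; the ion set is configurable because survey practice varies on
whether the nutrient anions enter the balance. |ICBE| ≤ 5 % is the QC pass.
Missing concentrations are treated as *not measured*: excluded from sums
with a logged warning, never imputed as zero, and no charge-balance
correction is ever applied to the data (QC flags only).

## Pollution indices

Single-factor ratios divide each concentration by its WHO guideline limit
(bundled: EC 400 µS/cm, turbidity 5 NTU, TDS 1000, Na 200, K 12, Mg 50,
Ca 100, PO₄ 0.1, NO₃ 50, HCO₃ 500, Cl 250, SO₄ 500, Cr 0.05, Ni 3.0,
Mn 0.5 mg/L). The Nemerow composite is the root-mean-square of the mean and
the maximum ratio; it is monotone in every concentration and lies between
max-ratio/√2 and max-ratio. pH is two-sided and excluded from the composite
by default; an explicit pH ratio against a 7.8 reference is available but
not part of NPI, because a one-sided ratio is ill-defined for a banded
guideline (6.5–9.2).

## Health-risk chain

The oral route only: for drinking-water surveys ingestion dominates, and
the bundled toxicity set covers it. The chain is homogeneous of degree 1 in
concentration, so group-level range endpoints map through unchanged.

**Exposure convention.** The default profile uses lifetime exposure —
EF = 365 d/y, ED = 70 y, AT = 70·365 d, hence EF·ED/AT = 1 and
CDI = C·IR/BW. A `printed_2023` profile with ED = 350 days (a convention
that appears in some published risk tables) is provided; it scales every
quantity by 350/25550. The lifetime convention is the default because it is
the one under which the published per-cohort intake endpoints for this
study design are reproduced exactly (e.g. Cr 4.5 mg/L → child
0.500 mg/kg/day).

**Toxicity constants.** RfDs are not universally tabulated for this metal
set at these conventions; the bundled values (Cr 1.5, Ni 0.02,
Mn 0.14 mg/kg/day) were fixed by inverting published CDI/HQ pairs and are
stored as data in `datatables.py`, overridable per profile. Note the Cr
value corresponds to total/Cr(III)-style assessments, not the much stricter
Cr(VI) oral RfD. CSFs: Cr 0.5, Ni 0.91 (mg/kg/day)⁻¹; Mn is not treated as
carcinogenic and requesting a slope factor for it is an error.

**Orderings.** With these constants and the bundled group means, nickel
dominates the noncarcinogenic hazard in every group and cohort (its RfD is
75× smaller than chromium's), and the carcinogenic chain orders
Ni > Cr > Mn (Mn nil). Chromium and manganese hazard quotients are close,
with Mn slightly ahead; a strict HQ ordering Cr > Mn is **not** asserted
anywhere because it does not follow from these constants. Cohort intakes
order child > female > male (IR/BW = 0.111, 0.0484, 0.0385 L/kg/day).

## Receptor models

**Uncertainty model.** u = (5/6)·MDL where C ≤ MDL, else
u = √(MDL² + (f·C)²) with error fraction f = 0.035 and detection limits
Cr 0.1, Ni 0.5 mg/L (Mn 0.05 as a package default). The below-limit branch
uses C ≤ MDL: stating it for C > MDL (as sometimes printed) would
contradict the above-limit formula, and 5/6·MDL is the standard convention
for censored values.

**PMF.** Weighted NMF on Q = Σ((X−GF)/U)² via multiplicative updates on the
weighted Frobenius objective (Q provably nonincreasing per iteration; the
suite asserts it). Defaults: 20 random nonnegative starts, 5000 iterations
maximum, convergence when the relative Q drop over 20 iterations falls
below 1e-8; best start kept; non-convergence is flagged on the result, not
raised. Q_robust caps |e/u| at 4 (each outlier cell contributes at most
16). Factor count is user-chosen; `factor_scan` reports Q over p = 3..5
but performs no automatic selection. Signal-to-noise per parameter is the
mean over samples of (x−u)/u where x > u, else 0. Factor order is
arbitrary; recovery metrics use Hungarian assignment on cosine similarity
of profiles. No bootstrap/displacement uncertainty estimation and no Fpeak
rotation are provided.

**APCS-MLR.** PCA on the correlation matrix, varimax rotation (delegated to
statsmodels' rotation routine, with per-factor sign fixed so the dominant
loading is positive), regression-method factor scores, absolute scores by
rescoring an artificial zero-concentration sample, and an ordinary
least-squares regression of the total measured burden on the APCS. Percent
contribution of source k = b_k·mean(APCS_k) / mean(fitted) × 100; the
intercept share is reported as unexplained. Regressing individual species
instead of the total burden is available via the `target` argument.

## Clustering

Euclidean distance on z-scored variables (mixed units make standardization
necessary), Ward linkage, tree cut at k = 3 to match the three-cluster
survey design. Variance decomposition uses the standardized total sum of
squares, so within% + between% = 100 exactly. Severity labels order the
three clusters by the sum of centroid single-factor metal ratios; ties
break lexicographically and are flagged.

## Speciation

Ionic strength I = 0.5 Σ m z²; Davies activity coefficients with A = 0.5092
at 25 °C (out-of-validity warning above I = 0.7); carbonate from pH and
HCO₃ via log K₂ = −10.33, hydroxide via log K_w = −14. The mineral set is
limited to simple congruent phases (calcite, aragonite, dolomite, gypsum,
anhydrite, halite, rhodochrosite, brucite — the latter written against H⁺);
log K values are data in one versioned table and overridable. SI
classification uses the universal threshold 0 (supersaturated above,
undersaturated below); a nonzero threshold can be passed for comparison
with schemes that classify at ±1. No redox couples, no temperature
correction, and no full thermodynamic database: reproducing a PHREEQC run
is out of scope.

## Spatial

IDW with power 2 default; ordinary kriging solves the standard augmented
system per query (weights sum to 1; exact with zero nugget). Variograms:
method-of-moments empirical semivariogram in 12 bins, least-squares fit of
spherical (default), exponential, or gaussian models. Grids are the
axis-aligned bounding box of the samples (default 100×100; the pipeline
uses 40×40 to keep runs fast). Vulnerability classes are equal-interval
five-class breaks between the surface minimum and maximum — the scheme that
reproduces published class edges such as 0.02–2.19 → breaks at 0.454,
0.888, 1.322, 1.756. Coordinates are treated as planar; lon/lat input is
accepted as-is with a warning (no projection engine).

## Synthetic generator

Defaults encode the study conditions: group sizes 35/20/5; per-group,
per-parameter ranges and mean ± SD from the survey's summary table;
water-type weights 0.466 / 0.266 / 0.233 / 0.035 (the minor Ca-Mg-Cl class
absorbs the rounding residual so the categorical weights sum to 1).

* **Marginals.** Truncated normals whose underlying (µ, σ) are solved by
  least squares so the *truncated* moments match the targets inside the
  range — a plain normal could not satisfy range and moments
  simultaneously. Solutions are cached per (range, mean, sd).
* **Facies structure.** Each sample draws a target quadrant; where the
  independent ion draws land in the wrong quadrant, the lighter panel side
  ((Ca,Mg) vs (Na,K); HCO₃ vs (Cl,SO₄)) is scaled just past parity with a
  random margin. TDS is a separate column and is untouched.
* **Charge balance.** The anion panel is then rescaled so each sample's
  ICBE equals a uniform draw in ±3 %, guaranteeing the ±5 % QC band. This
  preserves Chadha signs (uniform anion scaling) and never touches metals,
  so metal columns always respect their published ranges.
* **Mixing mode.** `generate_mixture` emits X = GF + ε with block-distinct
  nonnegative profiles, lognormal contributions with ~30 % dropout (each
  source inactive at some wells — without that contrast an all-positive
  shared mode makes any nonnegative factorization rotationally ambiguous),
  and ε ~ N(0, u_ij) under the uncertainty rule, clipped at zero. Default
  n = 60, m = 16, p = 3 mirrors the survey scale.
* **Clusters.** `generate_blobs` provides separated Gaussian blobs with
  counts 12/8/40 and increasing burden for clustering recovery (the 40/60
  design gives the 66.67 % severely-polluted share).

Not emulated: cross-parameter correlation (ions are independent before
post-processing; a correlation hook would be the natural extension),
spatial autocorrelation (coordinates are uniform scatter; kriging tests use
separately constructed smooth fields), and detection-limit censoring.
Passing recovery tests therefore shows the estimators are correct under
their own assumptions — not that real surveys are this well-behaved.

## Problem sizes and determinism

The test suite and the acceptance script run the recovery experiments at
the survey scale (n = 60 × 16 matrix, 20 PMF starts; 200 × 8 for the
APCS split; 2000 draws for moment-convergence checks), which keeps a full
run under a minute on one CPU while leaving the stochastic assertions
comfortably inside their tolerances. Every random draw flows from a single
`numpy.random.default_rng` seed; PMF fits are bit-reproducible for a fixed
seed, and the pipeline bundle is hash-identical across reruns with the same
input, config, and seed.

## Known limitations

* The Nemerow composite's parameter set and the pH denominator are
  conventions, not universals; both are configurable.
* RfD/CSF values are assessment-specific; treat the bundled toxicity table
  as an input, not a recommendation.
* The PMF solver is a local optimizer; multi-start mitigates but does not
  eliminate local minima for poorly identified mixtures.
* Davies activities degrade above I ≈ 0.5–0.7 mol/kg; brines need a
  Pitzer-class model this package does not include.
* Kriging assumes second-order stationarity and planar coordinates.
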