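# Methods

## The analysis

`madct` implements a landmark-based cardiac-CT analysis of mitral annular
dynamics (MAD) and mitral-regurgitation (MR) severity in dogs with
myxomatous mitral valve disease, together with the paired pre/post
treatment statistics used to report a drug effect.  Image acquisition and
segmentation are out of scope: the inputs are 16 manually placed 3D markers
per annulus (with two flagged fibrous trigones), per cardiac phase, plus
per-visit chamber volumes, oscillometric pressures and aortic flow/area
measurements.

### Annulus geometry

The closed annulus curve is a periodic cubic interpolating spline through
the 16 markers under chord-length parametrization, resampled at M
approximately arc-length-uniform points (default M = 512; the closed-form
checks below hold for any M ≥ 64).  No named curve model is standard for
annular rings; smooth periodic interpolation is the simplest model that
renders the familiar saddle and is exactly rigid-equivariant.

The projection plane is the total-least-squares plane of the resampled
curve (SVD of the centered points).  The normal is oriented toward the left
atrium using the declared marker winding (counter-clockwise from the atrial
view by default), which fixes the sign of saddle elevation.

Metric definitions:

* **MAA** — shoelace area of the curve projected onto the plane.
* **APD** — each portion's point of maximal signed elevation is its horn;
  APD is the in-plane distance between the horns' projections.  For rings
  flatter than 0.05 mm the horns degenerate, and the axis falls back to the
  line through the projected centroid and the trigone-chord midpoint,
  intersected with the projected curve.  The threshold is far below any
  realistic annular saddle height (millimetres) and far above coordinate
  noise, so the branch only triggers on deliberately planar test input.
* **ICD** — caliper width (max − min scalar projection) of the projected
  curve along the in-plane direction orthogonal to the APD axis.
* **TTD** — 3D chord between the trigone markers.
* **SI = APD/ICD**, **LAI = TLL/APD** at late systole.

APD and ICD are measured in projection; TTD in 3D.  The upstream tool's
convention is not published; in-plane measurement is what makes "orthogonal
to the APD" well defined, and all three agree for flat rings.  The aortic
portion is the shorter trigone-to-trigone arc (the aortomitral continuity
is the short anterior segment); a self-intersecting projection is flagged
as a warning but still measured, so one badly landmarked frame cannot crash
a batch.

Accuracy on the analytic saddle family `x = a·cosθ, y = b·sinθ,
z = h·cos 2θ` sampled at 16 markers: MAA within 0.02% of πab, APD/ICD
within 0.02% of 2a/2b, MAA independent of h to <0.01%, and all metrics
rigid-motion invariant to ~1e-15 relative (the tests assert the
much looser 1%/1e-9 contracts).

### Volumetrics, MR and indexing

TSV = LVEDV − LVESV and EF = TSV/LVEDV from the CT volumes; with no
relevant right-sided regurgitation, RV TSV stands in for the LV forward
stroke volume, so RVol = LV TSV − RV TSV and RF = RVol/LV TSV.  Negative
RVol is returned with a warning, not clipped — clipping would bias the
paired statistics.  Indexing: linear measures ÷ BW^(1/3), areas ÷ BSA
(cm²/m²), volumes ÷ BW.  BSA uses the standard canine allometric form
0.101·BW^(2/3); the constant is exposed (`BSA_COEFFICIENT`) because any
alternative convention rescales all area indices uniformly.

### Hemodynamics

Ea = MBP / (FSV/BW) with FSV = aortic VTI × valve area from echo; MBP is
the recorded oscillometric mean.  ADI = ((A_max − A_min)/A_min)/(SAP − DAP)
for the ascending aorta; the diastolic (minimal) area is the denominator,
the usual baseline for distensibility indices.  Both are unvalidated
surrogates and are treated as plain derived quantities.

### Dynamics classification

A profile maps phases (MD, LD, ED, MS, LS, ES) to metrics; missing phases
stay missing (no interpolation across the 20 reconstructed frames).
Systolic behaviour compares ES to ED with a ±1% relative dead-band:
published cohorts classify by the sign of mean changes, but per-subject
data need a tolerance so measurement noise does not flip labels.  The
classification is invariant to indexing since the denominators cancel.

### Paired statistics

Differences are pre − post (a treatment-induced decrease is positive,
matching the reporting convention).  Routing is by Shapiro–Wilk at
α = 0.05 only — Q-Q-plot inspection is not automatable.  Parametric route:
paired t-test.  Nonparametric: Wilcoxon signed-rank, zeros dropped, ties
midranked, exact two-sided distribution for n ≤ 25 and a
continuity-corrected normal approximation above.  The t-based 95% CI of
the mean difference is reported for every variable, including
nonparametrically routed ones, with a style flag — mean differences with
CIs are the quantity of interest even when the p-value is rank-based.
No multiplicity adjustment is applied across the ~32 variable × phase
cells; this mirrors single-cohort reporting practice and inflates the
family-wise error rate accordingly.

## The synthetic cohort generator

The generator defines the study conditions for all validation: 20 dogs,
body weight uniform on 4.3–19.6 kg (only the range of the target population
is published).  Per phase, each annulus is a saddle ellipse whose indexed
diameters (2a/BW^1/3, 2b/BW^1/3) equal the untreated cohort's per-phase
means (APD 9.75–10.96, ICD 11.18–12.17 mm/kg^1/3), times a subject-level
lognormal-free scale factor N(1, 0.08); saddle semi-height 0.9 mm/kg^1/3;
trigones at ±3π/16 so the indexed trigone chord ≈ 6.2 mm/kg^1/3.  Markers
are placed half a step off the horns (offset π/16), jittered with isotropic
Gaussian σ = 0.3 mm, and moved by a random rigid transform per frame.
Volumes obey conservation exactly before noise: LVEDV 4.21 mL/kg × subject
factor N(1, 0.15), total EF 0.639, RF 0.371, RV TSV = FSV = TSV − RVol.
MBP 89.5 ± 15 mmHg between subjects, ±6 mmHg per visit; ADI 5.379×10⁻³
mmHg⁻¹ with 18% lognormal subject spread; volume/flow CV 4%.  Noise levels
are the package's choice (no error model is published) and are set to
reproduce the printed pre-treatment between-subject SDs to first order.

The default treatment effect multiplies systolic semi-axes (ES: a×0.906,
b×0.934; MS: b×0.976; LS intermediate — the post/pre ratios of the printed
systolic means), shifts volumes additively (ΔLVEDV −0.52, ΔLVESV −0.28
mL/kg, ΔRF −0.0975, LA volumes likewise) and leaves diastolic geometry,
the trigone chord (the trigone angle is re-solved after the b-multiplier)
and pressures unchanged.  This reproduces the qualitative signature:
paradoxical systolic MAA expansion before treatment, contraction after.

What the generator does *not* emulate: non-elliptical annular shapes,
correlated (non-isotropic) landmarking error, observer drift between
visits, breed structure, and any coupling between annular size and MR
severity.  Passing tests therefore demonstrate correctness of the
computational pipeline and calibration of its statistics under the stated
model — not robustness to every property of real CT data.

## Validation results the code computes

* Type-I error of the full gated pipeline on 2000 null cohorts (n = 20):
  ≈ 0.05, asserted within [0.035, 0.065].
* Coverage of the t-based 95% CI for the programmed ES APD effect over
  1000 cohorts run through the full landmark pipeline: ≈ 0.95, asserted
  within [0.93, 0.97].  Coverage simulations use M = 128 and an ES-only
  phase list; replicate counts and M are chosen so a full run completes in
  about a minute on one core without changing the conclusions.
* The recovered ES APD mean difference carries a ≈1% low bias relative to
  the programmed 1.03 mm/kg^1/3 (spline horn localization under jitter);
  this is within the geometry pipeline's stated 1% tolerance and is small
  against the sampling SE, so CI coverage is unaffected.
* Noiseless cohorts return RF = 37.1% to machine precision and zero paired
  differences under a null effect.

## Numerical choices and degenerate inputs

Chord-length parametrization (not centripetal): markers are roughly
uniformly spaced on real annuli, and the periodic spline through 16 such
points shows no overshoot artifacts.  Arc-length inversion uses an 8×
oversampled grid.  Consecutive markers closer than 1e-6 mm are rejected as
degenerate; a constant difference vector routes nonparametric with
normality p = 0; all-zero paired differences define p = 1; ties in the
minimum-phase search resolve to the earlier phase.  Quantiles use linear
interpolation; SDs use the n−1 denominator.

## Known limitations

* Landmark placement error is the dominant real-world uncertainty and is
  modelled only as isotropic jitter.
* The LA percentage reductions quoted in the source cohort's prose are not
  derivable from its printed summary rows; they are stored in the fixture
  verbatim but never used as recompute targets.
* The printed echo-derived Ea is inconsistent with CT conservation
  (implied FSV 1.39 vs 1.65 mL/kg); the generator enforces conservation,
  so its Ea (~54 mmHg/mL/kg) sits below the printed mean but within 1 SD.
* RVol/RF by biventricular TSV difference assumes strictly isolated MR.
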