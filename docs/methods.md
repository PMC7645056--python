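# Methods

This note records the modelling assumptions, numerical choices and
calibration behind the package, and what the synthetic cohort can and
cannot demonstrate.

## DVH representation and metrics

A DVH is stored either as a cumulative curve (volume receiving at least
each tabulated dose) or as differential bins (edges plus one volume per
bin). All internal resampling uses a 0.1 GyE grid — export binning of
clinical systems varies and is rarely reported, so 0.1 GyE was fixed once
as a conservative default; the NTCP chain is verified to be insensitive to
rebinning between 0.05 and 0.2 GyE (relative effect < 1e-4).

- `Vx` and `Dx%` use piecewise-linear interpolation on the cumulative
  curve; ties on flat segments resolve toward the **higher** dose, so
  `D50%` of a curve pinned at the prescription returns the prescription
  exactly.
- `Dmax` is approximated by the midpoint of the highest occupied
  differential bin. A DVH no longer carries the single hottest voxel, so
  the point maximum of the 3-D dose grid is not recoverable; the bin
  midpoint is the least-biased surrogate and is documented as an
  approximation.
- `Dmean` is the volume-weighted mean of bin midpoints.
- Converting a cumulative curve whose last value is still positive places
  the residual volume in one appended bin of the median bin width; all
  curves produced by this package terminate at zero volume, so this path
  only matters for truncated third-party exports.
- Composite structures (the stomach+duodenum union used for one endpoint)
  require absolute (cc) volumes; the summed curve lives on a shared
  resampled grid. Structures are assumed non-overlapping.
- GyE (proton dose × fixed RBE 1.1) is treated as numerically identical to
  Gy throughout; doses are assumed pre-scaled upstream.

## Radiobiological chain

`EQD2` applies the linear-quadratic conversion per bin with
`d_i = D_i / n_fractions`: each bin's total dose is assumed accumulated
evenly over all fractions of the course. This is the standard and only
self-consistent reading for a uniformly fractionated course; α/β defaults
to 4 Gy for the GI organs. A transformed DVH carries an `eqd2` flag and a
second transformation raises, preventing silent double correction.

`gEUD` evaluates `(Σ vᵢ Dᵢ^(1/n))ⁿ` in a scaled form: the largest bin dose
is factored out so that exponents up to `1/n ≈ 14.3` (stomach bleed,
`n = 0.07`) cannot overflow, and zero-dose bins contribute exactly 0
(`0^(1/n) = 0`). For `n = 1` the expression reduces to the mean dose; as
`n → 0+` it converges to the maximum (verified at `n = 1e-3` to 0.1%).

The probit response `Φ((gEUD − TD50)/(m·TD50))` uses the closed-form error
function (`scipy.special.ndtr`); the defining Gaussian integral is treated
as definitional and cross-checked against quadrature to 1e-10 in the test
suite. The packaged parameter sets are applied in EQD2 space with no
further fractionation adjustment of TD50. Two caveats inherited from the
source literature are deliberately reproduced rather than "fixed": the
stomach parameter sets were fitted to stomach-*wall* DVHs but are applied
to whole-organ curves, and no parameter sets exist for liver, kidneys or
spinal cord, so no NTCP is reported for them.

## Target indices and constraints

`HI = (D2% − D98%)/D50%` and `CN = TV95²/(TV·V95)` with the 95% isodose
defined as 0.95 × prescription (47.88 GyE for 50.4). TV95 and V95 cannot be
derived from per-structure DVHs; the pipeline takes them from the synthetic
generator's ground-truth manifest (or, for real data, an explicit
body-structure DVH). The packaged constraint set covers the GI organs
(stomach/small bowel: Dmax ≤ 54 GyE, V50 ≤ 2%, V45 ≤ 25%; duodenum:
Dmax ≤ 55 GyE, V45 ≤ 33%), kidneys (V18 ≤ 50%, V23 ≤ 30%), liver
(mean ≤ 30 GyE), cord (Dmax ≤ 45 GyE) and the coverage/hotspot rules for
CTV and PTV. A rule whose structure is missing is reported not-evaluable,
never silently passed.

## Synthetic cohort

The generator emulates the *summary statistics* of a 24-patient
pancreatic-cancer planning cohort, not any individual patient:

- **Geometry.** CTV volumes are log-normal (mean 79.9, SD 46.85 cc); the
  PTV adds an independent log-normal margin increment so the PTV matches
  mean 198.06, SD 74.04 cc. PTV–OAR overlap fractions are gamma draws
  matched to means 7.15/5.52/2.76% (stomach/duodenum/small bowel), clipped
  at 25%. Absolute organ volumes are not published; literature-typical
  contoured volumes are used (stomach 200, duodenum 70, small-bowel loops
  180, kidneys 340, liver 1500, cord 35 cc, CV 0.25).
- **GI-OAR curves.** Each cumulative curve is a mixture of
  (i) a high-dose plateau whose fractional volume is the PTV-overlap
  volume divided by the organ volume, falling off logistically around the
  prescription and tapering quadratically to zero at a per-plan truncation
  dose (the near-maximum); (ii) an intermediate shoulder around 33 GyE that
  is **identical across the three plans of a patient** — the 30–45 GyE
  region of such plans differs little between techniques; and (iii) a
  modality-specific low-dose bath, exponential with a short scale, cut off
  above ~32 GyE. The proton archetype has a smaller bath (0.40 vs
  0.52/0.57), a faster bath decay (10.5 vs 13/16 GyE) and a ~2 GyE lower
  truncation dose (50.3 vs 52.4/52.1 GyE) than the photon archetypes.
  These values were fitted analytically to published per-modality cohort
  means of stomach V5…V50 and Dmax.
- **Noise structure.** Each (patient, structure) pair draws a shared
  anatomical factor (bath multiplier, falloff shift, truncation shift)
  applied to all three plans, plus a smaller plan-specific component —
  exactly the block structure a repeated-measures analysis assumes.
  Randomness is counter-based (one stream per patient × structure ×
  plan-slot derived from the global seed), so any subset of the cohort
  regenerates bit-identically.
- **Planner emulation.** After construction, a curve violating the organ's
  dose constraints has its falloff edge pulled down in 0.25 GyE steps until
  compliant, mirroring the constraint-driven trade-off of real planning.
- **Targets.** Target DVHs are Gaussian-tailed around the prescription with
  the median pinned exactly at it (the normalisation rule: 100% of the
  prescription covers 50% of the PTV) and truncated just below 107% of the
  prescription (the hotspot rule). The spread is set from the intended
  homogeneity index (PTV ≈ 0.10–0.12, CTV ≈ 0.04); the ground-truth
  conformity inputs emit a per-plan 95% isodose volume consistent with a
  conformation number near 0.82 for the PTV, which automatically yields
  CTV conformation numbers near 0.35 through the shared isodose volume.

What passing tests on this cohort show: the pipeline's metrics, NTCP chain
and paired statistics behave correctly on data with realistic magnitudes,
block correlation and modality ordering. What they do not show: anything
about real patients — the generator has no spatial anatomy, no organ
motion, no optimizer, and per-patient DVH shapes are stylised mixtures, so
agreement with published *cohort means* is built in by calibration, not
discovered.

## Statistics

The per-metric comparison is a one-way within-subject ANOVA computed from
the sums-of-squares definitions (treatment, subject, residual;
`F = MS_treat/MS_resid` on `(k−1, (k−1)(n−1))` degrees of freedom),
validated against both a brute-force residual computation and an
independent library implementation. Sphericity corrections
(Greenhouse–Geisser) are not applied; with k = 3 highly correlated
modalities the uncorrected test is the convention for this design.
Post-hoc pairwise comparisons are paired t-tests with Bonferroni adjustment
`min(1, 3·p)` — the standard reading of a "Bonferroni post-hoc" on a
within-subject design, and the adjustment reproduces the characteristic
capped `p = 1.0` entries. A zero-variance difference vector yields `p = 1`
with a warning rather than NaN. ΔNTCP is summarised from *per-patient*
photon-minus-proton differences, never as a difference of independently
computed means. Significance is fixed at α = 0.05.

Type-I calibration of the paired test was measured under the null (two
archetypes with identical parameters, independent plan-slot noise): the
rejection rate at α = 0.05 over replicate 12-patient cohorts is 0.053
(2000 replicates), i.e. nominal; the acceptance suite re-checks this at
1000 replicates within ±0.03. Replicate cohorts for this check generate
only the stomach structure to keep the suite fast.

## Problem sizes and runtime

Default analyses use the full 24-patient × 3-modality cohort (72 plans,
~550-point curves, nine structures per plan) and complete in a few seconds.
The statistical-calibration check uses 1000 replicate 12-patient,
single-structure cohorts (~12 s). These sizes were chosen so the whole
suite runs comfortably on one CPU while keeping every estimate's Monte
Carlo error far below the tolerances it is tested against.

## Known limitations

- DVH-level only: no DICOM RT-Dose/RT-Struct parsing, no voxel dose grids,
  no contouring; `Dmax` is a binned approximation.
- Fixed proton RBE 1.1 embedded in the input GyE scale; variable-RBE
  modelling is out of scope.
- NTCP parameter uncertainty ranges are shipped with the point values but
  only the point values enter the pipeline; sensitivity analysis over the
  ranges is left to the user.
- The composite stomach+duodenum structure assumes non-overlapping
  contours.
- The synthetic generator is calibrated to one published cohort's summary
  tables; transferring its archetypes to other sites, prescriptions or
  delivery techniques requires refitting.
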