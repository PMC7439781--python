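# Methods

## Scope and model reduction

`aortamech` analyses the biomechanics of the ascending aortic segment in a
cohort of congenital-heart-disease patients, half of whom show aortic
dilation (grouped by the aortic-diameter Z score).  The published analyses it
mirrors were run as 3D fluid-structure-interaction finite-element models on
patient CT geometries; those geometries are not public, so this package
implements the same physics as a *reduced-order* pipeline that is exactly
solvable and fully testable:

* the vessel is a stack of axisymmetric thick-walled rings (no bending,
  torsion, or non-axisymmetric modes);
* the wall is exactly incompressible, so the inflation of each ring reduces
  to one scalar equilibrium equation;
* blood flow is a quasi-1D mass/momentum balance in the compliant tube,
  coupled to the wall through a tabulated pressure-area law.

The statistics stage, by contrast, is *exact*: the published per-patient
metric values are packaged as fixtures and every group summary and
two-sample p-value is recomputed from them.

## Wall constitutive model

Strain energy (kPa), invariants of the right Cauchy-Green tensor C and the
fiber invariant I4 = n_f . C n_f with a circumferential fiber:

    W = c1 (I1 - 3) + c2 (I2 - 3) + D1 [exp(D2 (I1 - 3)) - 1]
        + K1/K2 { exp[K2 (I4 - 1)^2] - 1 }

Baseline constants (fitted to published human-aorta stress-stretch data,
R^2 = 0.73): c1 = -525.16, c2 = 165.9, D1 = 231.8, K1 = 33.4 kPa;
D2 = 3.5, K2 = 12.6.

Design choices:

* **Exact incompressibility.**  The source model is "nearly incompressible"
  with no bulk modulus stated; enforcing det F = 1 exactly removes that
  unspecified constant and admits the semi-analytic tube solution.  The
  hydrostatic Lagrange pressure is eliminated analytically, leaving the
  stress differences sigma_tt - sigma_rr = lam_t dW/dlam_t and
  sigma_zz - sigma_rr = lam_z dW/dlam_z.
* **"One ratio" stiffness scaling** multiplies only the four
  stress-dimensioned constants (c1, c2, D1, K1).  Scaling the dimensionless
  exponents D2, K2 would change the *shape* of the response, not its
  magnitude, and would break the exact linearity that the calibration
  stage relies on.
* **Negative c1.**  The printed baseline has c1 < 0; the incremental uniaxial
  stiffness can be non-positive somewhere in lambda in [1.0, 1.3] for scaled
  variants.  `check_uniaxial_stability` reports this with a warning, not an
  error, because the printed set is used as given.
* **Uniaxial fitting convention.**  `fit_baseline_params` fits the
  incompressible uniaxial extension along the fiber (circumferential strip,
  lateral stresses zero).  The original specimen protocol is not public, so
  the fit is validated by synthetic parameter recovery only.

## Structural solver

For a ring with reference inner/outer radii A, B and axial stretch lam_z,
incompressibility gives r(R)^2 = a^2 + (R^2 - A^2)/lam_z; radial equilibrium
with zero outer traction reduces to P = \int_a^b (sigma_tt - sigma_rr) dr/r,
solved for the deformed inner radius a with Brent's method (pressure residual
< 1e-8 relative).  Transmural samples sit at 16 Gauss-Legendre nodes in the
*reference* coordinate, so samples of different load states are the same
material points and displacement fields can be differenced state to state.
sigma_rr is reconstructed by integrating inward from the outer surface; the
principal axes coincide with the cylindrical axes, so the maximal principal
stress (stress-P1) at a sample is max(sigma_rr, sigma_tt, sigma_zz).

Defaults: wall thickness 2.0 mm everywhere (patient-specific wall thickness
is not resolvable from the imaging the cohort data are based on); lam_z = 1
(no axial pre-stretch is stated anywhere; exposed as a parameter); tissue
density is carried but unused — the solve is quasi-static, inertia is
dropped.  Whole-vessel summaries average over all rings and transmural
nodes; the lumen volume uses conical-frustum quadrature of the inner radii.
Axial refinement replaces mesh convergence: doubling the ring count changes
mean and max stress-P1 by well under the 2% criterion used for the original
tetrahedral models.

Displacement is reported diastole-to-systole (both configurations inflated
from the same zero-load reference).  Whether the published displacement maps
use the diastolic or the zero-load reference is not stated; this convention
is the conservative reading and is applied uniformly.

## Blood and flow model

Viscosity follows the linear hematocrit/protein formula
mu[cP] = 0.12 hct[%] + 0.17 tpp - 2.07.  Taking the protein term in g/L
(its nominal unit) gives 12-16 cP for normal bloods, inconsistent with the
cohort's printed 2.78-10.01 cP; plugging g/dL values reproduces the printed
range, so g/dL is the default dialect and the unit is an explicit argument.

The inlet pressure is a two-phase analytic aortic waveform (half-sine
systole over 0.35 T, exponential diastolic decay with time constant 0.25 T,
closed to a periodic curve and normalized to [0, 1]) scaled affinely to the
patient's DBP/SBP.  The cardiac period is not stated per patient; default
T = 0.8 s.  The outlet trace is the inlet trace minus a constant calibrated
offset.

Flow solves the staggered-grid system

    C_j dp_j/dt w_j = Q_{j-1} - Q_j ,
    (rho L_k / A_k) dQ_k/dt = p_k - p_{k+1} - 8 pi mu L_k Q_k / A_k^2 ,

with Poiseuille (fully developed) friction and the pressure-area law
tabulated from the structural solver (PCHIP-interpolated per ring).  A
Womersley-corrected friction factor was considered and deliberately left
out: the steady Poiseuille limit is one of the validation oracles, and a
frequency-dependent friction has no faithful time-domain form at this level
of reduction.

**Periodic startup.**  Poiseuille friction damps the tube's wave modes only
at 8 pi mu/(rho A) ~ 0.3 1/s for aortic calibers, so marching from rest
would need tens of cycles to become periodic.  The solver instead
initializes on the periodic orbit of the *linearized* system — a
frequency-domain LCR transmission-line solve per Fourier harmonic (96
harmonics) of the boundary pressures about the cycle-mean state — and then
integrates a small number of nonlinear cycles (LSODA).  In the
friction-dominated regime (offsets of a few mmHg) the returned cycle is
periodic to ~0.03%; in the inertia-dominated regime (offsets of ~0.02 mmHg,
which is what physiologic velocities imply in a 60 mm segment) the residual
ringing settles only slowly and cycle-to-cycle periodicity plateaus around
1-3%, while the cycle-averaged velocities used by calibration are stable to
~1e-4.  This is a known limitation of prescribing both boundary pressures
with pure Poiseuille damping.

Integration tolerance is rtol = 1e-5 for calibration work: coarser
tolerances leave ~1% step-sequence jitter in the cycle-averaged velocity,
which is larger than the calibration's inner tolerance.  The axial grid is
thinned to 5 pressure nodes for the stiff integration (the tube law is
built per ring; thinning keeps endpoints).  Systolic/diastolic "instants"
are the argmax/argmin of the inlet waveform; reported velocities at those
phases are instantaneous values.

## Inverse procedures

All three stages use bracketed root finding (Brent, or bracketed secant
with bisection fallback for the flow stage), converge the root to ~0.1%,
and then re-verify the 5% relative-error contract on the target quantity;
`converged` is never set on a marginal root.  All stages are deterministic.

1. **Preshrink.**  Candidate zero-load radii = imaged diastolic radii
   x (1 - s), wall thickness from wall-area conservation (so forward
   inflation returns the imaged wall exactly).  s starts at 5% and is
   adjusted in [0, 40%] until pressurizing the candidate to DBP reproduces
   the imaged lumen volume.
2. **Material calibration.**  The systolic-diastolic pressure difference is
   applied to the imaged diastolic shape (treated as stress-free for this
   stage, matching the published construction) and the stiffness ratio is
   found on a log grid in [0.05, 50] so the resulting volume matches the
   systolic CT volume.
3. **Outlet calibration.**  p_out(t) = p_in(t) - delta, delta in
   [0, 30 mmHg], so the cycle-averaged inlet velocity matches the Doppler
   measurement.  The velocity-offset map is near-affine, so this costs
   ~4 flow solves.

In the per-patient pipeline the material stage runs *before* preshrink:
both consume the imaged diastolic shape, and running stiffness first lets
the zero-load state be built with the patient-specific wall.

One documented tension in the source protocol: the calibration tolerance is
stated as 5% while the achieved per-patient volume errors are reported as
"less than 8%".  The pipeline enforces 5% and records the achieved error in
every `CalibrationResult`.

## Synthetic cohort

The generator draws two groups of 10 from independent truncated normals
anchored to the reference cohort's printed group summaries (age, height,
weight, SBP, DBP, diameter, Z score).  The dilated-group Z-score SD uses
2.11, the value implied by the printed per-patient Z scores (the printed
summary SD of 1.27 is inconsistent with its own rows).  Hematocrit
(50 +/- 12%) and plasma protein (7.5 +/- 1.5 g/dL) are chosen so the derived
viscosities span the cohort's 2.8-10 cP range.  SBP > DBP + 15 mmHg is
enforced by redrawing the pair.  Field correlations are not modelled (none
are published).

Hidden truth per patient: a tapered zero-load geometry (60 mm length, 13
rings, +/-5% linear taper, mid-diameter = 0.92 x AAD so the diastolic shape
lands near the recorded diameter), a stiffness ratio drawn lognormally
(median 1.15 nondilated, 0.75 dilated — dilated walls softer, consistent
with the elevated stress and displacement the reference cohort shows), and
an outlet offset uniform in [0.008, 0.03] mmHg, which yields Doppler-scale
(100-400 mm/s) cycle-averaged inlet velocities in this reduced model.

Measurements are manufactured by the same forward conventions the
calibration stages invert (diastolic volume from the zero-load inflation;
systolic volume from the diastolic-as-stress-free inflation; Doppler
velocity from the flow solve at the true offset), plus multiplicative
Gaussian noise.  Defaults: 0.5% on volumes, 3% on velocity.  The volume
level is deliberately below the ~4% systolic-diastolic volume change:
the stiffness ratio amplifies volume error by roughly the inverse of that
change (~50x), so percent-level volume noise would make the ratio
unidentifiable; velocity noise passes through to the offset roughly 1:1 and
tolerates the 3% clinical-scale level.  Parameter-recovery checks therefore
run at zero noise; the noisy defaults are the conditions for the
group-level directional analyses.

What passing these tests shows — and does not show: recovery tests prove
the inverse machinery inverts *this* forward model; they cannot certify
accuracy against 3D FSI on real anatomies, non-axisymmetric geometry
effects, or measurement biases that are not multiplicative noise.

## Statistics protocol

Per metric: Shapiro-Wilk per group (Royston, via scipy), Levene's test with
median centering (Brown-Forsythe — this variant, not the mean-centered one,
reproduces the published variance-test values), then a two-sided pooled
Student t-test when Levene's p > 0.05 and Welch otherwise.  Following the
reference protocol, a failed normality test is recorded but does not gate
the t-test; `strict_normality=True` switches such metrics to a two-sided
Mann-Whitney U test.  The categorical sex comparison uses a two-sided
Fisher exact test.  No multiple-testing correction is applied (none is in
the protocol being reproduced).

Known irreproducibilities, recorded rather than patched: the reference
Table's diameter p-value (printed 0.051) is 0.047 under a pooled t-test on
its own per-patient values, and the dilated Z-score SD cell (1.27) is
inconsistent with its rows (2.11).  Both cells are excluded from exact
checks.  A permutation oracle (100k draws) agrees with the Student p-values
to 0.002 on the normally distributed metrics; the two inlet-velocity
metrics with Shapiro-Wilk p < 0.05 deviate up to 0.015 — a genuine
t-versus-permutation difference on non-normal data, bounded in the tests at
its observed level.

## Problem sizes and tolerances

Defaults used by the test suite and the acceptance script: 16 transmural
quadrature nodes; 11-26 axial rings (13 for patient geometries);
5 flow nodes, 2-5 cycles, rtol 1e-5; 20-patient recovery cohort; 5-seed
directional study with 5 patients per group.  Structural root tolerance
1e-8 (pressure residual, relative); calibration contract 5% with roots
converged to ~0.1%.
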