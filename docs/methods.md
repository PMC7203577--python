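# Methods

`amylv` assesses the progression of cardiac amyloidosis between a baseline
and a follow-up scan from model-based markers of left-ventricular (LV)
passive mechanics and shape.  This note records the models, the numerical
choices, and what the synthetic-data tests do and do not establish.

## Passive myocardium model

The myocardium is an incompressible, orthotropic hyperelastic solid with
the Holzapfel–Ogden strain-energy density (kPa, reported relative to the
reference state so that ψ(I) = 0):

    ψ = a/(2b) [exp(b(I₁ − 3)) − 1]
      + Σ_{i=f,s} a_i/(2b_i) [exp(b_i (max(I₄ᵢ, 1) − 1)²) − 1]
      + a_fs/(2b_fs) [exp(b_fs I₈fs²) − 1]

with I₁ = tr C, I₄f = f₀·C f₀, I₄s = s₀·C s₀, I₈fs = f₀·C s₀, C = FᵀF.
The fiber and sheet terms engage only in tension (`max(I₄,1)`): collagen-
reinforced directions carry no compressive load.  The cross term is the
canonical `exp(b_fs I₈²) − 1` form.  All eight constants are strictly
positive; a-type constants are stresses (kPa), b-type are dimensionless
exponents.  Fibers follow the rule-based architecture: helix angle linear
from −60° (epicardium) to +60° (endocardium), sheet angle from −45° to
+45°; sheets are constructed exactly orthogonal to the fibers.

## Geometry and strain pipeline

Scans are represented as co-registered structured hexahedral wall meshes
between an endocardial and an epicardial surface (lengths in cm, volumes in
mL).  Alignment follows the imaging convention: frames translate along the
long axis by `d_t − min(d_i)` toward the annulus, and rotate about the long
axis so the inferior right-ventricular insertion point v₁ matches a
reference angle.  Per-element deformation gradients are least-squares
affine fits to the eight node displacements — exact for affine motions and
independent of node ordering.  Green–Lagrange strains `E_cc = c·E c`,
`E_ll = l·E l` use the reference-frame local triad (circumferential c,
transmural r pointing endo→epi, longitudinal l = r × c).  Regional strains
average elements over 3 short-axis layers × 20 circumferential regions;
the layers are the element rings nearest 25/50/75 % of the long-axis span,
and region 1 starts at v₁, counter-clockwise viewed from base to apex.
Early diastole is the strain reference (not end-diastole).

Cavity volume integrates the endocardial surface capped by the flat basal
polygon (divergence theorem); wall volume sums hexahedral cell volumes with
a globally consistent face triangulation, which makes
`V_wall + V_LV = V(capped epicardium)` exact to round-off.  Wall thickness
is the median over epicardial vertices of the exact distance to the
triangulated endocardial surface.

## Template and synthetic data

The synthetic template is a truncated prolate spheroid: endo and epi
spheroids sharing a flat basal plane (`truncation_fraction` of the
epicardial semi-axis kept above the equator), meshed as rings closed at the
apex by a structured quad cap, so no element collapses at the pole.  Cavity
volumes are analytic, which supplies closed-form test oracles.  With the
default resolution (20 circumferential × 143 longitudinal rings plus the
cap) each surface carries 2,896 vertices — 5,792 for both, a 17,376
dimensional shape vector.  Mechanics and inference use a coarse variant of
the same family (20 × 5 × 3 by default); the default mechanics template is
thick-walled (endo radius 1.9 cm, wall 1.1 cm) so its wall-to-cavity volume
ratio (~2.1) and scaled pressure are in the amyloid range.

Diastolic series are generated by the forward model below under a linear
pressure ramp from 0 to P_ED over 13 frames.  Measurement noise applies to
the *derived observations* (relative SD 2 % on chamber volumes, absolute SD
0.01 on regional strains; frame 0 is the reference and is noise-free), not
to node positions, matching the error model the residual bootstrap assumes.
The default synthetic amyloid stiffness scales a healthy literature-range
parameter set by 8, chosen once so that inflating the default template to
its scaled P_ED fills the cavity by roughly a third — a physiological
diastolic filling fraction.  Shape cohorts draw wall thickness per subject
from a normal around the class median (0.77 cm healthy, 1.11 cm amyloid;
SD 0.08 cm) plus a 4 % global size variation.

What the generator does *not* emulate: real anatomical shape modes,
out-of-plane longitudinal motion of the imaging planes (so synthetic E_ll
is cleaner than image-derived E_ll), segmentation error correlated across
frames, and regional disease heterogeneity (material parameters are
homogeneous).  Passing tests therefore validate the *pipeline*, not
image-analysis robustness.

## Reduced-order forward model

The full finite-element problem is replaced by a Ritz reduced model: wall
deformation is restricted to a smooth 11-parameter kinematic family

    u_xy = [g₀(ℓ) + g₁(ℓ) s + g₂(ℓ) s²]·(x, y),   u_z = ζ(ℓ)·(z − z_b)

(ℓ longitudinal, s transmural with s = 0 on the epicardium; g₀ vanishes at
the base).  This realises the basal conditions exactly: zero long-axis
displacement on the basal plane, prescribed (default zero) in-plane motion
of the epicardial basal edge, remaining basal nodes free in-plane.  The
basis is QR-orthonormalised for conditioning.  Equilibrium at each step of
the pressure ramp minimises the total potential

    Π(q) = Σ_e V_e [ψ(F_e) + κ/2 (J_e − 1)²] − p·V_cavity(q)

with a penalty bulk modulus κ = 1000·a (volume-averaged |J − 1| stays below
0.01 at physiological inflations) and the exact cavity-pressure potential.
The solver is a damped Newton method with finite-difference Hessians of the
analytic gradient, per-step Hessian caching for warm restarts, and an
L-BFGS fallback; internally kPa/cm (1 mmHg = 0.133322 kPa), outputs in
mmHg/mL.  The model is pluggable: anything implementing `solve` with the
same contract can replace it.  Against the thin-shell membrane (Laplace)
limit the inflated volume agrees within 10 %.

The pseudo-uniaxial stress–stretch test stretches a homogeneous
incompressible sample with fibers along the load axis and the sheet along
one transverse axis, solving the transverse stretch for zero transverse
Cauchy stress; the average stiffness marker f̄ is the secant slope of σ(λ)
over λ ∈ [1, λ_max], λ_max = 1.15 by default (the averaging rule is this
package's definition; the stretch range is configurable).

## Pressure scaling and two-step inference

End-diastolic pressure is unobservable non-invasively and is scaled from
geometry: P_ED = P_EDm·(V_wall/V_LV)/(V_wall/V_LV)_m with P_EDm = 19 mmHg
and population mean ratio 2.678 at early diastole.

The misfit is F_VE = F_V + F_E with F_V = w_v Σ_i[(V_i − V̂_i)/V̂_i]² over
frames and F_E = w_E/(n_layer·n_reg) Σ (E_cc − Ê_cc)² over layer × region ×
frame; longitudinal strains are excluded (their image-derived uncertainty
is much larger).  The weights default to w_v = w_E = 1 (neutral; zero-noise
recovery is weight-insensitive).  Step 1 estimates {a, b, a_f, b_f, a_fs}
with {a_s, b_s, b_fs} pinned at healthy-volunteer values (0.5426 kPa,
1.5998, 3.3900), by bounded trust-region least squares in log-parameter
space (bounds a ∈ [0.05, 50] kPa, b ∈ [0.5, 30]) from 5 seeded starts.
Trust-region least squares was chosen over derivative-free search because
the objective is an explicit sum of squares and the trust-region method
reaches the same minima in a fraction of the evaluations; the non-convexity
is handled by the multi-starts.  Step 2 recovers the second group through
the empirical closure regressions

    a_s/a_fs = 1.72·a_f/a_s − 3.65,    b_s/b_fs = −0.43·b_f/b_s + 1.61

parameterised by ξ = b_f/b_s ∈ [1.44, 2.96] (a_s is the positive root of
the induced quadratic), with ξ found by bounded scalar minimisation of F_E
(tolerance 1e−3) plus explicit endpoint checks.  Individual parameters are
not separately identifiable; the estimator's validated target is the
stress–stretch *curve*, which zero-noise synthetic data recovers to well
under 5 % relative RMS.

## Residual bootstrap

Uncertainty comes from a residual bootstrap: volume and strain residuals
are resampled separately with replacement (frame 0, the reference, is never
perturbed), surrogate datasets `prediction + resampled residual` are refit
warm-started from the point estimate plus an optional random restart, and
the parameter draws are propagated to the markers.  Two numerical points:

* **Residual standardisation.**  The nonlinear volume response can
  partially interpolate per-frame volume noise, deflating raw volume
  residuals and making the naive bootstrap over-confident.  Before
  resampling, each pool is rescaled by `max(1, ŝ/rms(r))` where ŝ is a
  second-difference estimate of the per-frame noise taken along the frame
  axis of the residual traces (the fitted response and anything it absorbs
  are smooth in the frame index, so second differences isolate the
  independent noise).  A `standardize=False` flag restores the raw pools.
* Replicates that exhaust the refit budget keep their best-so-far estimate;
  only genuine failures are dropped, and more than 20 % drops is an error.

Interval construction: `bootstrap_interval` reports the draw span (nominal
level (n−1)/(n+1) for n draws) either directly (percentile) or reflected
about the point estimate (basic, the default) — the basic form is the
standard choice when the estimator is biased, since the bootstrap
reproduces its own bias around the estimate.

Marker propagation pairs draw i of the baseline with draw i of the
follow-up; the volume ratio and the two mean strains are data-derived and
contribute zero-width distributions, while W, σ̄₁ and f̄ are recomputed per
draw.  Percent changes are reported as mean (SD); the induced distribution
over better/worse calls gives the recovery-score distribution.

## Markers, score, and shape analysis

Seven markers per scan: V_wall/V_LV (reference frame), mean end-diastolic
E_cc and E_ll over the 3 layers × 20 regions, filling work W = ∫p dV
(trapezoidal, mmHg·mL), mean end-diastolic first principal Cauchy stress
over the three layers' elements, f̄, and the shape-trajectory direction.
Improvement directions: thinner wall, larger strains, less work, lower
stress, shallower σ–λ slope, movement toward the healthy shape group; an
exact zero change conservatively counts as "worse" (never encountered in
practice).  The recovery score is the unweighted fraction of "better" calls
among the seven; scores strictly above 0.5 predict a stable-or-recovery
course.

Shape analysis stacks aligned endo+epi surface coordinates into a subjects
× 17,376 matrix.  PCA (centered SVD) provides modes of variation;
classification uses PCA-reduced scores (smallest component count explaining
≥ 95 % variance, capped at n − 2 to keep the LDA scatter nonsingular)
followed by LDA or an RBF-kernel SVM whose bandwidth follows the median
pairwise-distance heuristic with unit box penalty.  Leave-one-out
cross-validation refits PCA and the classifier inside every fold (no
leakage); amyloid is the positive class for sensitivity/specificity/F1.
Shape trajectories are signed LDA distances from the healthy group
normalised by the healthy-class projection SD, trained with the scored
patient left out; a decreasing distance ("down") is movement toward the
healthy group.  Group thickness differences use Mood's median test (2×2
table against the pooled median, chi-square with continuity correction;
all-identical data returns p = 1).

## Numerical and degenerate-input conventions

* Exponents in the energy are clipped at 80 to keep trial parameter sets
  finite; determinant-negative trial states return a large barrier value.
* Deformation gradients reject rank-deficient elements; volume routines
  reject non-watertight capped surfaces and inverted cells.
* Alignment operations are idempotent; strains vanish identically on rigid
  motions (tested on random rotations).
* All stochastic operations take explicit seeds and record them; repeated
  runs are bit-identical (warm solver caches are reset at the start of each
  fit so optimisation paths cannot leak history into results).
* The apex cap requires the circumferential count divisible by 4; exact
  20-region tiling additionally needs divisibility by 20, otherwise the
  region partition raises on the first empty region.

## Scaled-down test problem sizes

The test suite runs the full machinery at reduced sizes chosen for a
single-CPU desktop: mechanics and inference tests use 20 × 3–5 × 3 element
templates; the zero-noise curve-recovery test uses 7 diastolic frames; the
bootstrap coverage study uses 13 frames (the frame count matters — the
second-difference noise estimate and the residual pools need enough frames
to be meaningful), 15 bootstrap draws per replicate and 50 Monte-Carlo
repetitions; the end-to-end study smoke test runs 2 cases with 10 bootstrap
draws.  The packaged reference-cohort tables are reproduced exactly at full
size (they are just arithmetic).

## Known limitations

* The reduced kinematic family cannot represent non-axisymmetric wall
  motion; regional strain *variation* within a synthetic scan is therefore
  smoother than in images.
* P_ED scaling transfers a population relation to individuals; absolute
  stresses inherit that uncertainty (relative baseline/follow-up changes
  are the intended readout).
* Step-1's pinned second group biases the first-group estimates whenever
  the true second group is far from the healthy values; the two-step
  procedure corrects this only through the closure relations.
* Bootstrap intervals are conditional on the realised dataset; with few
  frames the realised noise of a single series can be atypical and the
  interval correspondingly narrow or wide.
* The pseudo-uniaxial fiber curve is only weakly identified by cavity
  volumes plus circumferential strains: near-equal-misfit parameter sets
  can differ by ~20 % in σ(λ), the estimator inherits a nonlinearity bias,
  and residual-bootstrap intervals under-cover truth-implied curve values
  in scaled-down Monte-Carlo studies (the warm-started refits cannot see
  variability from basin selection between near-equivalent optima).
  Relative baseline-to-follow-up *changes* — the markers' actual readout —
  are far more stable than the absolute curve values.
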