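# Methods

`capsfem` models the soft-tissue envelope of the glenohumeral joint — the
synovial capsule with its embedded glenohumeral ligaments and the labrum —
as a thin hyperelastic membrane, and asks how the strain field of an
external-rotation test changes when the superior labrum detaches from the
glenoid rim (an Isolated Type II SLAP lesion).  This note records the model,
its assumptions, the numerical choices, and the limits of what the synthetic
geometry can show.

## Constitutive models

Each of the five capsule regions (antero-superior capsule, posterior
capsule, anterior and posterior bands of the inferior glenohumeral ligament,
axillary pouch) is an incompressible, isotropic, third-order Yeoh solid,

    W = c1 (I1 - 3) + c2 (I1 - 3)^2 + c3 (I1 - 3)^3,

with regional constants (MPa) and wall thicknesses (mm) bundled in
`capsfem/data/capsule_materials.yaml`.  `c1` is half the small-strain shear
modulus; the negative `c2` with large positive `c3` encodes the toe-then-lock
response of capsular collagen.  The labrum is a 4 mm plane-stress Saint
Venant–Kirchhoff band with E = 45.6 MPa and nu = 0.449 — the literature
treats it as linear elastic without specifying a finite-strain extension, so
the SVK form is our choice of extension.  The Veronda–Westmann model is also
implemented in its standard exponential form

    W = c1 (exp(c2 (I1-3)) - 1) - (c1 c2 / 2)(I2 - 3),

because the regional Yeoh constants originate historically from least-squares
conversion of Veronda–Westmann fits; the source constants are not published,
so the table can only be validated by round-trip self-consistency
(regenerate the uniaxial curve from each row, refit, recover the row — the
`calibrate` subcommand and the acceptance script do exactly this).

Two printed-formula caveats are deliberate:

* The uniaxial invariant and stress expressions circulate in a
  typographically corrupted form ("I1 = λ2 + 2λ", prefactor "(λ2 + 2λ)").
  We implement the only forms consistent with zero stress in the reference
  state: I1 = λ² + 2/λ, I2 = 2λ + 1/λ², and
  σ = 2(λ² − 1/λ)(∂W/∂I1 + (1/λ) ∂W/∂I2).
* The humeral retroversion regression is implemented exactly as printed,
  retroversion = −2.33·BD − 0.1 degrees, giving −28.293° at BD = 12.1 mm.
  The source text quotes −28.89° for the same BD; the −0.6° discrepancy
  (rounding of the regression coefficients, or a different upstream formula)
  is noted and not silently "fixed".

A genuine property of the published axillary-pouch constants
(0.22, −17.4, 111.9): `dW/dI1 = c1 + 2 c2 x + 3 c3 x²` has real roots at
x ≈ 0.0068 and x ≈ 0.097, so the uniaxial Cauchy stress *dips negative* for
stretches ≈ 1.05–1.19 (minimum ≈ −0.59 MPa) before the cubic term
re-stiffens it.  The material is therefore not monotone — and not even
pointwise stable — over part of the working strain range.  We keep the
constants as published; the consequences for the solver are handled
numerically (below) and the non-monotonicity is asserted as a fact in the
test suite rather than papered over.

## Synthetic capsule geometry

No patient geometry is available, so the capsule is emulated as a
triangulated tube of revolution between two rings: the glenoid rim (radius
15 mm) and the humeral insertion (radius 25 mm), 20 mm apart with a 3 mm
outward bulge — plausible adult dimensions, all configurable, never
presented as patient data.  The local frame is +x anterior, +y superior,
+z lateral (right shoulder).  Elements are labelled by the clock hour of
their circumferential position (12 superior, 3 anterior, clockwise for a
right shoulder viewed from lateral; a `handedness` switch mirrors the
anterior axis for left shoulders).  Default angular spans: antero-superior
12–3, AB-IGHL 3–5, axillary pouch 5–7, PB-IGHL 7–9, posterior 9–12 — the
three ligamentous bands share the inferior half, the capsule walls the
superior half; the true angular extents are not quantified anywhere, so
they are configuration, not anatomy.  The first axial element row at the
glenoid edge is the labrum band.  The default resolution is 32 × 8
(512 triangles): fine enough to resolve one-hour lesion sectors and the
five regions, coarse enough that a four-scenario study solves in minutes.

The anatomical-frame utilities reproduce the axis construction used with
patient imaging: an epiphyseal sphere whose center is the rotation center, a
retroversion axis perpendicular to the cartilage junction line in the
mid-sphere transverse plane, and a trans-epicondylar axis rotated from it by
the retroversion angle about the humeral axis.

### External-rotation convention

The humeral axis at 90° abduction is inclined 60° to the glenoid face
normal, tilted superiorly.  On the synthetic tube, a straight-chord analysis
shows that the literal right-handed rotation about that axis *shortens* the
anterior glenoid-to-humerus fibres: the anatomical tightening of the
anterior capsule in abduction–external rotation comes from the capsule
wrapping around the humeral head, a mechanism a tube without head contact
does not possess.  The generator therefore defines external rotation
*functionally*: the positive rotation sense is the one that elongates the
anterior capsule, which is what external rotation does anatomically (the
apprehension position).  This choice was made from the chord analysis at
design time, before any end-to-end statistics were computed.

## Membrane finite-element solver

A total-Lagrangian, constant-strain-triangle membrane: bending and
transverse shear are dropped relative to a shell formulation, a deliberate
modelling deviation justified by the capsule being thin and
tension-dominated under rotation plus inflation.  Per element, the in-plane
Green–Lagrange tensor is computed from the difference of deformed and
reference edge metrics in a reference tangent basis,
E = ½ R⁻ᵀ (G_def − G_ref) R⁻¹ — exactly zero for rigid motion and exactly
objective.  Incompressibility is enforced analytically through the
thickness, λ₃ = 1/(λ₁λ₂), giving the in-plane second Piola–Kirchhoff stress
S = 2 W′(I1) (I − C⁻¹/det C) with I1 = tr C + 1/det C; this is exact for a
membrane and cannot lock.  Internal pressure (0.7 kPa = 7·10⁻⁴ MPa by
default) is a follower load; the optional humeral head is a rigid analytic
sphere with frictionless radial penalty contact (default 10 N/mm per node,
disabled by default — the inflated capsule stands off the head).  The
scapular attachment is realized by fixing the glenoid-ring nodes, the
humeral insertion by prescribing the rigid rotation map of the humeral-ring
nodes — equivalent to bonding onto a fixed scapula and a rigid humerus.

Two discretizations of the pressure load coexist deliberately.  The public
`pressure_load` operation applies the classical lumped rule, p·A·n/3 per
node per triangle.  The solver assembles the *conservative* variant — p
times the gradient of the enclosed volume, f_a = (p/6) x_b × x_c (cyclic) —
which coincides with the lumped rule on every interior node and on closed
surfaces and differs only in how the free-edge pressure force of an open
boundary (the detached lesion edge) is attributed.  The conservative choice
makes the pressure an exact potential, which the globalization below
requires.

Equilibrium per rotation step (default: ten 3° increments to 30°) is found
by damped Newton iteration: dense tangent assembled from central finite
differences of the *analytic* element force vectors (so converged accuracy
is set by the analytic residual, not the tangent), Levenberg-style adaptive
diagonal regularization, and a backtracking line search on the residual
norm.  Convergence requires the free-dof residual to fall below
`tol_rel` (default 10⁻⁶) times the larger of the external-load norm and the
predictor residual norm.  Because the axillary-pouch softening band and
membrane compression make the tangent indefinite, Newton alone can stall;
the solver then minimizes the total potential (strain energy − p·volume +
contact penalty) by L-BFGS — exactly consistent with the residual thanks to
the conservative pressure — and lets Newton polish.  Everything is
deterministic; there is no randomness anywhere in the solver.

Wrinkling (negative minor principal stress) is not specially treated.  Its
practical consequence is that equilibria in compressed zones are non-unique
(wrinkle patterns are mesh-scale), so pointwise properties such as load-path
independence and frame indifference of the *full* solution are only
well-posed — and only asserted — in tension-dominated states (inflation);
objectivity at the element level holds identically everywhere.

### Verification oracles

* Patch test: a flat membrane patch with affine boundary stretch reproduces
  the uniform strain field to 10⁻¹⁰ (the formulation satisfies the patch
  test exactly; the residual tolerance sets the observed deviation).
* Balloon: a thin icosphere (refinement 3) under internal pressure matches
  the closed-form relation p = 4H/(Rλ³)(λ² − λ⁻⁴) W′(I1), I1 = 2λ² + λ⁻⁴,
  to well under 2% in equilibrium stretch (measured: ≈ 0.06%).
* Equibiaxial membrane tension: boundary reactions of a stretched patch
  equal h·σ_biaxial(λ)/λ per unit reference length to 10⁻⁶ relative.

## Lesion model

A Type II SLAP subtype is purely a boundary-condition change: the
glenoid-ring (labrum attachment line) nodes inside a clock sector are no
longer pinned — anterior 12–1, posterior 11–12, combined 11–1 — and every
other condition is identical to the healthy run.  Release is binary per
node; whether the detachment should extend deeper than the attachment line
is unknown, so the released set is the ring nodes by default and
configurable.  An empty sector reproduces the healthy run bit for bit.

A consequence worth stating precisely: under *prescribed rotation* the
equilibrium minimizes the total potential over the admissible displacement
set, and releasing constraints enlarges that set, so the stored strain
energy at 30° *decreases* monotonically with lesion extent (measured on the
default capsule: healthy 11044 > anterior 10722 > combined 10655 N·mm).
Releasing constraints does make the structure more compliant — but under
displacement control that shows up as *lower* energy, not higher.

## Strain statistics

The comparison statistic is the per-element maximum principal in-plane
Green–Lagrange strain (the through-thickness stretch is excluded; which
variant the original ANSYS post-processing reported is unknown, so the
choice is documented here).  Per region, an odd number of samples (default
25) is drawn area-weighted without replacement from the region's elements
with a fixed seed; the same sampled elements are evaluated in both
scenarios.  Healthy and injured samples are compared with a classical
two-group one-way fixed-effects ANOVA (F from the sum-of-squares
decomposition, p from the upper F tail, 5% significance); a descriptive
post-hoc power of the observed effect is reported and never used as a
pass/fail gate.  Elements within two edge-hops of released nodes can be
excluded (default on), because the free lesion edge carries a local strain
artefact that is not representative of the band.

What the synthetic study does and does not show: on the default capsule at
30° external rotation the regional ordering of mean strain is AB-IGHL
(≈ 0.30) > axillary pouch (≈ 0.19) > PB-IGHL (≈ 0.01), and the anterior
lesion leaves the AB-IGHL strain distribution statistically
indistinguishable from healthy (p ≈ 0.98).  Both findings are *qualitative*
reproductions of the patient-model results; the synthetic tube has no
humeral-head wrap, no patient-specific region shapes, no folded inferior
pouch, and a much cleaner symmetry, so absolute strain values and p-values
are geometry-specific and are never asserted against the patient-model
numbers.  The PB-IGHL value in particular is small here because the
posterior side of a straight tube goes slack rather than wrapping taut.

## Reproducibility

All randomness (strain sampling) flows from a single configured seed; the
solver is seedless-deterministic.  A run manifest records the SHA-256 of
the canonical configuration, package and library versions, per-step Newton
iteration counts and residuals, and the final strain energies; re-running a
serialized configuration reproduces reports byte for byte.  Units at every
interface: millimetres, degrees, kPa for pressure (stored internally as
MPa); Table constants in MPa.

## Known limitations

No bending stiffness (no wrinkling regularization, no buckling resistance);
no viscoelasticity, anisotropy, damage, or fibre families; no biceps
tendon; the humeral head enters only as an optional analytic sphere; the
lesion does not propagate; the synthetic geometry is a stand-in, not a
segmentation.  The solver's dense tangent limits practical meshes to a few
thousand nodes, which is ample for the study sizes used here.
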