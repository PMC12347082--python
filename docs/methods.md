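# Methods

## Problem and model

Two digital surgical plans of the same head — a pretreatment plan (T0)
and a presurgical plan (T1) — differ, per osteotomized segment, by a
rigid motion: jaw segments neither scale nor deform between plans, so
the difference is fully described by six degrees of freedom. The
package estimates that motion from three anatomical landmarks per
segment and summarises cohorts of such differences.

The pipeline assumes:

1. **Common frame.** Both plans are expressed in one canonical patient
   frame (+X = patient left, +Y = anterior, +Z = cranial, mm). When the
   inputs are not pre-aligned, a bony reference surface (in the
   clinical workflow, the non-dental maxilla) is registered first and
   the resulting transform is applied to all T0 data. File readers
   enforce a frame tag so data in other conventions cannot enter
   silently.
2. **Rigid segments.** Each segment's three landmarks form a
   non-degenerate triangle that moves rigidly with the segment.
   Landmark indication error is the only non-rigid effect considered,
   and is modelled as isotropic Gaussian noise.

## Segment displacement extraction

The rigid superimposition of the T0 triangle onto the T1 triangle is
the closed-form Kabsch solution on the three ordered vertex pairs
(SVD of the cross-covariance with the sign correction that excludes
reflections). Scaling is deliberately not estimated: it has no clinical
meaning for bone segments, and the rigid solution is exact (zero
residual) on congruent triangles. Ordered correspondence (right,
midline, left vertex) is fixed per segment, so no point matching is
involved.

**Angles.** The rotation is factored as
`R = Rz(yaw) · Rx(pitch) · Ry(roll)`. No standard exists for the Euler
order in this application; this order is fixed, documented, and used
identically by the generator and the decomposition, making
compose→decompose an exact round trip. For the small rotations between
two plans of one patient (a few degrees) the order affects results only
at second order. Positive angles are anti-clockwise about the positive
axis by the right-hand rule; for pitch (about +X = patient left) this
realises "anti-clockwise as seen from the patient's right side". The
convention is validated by round-trip and oracle tests rather than by
anatomical reasoning, since the verbal description alone does not fix
the sign. At gimbal lock (|pitch| = 90°, far outside the clinical
range) yaw and roll are inseparable; the decomposition flags the result
and reports roll = 0 with the whole residual rotation as yaw.

**Translations.** Reported as the displacement of the T0 triangle
centroid under the transform. For a rotating rigid body the reported
translation depends on the anchor point; the centroid is chosen because
it is symmetric in the three landmarks and reproducible. Published
analyses of this kind do not state their anchor, so absolute
translation values are only comparable between tools that share this
choice.

## Surface registration

Landmark-initialized trimmed point-to-point ICP on mesh vertices:
nearest-neighbour correspondences (k-d tree), discarding the largest
`trim_fraction` of squared residuals each iteration (default 0.1), then
a Kabsch update on the kept pairs. The trimmed RMS residual is monotone
non-increasing; iteration stops when the change drops below `tol`
(default 1e-6 mm) or at `max_iter` (default 200). Meshes above 5,000
vertices are uniformly subsampled first. Non-overlapping inputs
(median nearest-neighbour distance above 10× the target's median vertex
spacing) produce a diagnostic failure result rather than an exception,
so a batch run can skip and report such patients.

The clinical workflow registers CBCT volumes by voxel intensity on the
anterior cranial base; that step requires the volumes and is out of
scope here. The landmark initialization plus masked ICP on a bony
reference mesh is this package's surrogate, and the region mask (vertex
index list or bounding box) is its generalization of the "bony
non-dental" matching region, which the original workflow delineates
interactively.

## Cohort statistics

Per segment and parameter: mean, SEM = sd/√n, two-sided one-sample t
against 0 (df = n−1), 95% CI = mean ± t(0.975, n−1)·SEM. The top-10%
value is the 90th empirical percentile of absolute differences with
linear interpolation between order statistics (numpy's `linear`
method), stated here for bit-reproducibility. Out-of-range percentages
count |difference| strictly greater than the tolerance (4° rotations,
2 mm translations by default); a value exactly at the limit is within
range. The tolerance report's "mean rotations"/"mean translations" rows
are arithmetic means of their three parameter rows by construction.
Subgroup contrasts (SARME, maxillary/mandibular extraction) use Welch's
unequal-variance t by default — the analysis convention of R, in which
such studies are typically analysed — with pooled-variance Student as
an option; the CI uses the Welch–Satterthwaite df. Zero-variance
samples are flagged degenerate with p reported as the limit. No
multiple-testing correction is applied; reports record the number of
tests performed. p-values below 0.001 render as "<0.001" in CSVs while
the JSON keeps full precision.

## Synthetic cohorts

The generator emulates a two-timepoint planning study on a fixed
template anatomy (plausible adult landmark coordinates, bilaterally
symmetric about X = 0, plus parametric arch-band meshes with an
asymmetric undulation so ICP has a unique optimum). For each patient
and segment a 6-DOF displacement is drawn componentwise from Gaussians;
the default means equal a published 26-patient cohort's means and the
default SDs are derived from its SEMs (sd = sem·√26), so the default
cohort reproduces that study's effect structure. The displacement is
composed about the segment's T0 centroid in the same Euler order the
pipeline decomposes with, making noiseless generation→measurement exact
to machine precision — the basis of the parameter-recovery tests.
Optional additions: isotropic landmark noise (mm) on T1 landmarks, and
additive covariate shifts per (covariate, segment, parameter).
Covariate flags default to the published composition (15/26 SARME, 4/26
maxillary and 13/26 mandibular extractions, maxillary nested within
mandibular), scaled proportionally for other cohort sizes.

What the generator does **not** emulate: real landmark indication error
is anisotropic and observer-dependent, dental arches deform during
orthodontic preparation (the rigid-segment assumption is exact here by
construction), and registration inputs are clean meshes rather than
segmented CBCT surfaces. Passing recovery tests therefore demonstrates
the correctness of the estimator chain, not the clinical accuracy of
any planning workflow.

**Seeding.** One root seed; patient *i*, segment *j* uses the
`SeedSequence(seed, spawn_key=(1+i, j))` substream and covariate
assignment uses `spawn_key=(0,)`. Cohorts are bitwise reproducible and
patient substreams are independent of cohort size.

## Numerical choices

- Rotation validity: orthonormality and det = +1 within 1e-9,
  enforced on every transform constructed anywhere in the package.
- Degeneracy: a point configuration is collinear when the second
  singular value of its centered coordinates is below 1e-6 mm (for
  3-point sets the third singular value is identically zero, so the
  second is the informative one); triangles additionally require area
  > 1e-6 mm².
- Angles are reported in (−180, 180], with −180 mapped to +180.
- The Kabsch rotation is re-projected onto SO(3) after the sign
  correction to keep the 1e-9 orthonormality invariant under floating
  arithmetic.

## Problem sizes

The validation suites use the cohort size the default generator
emulates (n = 26): noiseless recovery on all 18 segment-parameters,
noisy recovery bias over 1,000 replicate cohorts at 0.2 mm landmark
noise, type-I error of the one-sample test over 10,000 null replicates,
Kabsch optimality against 10,000 random candidate transforms, and ICP
recovery on the ~800-vertex template maxilla mesh with 20% outliers.

## Known limitations

- Translation values depend on the centroid anchor choice (above).
- The Euler order is a convention; tools using a different
  factorisation will disagree at second order for large rotations.
- ICP is point-to-point on vertices; very coarse or topologically
  broken meshes should be cleaned upstream.
- Subgroup CIs assume independent groups; patients carrying several
  covariates are not modelled jointly (no interaction terms).
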