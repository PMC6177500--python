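# Methods

This note documents the models, algorithms, default parameters and
numerical choices behind `wallmap`, and what the synthetic verification
battery does and does not establish about real data.

## Synthetic cohort generator

**Geometry.** Each subject is a carotid-like bifurcation: a CCA trunk
splitting into ICA and ECA daughter branches, each a straight axis
segment with a linearly tapering radius. The lumen surface is the zero
level set of the union of the branch signed-distance fields,
triangulated by marching cubes at a configurable pitch (default 0.7 mm,
≈1500–2500 vertices). Nominal junction-end radii are 3.0 / 2.4 / 2.0 mm
(CCA / ICA / ECA), daughter angles +25° / −35° from the CCA axis,
lengths 15 / 12 / 10 mm, tapers 10% / 18% / 12% towards the free ends.
Per-subject variability multiplies radii and angles by independent
`1 + N(0, σ_g)` draws (default σ_g = 0.1), clipped at 2σ so no subject's
geometry degenerates. Branch labels (CCA/ICA/ECA/bifurcation) and
cap-disk flags are carried per vertex; the saddle within 1.5 × the
largest radius of the junction is labelled "bifurcation".

**Flow.** Steady (non-gated, time-averaged) flow only. Axial velocity
follows the parabolic profile `v = v_peak(s)·(1 − ρ²/R(s)²)` per
branch; volume-flow conservation sets the peaks: the CCA junction peak
is the configured `peak_velocity` (default 60 cm/s, the venc-like
scale), daughters receive a 65/35 ICA/ECA flow split, and along a
tapering branch `v_peak(s) ∝ R(s)⁻²`. Where branches overlap near the
junction the fields are blended by the smooth partition of unity
`w_b = max(0, 1 − ρ/R)`; exactness is claimed only on single-branch
segments. Taper plus flow conservation matters statistically: with
constant per-branch peaks, `WSS·D = 4μ·v_peak` is constant and the
interaction term of the wall model becomes collinear with the
intercept; tapering makes WSS ∝ R⁻³, D ∝ R and WSS·D ∝ R⁻² vary
independently, so all four coefficients are identifiable.

**Ground-truth maps.** WSS is the Poiseuille closed form
`2μ·v_peak(s)/R(s)` of the nearest branch (μ default 3.2×10⁻³ Pa·s, a
standard blood-viscosity constant; the value used is recorded in all
outputs). D is twice the distance to the nearest branch axis. WT is
the linear model `β0 + β1·WSS + β2·D + β3·WSS·D + ε` with i.i.d.
Gaussian vertex noise ε (default SD 0.2 mm; optional spatial smoothing
of the noise field by neighbour averaging), clipped at a 0.1 mm
physical floor. Default β = (1.0 mm, −0.15 mm/Pa, 0.05, 0.01 mm/(Pa·mm)),
chosen once to keep WT in a realistic 0.3–1.9 mm band over the WSS
range the geometry produces (≈1–5 Pa) with a net negative WSS effect
(`∂WT/∂WSS = β1 + β3·D < 0` at all diameters present). The noise
distribution is an assumption (the ε distribution is not constrained by
anything upstream) and is exposed in the configuration.

**Outer wall.** The outer wall is extracted as the level set
`dist_to_lumen(p) = WT(p)` by marching cubes, not by offsetting lumen
vertices along normals: vertex offsetting makes the daughter branches'
outer sheets cross in the bifurcation crotch, whereas the level set
merges them there — the physical picture of a shared adventitia — and
guarantees the lumen is strictly enclosed wherever WT > 0. Vertex noise
is carried onto the level set by inverse-distance weighting of the four
nearest lumen vertices. The surface-extraction floor is
`max(0.1 mm, 0.5 × grid pitch)` so the discretised level set cannot
cross the lumen; the truth WT map keeps the plain 0.1 mm floor.
Consequence: lumen-vertex-to-outer-wall distance equals the truth WT to
within 2% + one edge length on all non-bifurcation vertices, while in
the crotch merge zone the geometric distance legitimately exceeds the
model WT (the wall "fills" the saddle). Tests assert the invariant on
non-bifurcation vertices and a >95% overall fraction.

**Velocity volumes.** Evaluated at voxel centres on a regular grid
(default 0.45 mm isotropic — finer than a clinical protocol, chosen so
at least three samples fit along the smallest jittered daughter radius),
with optional constant background offset per component (emulating
uncorrected phase offsets) and i.i.d. Gaussian noise. No partial-volume
averaging, phase wrapping or pulsatility is modelled.

**Randomness.** One master seed; `numpy.random.SeedSequence` is spawned
per subject, and each subject's sequence into (geometry, wall-noise,
velocity-noise) streams, in that order. Identical configuration + seed
reproduce cohorts bit-for-bit.

## Map extraction

**Wall thickness** is the exact point-to-triangle distance from each
lumen vertex to the outer surface (resolution-independent, unlike
point-to-vertex). Distances use an owned vectorised closest-point
routine with k-d-tree candidate pruning (24 nearest triangle
centroids — exhaustive in practice on the near-uniform meshes used
here) and an angle-weighted pseudo-normal inside/outside test; lumen
vertices found outside the outer surface raise an error listing the
offending vertices.

**Centerline.** Cross-section centroid chaining: branch vertices
(by label) are binned along the branch's principal axis (bin width
max(2 × mean edge, 1 mm)); end nodes within ~one tube radius are
dropped (their bins cut truncated or oblique rings); three passes of
slab re-collection perpendicular to the evolving tangent relax the
interior onto the centerline; light 1-2-1 smoothing suppresses
centroid noise; and the dropped extent is restored by continuing the
best-fit local circular arc (Kasa fit in the segment's own plane, with
a straight-line fallback), since vessel centerlines are locally
arc-like. Daughter paths are prepended with the CCA path and the
junction point, so both outlet paths share the trajectory through the
bifurcation. The inscribed radius at each node is its distance to the
wall, measured against the surface with cap-disk faces removed (caps
are artificial closures, not wall); nodes nudged outside the closed
surface by extrapolation are dropped, and the computation fails if more
than 20% of a path falls outside. On analytic cylinders the centerline
lies on the axis to < 0.01 mm with radii within 1%; on a 70° torus
segment radii are constant within 5%.

**Diameter** is twice the distance to the nearest point of the densely
resampled (0.25 mm) centerline paths, nearest over all branches; exact
ties resolve to the first path in sorted branch-name order.

## WSS estimation

Per vertex: the local radius r = D/2 from the diameter map; velocities
interpolated at distances {0, r/2, r} along the inward normal ("three
equidistant points spanning one radius", the wall point included);
each sample rotated into a local wall frame whose primary in-plane axis
is the innermost sample's velocity projected onto the tangent plane
(secondary axis by cross product) — this separates the wall-normal
component from the two in-plane components without reference to any
scanner frame. A smoothing spline (default smoothing 0; with three
points this is the unique interpolating quadratic, whose wall
derivative has the closed Lagrange weights (−3/r, 4/r, −1/r)) is
fitted per in-plane component; the gradient magnitude converts as
1 (cm/s)/mm = 10 s⁻¹, and WSS = μ × gradient. Vertices whose samples
leave the volume, or on cap disks, are excluded and carry NaN through
all downstream statistics.

Image interpolation defaults to cubic B-splines; trilinear
interpolation is available (`interp_order=1`) but leaves a substantially
larger partial-volume bias at the wall sample (median WSS error ~17% vs
~6% at R = 2 mm with 0.5 mm voxels). The derivative is taken from the
spline at the wall (not a finite difference of the first two samples).
Background phase offsets are corrected by subtracting the mean velocity
over a static-tissue mask (voxels ≥1.5 mm outside the lumen by
default).

On analytic Poiseuille cylinders (v_peak = 60 cm/s, 0.45 mm voxels) the
median relative error against `2μ·v_peak/R` is ≈6% / 5% / 3% at
R = 2 / 3 / 4 mm. The residual bias is the wall sample's partial-volume
contamination, inherent to sampling at the no-slip boundary of a
discrete image.

## Cohort atlas

The shared geometry is the first subject's lumen mesh; every other
subject is rigidly aligned to it (translation of the bifurcation
landmark — the centroid of bifurcation-labelled vertices — plus
rotation of the CCA/ICA branch-direction frame, refined by
point-to-point ICP on an 800-vertex subsample), and correspondences are
nearest aligned vertices within a gate of 2 × the atlas mean edge
length (weight 1; barycentric projection is a known upgrade path).
Gated-out atlas vertices are missing for that subject. Averaging over a
subject multiset (with repetition, as the bootstrap requires) is
vertex-wise and available-case, with the contributing count recorded;
all downstream statistics use "complete" vertices covered by every
subject. A registered-first-subject atlas rather than a mean shape is a
deliberate simplification: any common vertex set supports the
resample-then-average contract, and the choice is isolated behind the
`SharedGeometry` interface.

## Statistics

Spearman's ρ uses mid-ranks (ties are common in quantised maps) and is
undefined (NaN, with a warning) for constant inputs. The per-subject
test Fisher-z-transforms the ρ values and applies a two-sided
one-sample t-test against 0; reported means/SDs are on the raw ρ scale.
The bootstrap draws B subject multisets once per seed
(`bootstrap_multisets`), so correlation and regression bootstraps run
with the same seed share their resampling exactly. CIs are percentile
(2.5th–97.5th); significance is 0 outside the CI. The linearity check
is a lack-of-fit F-test of the simple linear fit against decile-binned
means at α = 0.05 (the exact method is a free choice, isolated behind
one function).

**Null calibration.** The false-positive-rate experiment gives the
population mean WT and WSS maps fixed spatial patterns in quadrature
(sample ρ between them ≈ −5×10⁻⁴) plus independent per-subject vertex
noise: true ρ = 0, and the between-subject noise the bootstrap
resamples is exactly what makes the observed cohort-averaged ρ
fluctuate. Measured firing rate ≈7% (nominal 5%). Under a structureless
null (mean maps constant, maps pure noise) the procedure is instead
strongly conservative — the flag essentially never fires — because the
bootstrap spread exceeds the null sampling spread of ρ; both behaviours
are properties of the subject-resampling bootstrap itself, not of this
implementation.

## Wall-model fits and prediction

OLS with intercept on the requested terms (full: WSS, D, WSS·D;
reduced: single terms), via `numpy.linalg.lstsq` with an explicit rank
check that names the collinear term. Coefficients are always reported
as a 4-slot vector (zeros in inactive slots). Bootstrap regression
ensembles reuse the correlation bootstrap's multisets; note the cohort
regression is intentionally misspecified under averaging (the mean of
`WSS_i·D_i` is not `mean(WSS)·mean(D)`), which is a property of the
method being studied — at the default conditions the across-seed
aggregate of the ensemble mean recovers β0 and β1 to ≈1%, while single
seeds scatter within their (95%-covering) CIs. Predictions are raw
linear values — negatives retained and counted (clipping exists for
display only). Self-fit evaluation uses the subject's native mesh
vertices; cohort-coefficient prediction applies the ensemble mean β to
the subject's native maps (atlas-resampled prediction is also
supported). The top-5% "maximum WT" uses ⌈0.05·n⌉ values, ties by value
then index.

## Verification battery sizes

The test suite and the results-reproduction script run, on one CPU in
minutes: 20 (tests) / 10 (script) independent default-condition cohorts
of 20 subjects at 0.7 mm mesh pitch with B = 1000 bootstraps; 200 null
replications at B = 200 with 20 subjects × 400 vertices; three analytic
cylinders at 0.45 mm voxels; and 200 random rank-formula checks. These
sizes are the package's standing verification conditions and are not
tuned per run.

## What passing does and does not show

The generator emulates the statistical structure the analysis assumes —
a shared linear wall model, independent vertex noise, per-subject
geometric variability, parabolic steady flow — and deliberately omits
pulsatility, phase wrapping, partial-volume averaging, plaque
morphology, lumen-segmentation error and registration error between
velocity and anatomy. Passing therefore establishes correctness of the
estimators and inference machinery under the stated model, and the
qualitative phenomena (noise dilution of individual correlations,
cohort-averaging gain, model ordering); it does not establish accuracy
on clinical MRI, where the omitted effects dominate the error budget.

## Known limitations

* The bifurcation crotch: WSS truth is a per-branch closed form blended
  ad hoc at the junction, and the outer-wall merge makes geometric WT
  exceed the model WT there; bifurcation-labelled vertices are the
  least trustworthy in every map.
* Nearest-vertex atlas correspondence bounds resampling error by the
  mesh resolution; fine-scale map structure below the gate distance is
  not preserved.
* The centerline is a centroid-chaining approximation, accurate for
  tubular, moderately curved branches; it is not a medial axis and will
  not follow highly eccentric or aneurysmal cross-sections.
* Percentile bootstrap CIs with 20 subjects undercover slightly in hard
  regimes; coverage ≈95% was measured at the default conditions only.
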