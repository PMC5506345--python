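# Methods

`retfshape` analyzes peri-papillary retinal layer morphometry point-wise
across a cohort of eyes.  Each eye contributes, per layer (retinal nerve
fiber layer, RNFL; choroid), a *functional shape* — a triangulated surface
`X` (the layer's anterior boundary) carrying a scalar field `f` (layer
thickness in mm).  All eyes are registered into a common mean template, on
whose vertices every eye's thickness is indexed, so group differences,
covariate trends and per-eye deviations can be computed at every point
rather than only as sector averages.

## Spatial reference: the BMO ellipse

The Bruch's membrane opening (BMO) is the anatomical anchor.  Its best-fit
3D ellipse is computed from delineated BMO points (80 by default, matching
radial manual delineation) by (i) a PCA plane fit of the centered points,
(ii) a direct ellipse-specific least-squares conic fit in that plane
(`skimage.measure.EllipseModel`), (iii) lifting back to 3D.  A nonlinear
geometric-distance fit (`geometric_ellipse_fit`) is available as the slower
reference; on 80-point sets with 10 µm isotropic noise the algebraic fit's
mean semi-axis error is statistically indistinguishable from it
(ratio ≈ 1.0, measured by `run_ellipse_study`).

Everything downstream lives in the **canonical right-eye frame**: BMO
centroid at the origin, BMO plane normal along +z (anterior up), ellipse
major axis in the +x half-plane, and left eyes mirrored across the y–z
plane so nasal is +x and superior +y for every eye.  Thickness is the
closest 3D Euclidean distance from each anterior vertex to the posterior
boundary surface (point-to-triangle, exact: KD-tree candidate pruning with
a proven bound, so the result equals the exhaustive minimum).  Surfaces are
cropped to a BMO-distance band, 0.25 mm (inner, where the layer boundary is
ambiguous near the cup) to 2.0 mm (outer, bounded by the field of view);
BMO distance is planar (measured in the BMO plane), which keeps annuli
well-defined on tilted retinas.  A face is kept only if all three vertices
are in band (conservative; avoids boundary slivers).

## Varifold dissimilarity

Fshapes are compared without correspondences through a functional-varifold
kernel metric.  Each face contributes a weighted Dirac at (face center
`c`, unit normal `n`, face-mean signal `g`) with mass = area `a`; the
inner product of two fshapes is

    N(A,B) = Σ_a Σ_b exp(−|c_a−c_b|²/σ_W²) · exp(−(g_a−g_b)²/σ_f²)
             · k_n(n_a,n_b) · a_a a_b

and D²(A,B) = N(A,A) − 2N(A,B) + N(B,B) ≥ 0.  The normal kernel is the
unoriented Binet kernel (n_a·n_b)² by default (insensitive to winding);
an oriented linear kernel is available.  Defaults: σ_W = 0.4 mm (roughly
an annulus width), σ_f = 0.05 mm (the scale of RNFL lobe amplitude).
Gradients with respect to vertex positions and vertex signals are
analytic; the pairwise sums are `numba`-compiled.

## Deformation model and registration energy

Deformations are LDDMM geodesic shoots: initial momenta `p0` attached to
control points (template vertices by default; a configurable stride
subsamples them) generate a Hamiltonian point flow under a Gaussian
reproducing kernel (σ_V = 0.6 mm), integrated by the explicit midpoint rule
(10 steps by default).  Template vertices are transported by the induced
velocity field, and the template signal rides on its vertices, realizing
(f* + ζ)∘φ⁻¹ without interpolation.  The reverse-mode adjoint of the
integrator is hand-coded, so every energy gradient is exact (verified by
central differences to ≤ 1e-5 relative error).

Matching a template (X*, f*) to a target minimizes

    E(p0, ζ) = γ_V · p0ᵀK(X*)p0  +  γ_f · Σ_k A_k ζ_k²  +
               γ_W · D²((φ(X*), f*+ζ), target)

over momenta and the per-vertex functional residual ζ.  The ζ penalty is
area-weighted L², with vertex areas **frozen at the undeformed template**
so the energy is exactly differentiable in all optimized variables; no
smoothness term is imposed on ζ (hook left in config).  Defaults
γ_V = 0.1, γ_f = 20, γ_W = 1: large enough γ_f that residuals stay
interpretable, small enough that they absorb genuine thickness differences.
Two optimizers are provided: block gradient descent with per-block adaptive
step sizes and backtracking (default), and L-BFGS over the packed variables
with the same analytic gradient (used by the heavier cohort analyses; both
are deterministic).  A coarse-to-fine option halves σ_W and σ_V once
mid-run (off by default; energy traces are then monotone only within each
phase).

## Mean template estimation

The cohort template minimizes Σ_i E_i over (X*, f*) and all per-subject
(p0_i, ζ_i) by alternating blocks: (1) warm-started per-subject matches;
(2) a **residual-centering step** f* ← f* + mean_i ζ_i, ζ_i ← ζ_i − mean_i ζ_i,
which leaves every D² unchanged (only f*+ζ_i enters) and strictly lowers
the residual penalty — it removes the translation degeneracy between the
template signal and the residuals and is what drives f* to the cohort mean
(without it, block descent zigzags: at each match optimum the template
gradient equals −2γ_f A ζ̂_i, but a fixed-ζ line search can move only a small
fraction of the way); (3) a few gradient steps on (X*, f*) with
backtracking, preconditioned by inverse vertex area so step sizes are
uniform across the mesh.  Accepted-step total energy is non-increasing by
construction.  The template is initialized from a canonical annulus sized
by the cohort's median BMO semi-axes, with the cohort-mean signal projected
by nearest vertex (a cohort-unbiased alternative to seeding from one
subject).  Fixed-point behavior is exact: a cohort of identical fshapes
leaves the initialization untouched.

Each subject's thickness on template coordinates is t_i = f* + ζ_i.

## Sectorization and statistics

Sectors are BMO-referenced: elliptical annuli at planar distances
(0.25, 0.75, 1.25, outer) crossed with an angular layout about the BMO
center — N, S, I, T spanning 60° centered on the cardinal axes and SN, ST,
IT, IN filling the 30° gaps, half-open intervals, counter-clockwise in the
right-eye enface view, axis-aligned (not rotating with the ellipse's major
axis).  Sector means are unweighted vertex averages by default (area
weighting available).

Point-wise statistics on the vertices × eyes matrix: group mean-difference
maps; two-sample t/p maps (Welch by default, pooled available; raw
point-wise p values, with an optional Benjamini–Hochberg q-map off by
default); per-vertex OLS of thickness on age (mm/year) or visual-field
mean deviation (mm/dB) with r²; and z-score maps
z_k = (x_k − x̄_k^ref)/σ_k^ref using the sample (n−1) standard deviation of
the reference group, on which the within-reference mean-0/sd-1 identity
holds exactly.  Eyes (not subjects) are the unit of analysis; fellow eyes
are included, so inter-eye correlation is uncorrected — a known limitation
of the cross-sectional design.  Column visualizations order vertices by
sector sequence N→SN→S→ST→T→IT→I→IN and by BMO-center distance within a
sector, and eyes by VFMD or age.

## Synthetic cohorts

No real images ship with the package; the generator emulates the
study-relevant structure so recovery can be tested against known truth:

- **Geometry.** Per-eye BMO ellipse (semi-major ≈ 0.90 ± 0.05 mm, axis
  ratio ≈ 0.78) with a mild random plane tilt (4° sd) and a major-axis
  orientation jittered 8° sd about the temporal-nasal axis — after
  axis-based canonical alignment this jitter is exactly the residual
  rotational misalignment the pipeline sees.  Annular surfaces (14 rings ×
  72 angles ≈ 1000 vertices by default) are offset from the ellipse
  boundary along its outward normal, so the BMO distance of ring k is its
  ring parameter by construction; a gentle parabolic dome and per-eye
  random tilt/warp (smooth Gaussian-bump displacement field, 0.08 mm
  amplitude) supply anatomy variation.  Left eyes are generated mirrored.
- **Thickness.** RNFL: base 0.08 mm plus superior/inferior lobes of
  0.10 mm (40° angular width) decaying radially (1 mm e-folding) — the
  hourglass; glaucomatous loss proportional to |VFMD| (0.006 mm/dB at the
  window center), confined to a raised-cosine inferior window (210°–330°)
  and decaying away from BMO (1/mm).  Choroid: base 0.15 mm with a
  ±0.03 mm nasal/superior cosine bias and age-related thinning of
  0.0015 mm/year about a 40-year reference.  These magnitudes are
  physiologically plausible config values, not calibrated to any dataset.
- **Noise.** The posterior boundary position carries a spatially
  correlated Gaussian field (8 µm sd, 0.4 mm correlation length,
  white noise smoothed on the parameter grid) mimicking segmentation
  error; BMO points get 10 µm isotropic noise.
- **Covariates.** Ages N(29.8, 3.6²)/N(57.0, 4.4²)/N(61.7, 7.9²) for the
  young-normal/older-normal/older-glaucoma groups (10/10/18 eyes, two eyes
  per subject); normal VFMD clipped N(−0.5, 0.5²) to [−2, 0] dB and
  glaucoma VFMD uniform on [−15, −2.5] dB, which guarantees every glaucoma
  eye is below every normal eye.
- One master seed spawns per-eye streams, so any single eye is
  reproducible in isolation.

What the generator does *not* emulate: OCT speckle or image formation,
segmentation failures beyond additive boundary noise, axial motion,
vascular structure, or floor effects of severe disease.  Passing recovery
tests therefore demonstrates the pipeline's correctness under plausible
anatomy and noise, not performance on real OCT segmentations.

## Recovery experiments and their sampling behavior

`retfshape.experiments` drives the validation studies (also run by
`scripts/acceptance.py`): varifold-vs-brute-force equivalence, gradient
checks, matching/template fixed points, constant-shift residual recovery
(≈ 0.03% error), end-to-end localization of the imposed glaucoma deficit
(smallest-p vertices of the B-vs-C t-map inside the imposed window; null
A-vs-B map without contiguous significant regions), sector-average deficit
recovery, per-vertex choroidal age-slope recovery (≥ 90% of vertices
within 2 SE), and the ellipse-fit comparison.  Problem sizes are
desk-scale by design: ~1000-vertex meshes, 30-eye cohorts, 5 integration
timesteps, momenta on every 4th vertex, 2 outer template iterations.

The age-slope study uses one eye per subject: fellow eyes share an age, so
with paired eyes the iid per-vertex OLS standard error is slightly
optimistic and 2-SE coverage dips below its nominal level — the same
fellow-eye caveat that applies to the main cohort's maps (eyes, not
subjects, are the unit of analysis there, uncorrected for inter-eye
correlation).  The independent design isolates the estimator the
experiment is meant to validate.

One caveat worth stating: the sector-average deficit comparison estimates a
~20 µm group difference from 10 + 10 eyes whose per-eye sector means carry
coherent anatomical error (warp and axis jitter move the steep hourglass
pattern relative to the sectors), giving the recovery error a sampling sd
around 10–15% of the deficit; individual cohort draws can exceed 25% even
though the estimator is unbiased-to-a-few-percent.  The registration-based
t-map localization is much more stable because it uses the full spatial
pattern rather than one sector's mean.

## Numerical choices and degenerate inputs

- Ellipse fits require ≥ 6 points and non-collinear geometry; non-elliptic
  conic solutions raise with a diagnostic.
- Nearest-point-on-ellipse uses multi-start Newton in the folded first
  quadrant (interior points near an axis have a spurious critical point
  which the multistart avoids); agreement with a dense boundary-sampling
  oracle is ≤ 1e-6 mm.
- Truth fields clamp at a 5 µm floor with a warning; t-tests flag
  zero-variance rows (t=0/p=1 when means agree, ±inf/0 flagged otherwise);
  z-scores flag zero-sd reference rows as NaN.
- Ties: half-open interval conventions for annuli and angular sectors;
  column unravel breaks ties by vertex index; eye ordering by eye id.
- Convergence: relative total-energy change < 1e-5 or the iteration cap;
  a match that hits the cap is returned flagged non-converged.
- Determinism: optimization is deterministic; randomness enters only
  through generator seeds.

## Limitations

Registration quality at desk scale is deliberately modest (strided control
points, few outer iterations): transported thickness is mildly smoothed
toward the template, which attenuates per-eye amplitudes but preserves
spatial localization and correlation structure — adequate for the
group-level maps the package targets.  Real cohorts would need denser
meshes, more iterations, and ideally a GPU kernel backend; the module
boundaries (varifold / shooting / matching / template) were drawn so such a
backend can replace the numba kernels without touching the analysis code.
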