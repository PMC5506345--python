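# retfshape

Point-wise morphometry of peri-papillary retinal layers via
functional-shapes (fshape) registration.

## The problem

Optical coherence tomography (OCT) resolves the retinal nerve fiber layer
(RNFL) — which thins in glaucoma — and the choroid — which thins with age —
at micrometer scale around the optic nerve head.  The conventional analysis
averages layer thickness within a handful of sectors per eye, which is easy
to compare across eyes but blind to spatial detail.  This package
implements the alternative: register every eye's layer surface *together
with its thickness map* into a common template, so thickness can be
compared **at every surface point** across a cohort — group difference and
t-maps, per-vertex regression on age or visual-field mean deviation (VFMD),
and z-score deviation maps — alongside the sector analysis it generalizes.
It is aimed at researchers in ocular imaging who want vertex-wise cohort
statistics from segmented layer surfaces (and, since such cohorts are
rarely shareable, at validating that machinery on synthetic cohorts with
known ground truth).

## The model

Each eye contributes an fshape (X, f): a triangulated anterior layer
surface X in the canonical right-eye frame (anchored on the Bruch's
membrane opening — BMO — ellipse; left eyes mirrored) carrying per-vertex
thickness f, the closest 3D distance to the posterior surface.  A cohort
mean template (X*, f*) and per-eye deformations are estimated jointly by
minimizing, over template, momenta p0_i and functional residuals ζ_i,

    Σ_i  γ_V ‖p0_i‖²_{K(X*)}  +  γ_f ‖ζ_i‖²_A  +
         γ_W D²( (φ_i(X*), f* + ζ_i), (X_i, f_i) )

where φ_i is an LDDMM geodesic shoot generated by p0_i and D² is a
functional-varifold dissimilarity (Gaussian kernels on face centers and
face-mean signals, unoriented Binet kernel on normals) that needs no
point correspondences.  After convergence, eye i's thickness on common
coordinates is t_i = f* + ζ_i, and statistics are computed per template
vertex.  See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Generate a synthetic cohort shaped like a three-group study (10 young
normals, 10 older normals, 18 glaucoma eyes; hourglass RNFL, VFMD-scaled
inferior deficit, age-thinned choroid) and run the analyses:

```
python analysis/01_simulate_cohort.py     # meshes + BMO points + table
python analysis/02_sector_analysis.py     # conventional sector averages
python analysis/03_fit_mean_templates.py  # fshape registration (slow)
python analysis/04_pointwise_statistics.py
python analysis/05_zscore_columns.py
python analysis/06_recovery_experiments.py
```

`02` prints where the conventional analysis sees the glaucoma deficit —
the inferior sector, strongest in the innermost annulus, fading outward:

```
largest B-C RNFL sector deficits (mm):
annulus  sector
0        I         0.0227
1        I         0.0162
2        I         0.0118
```

i.e. older-normal minus glaucoma RNFL is ~23 µm in the inner inferior
sector.  `06` checks the pipeline against the generator's ground truth:

```
ellipse fit: mean semi-axis error 1.38 um (0.98x the geometric oracle)
choroid age slope: true -1.50 um/yr, estimated -1.57 um/yr, 2SE coverage 90.0%
sector deficit: true 21.0 um, measured 16.4 um (21.7% error)
constant-shift residual recovery error 0.03%
```

— the BMO ellipse fit matches a nonlinear geometric fit, per-vertex OLS
recovers the imposed choroidal age slope, and a constant thickness offset
between template and target is absorbed into the functional residual
essentially exactly.  `03` registers all 38 eyes per layer (total energy
10.15 → 8.28 for RNFL, 36.07 → 28.40 for choroid over the accepted steps),
and `04` then computes the point-wise maps on the template:

```
RNFL: 21.6% of vertices p<0.01 for B-vs-C; median age slope -0.01 um/yr; median VFMD slope +0.16 um/dB
choroid: 0.4% of vertices p<0.01 for B-vs-C; median age slope -1.38 um/yr; median VFMD slope +0.73 um/dB
```

Glaucoma thins the RNFL over a fifth of the template (the significant
vertices sit in the imposed inferior window) but leaves the choroid
statistically untouched, while the choroid's recovered age slope
(−1.38 µm/yr) tracks the imposed −1.5 µm/yr; the per-vertex VFMD slope is
positive (thickness falls as VFMD becomes more negative).  `05` writes the
multi-subject column plots (vertices ordered N→IN by sector and BMO
distance, eyes ordered by VFMD or age) and their z-score versions.

The same pipeline runs from the shell on any cohort directory:

```
retina-fshape synth --seed 1 --out cohort/
retina-fshape run --config config.json
```

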