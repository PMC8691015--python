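# Methods

This note documents the models and numerical choices behind
`heartatlas`: what each stage computes, what the synthetic cohort does
and does not emulate, and where design decisions were genuinely open.

## Coordinate and unit conventions

Patient frame: +x patient-left, +y anterior, +z cranial; "caudal" is
−z everywhere.  Lengths are mm, volumes cm³, doses Gy.  `GridSpec`
origins name the *center* of voxel (0,0,0), matching the medical-image
convention used by the NRRD I/O.

## Geometry

Structures are closed, outward-oriented triangle meshes.  Volumes and
solid centroids come from the divergence theorem (via trimesh); a mesh
with inconsistent winding is repaired with a warning, a non-watertight
mesh is rejected with its boundary edges listed.

**Voxelization** is a z-column scanline parity fill: a vertical ray
through every voxel-column center collects surface crossings, and a
voxel is inside iff an odd number of crossings lie above its center.
This is the "voxel center inside the closed surface" rule with no
partial-volume weighting — deterministic, and biased at order
(spacing / feature size), which the convergence tests quantify (≲1%
at 1 mm for ~20 mm primitives).  Ray positions carry incommensurate
sub-micron offsets on x and y so exact vertex/edge hits (e.g. the
diagonal of a triangulated quad) cannot be double counted.  Boolean
volumes (intersection, union) are integer voxel counts on a shared
grid, so inclusion–exclusion holds exactly and Dice/Jaccard satisfy
DSC = 2·JSC/(1+JSC) to machine precision.

**Margins** are Euclidean: the inner margin keeps voxels whose distance
transform to the outside exceeds the margin; the outer shell is the
set difference, so shell ∪ core partitions the input voxelwise.  A
margin that erases the whole structure warns rather than errors —
small synthetic hearts can legitimately lose their deep-structures
core.

Point-to-mesh distances (needed to size the pulmonary-valve sphere)
use an exact vectorized closest-point-on-triangle computation rather
than trimesh's proximity module, which needs an R-tree dependency this
package does not require.

## Atlas construction

Valves are analytic meshes: the aortic-valve cone has its base at the
aortic root and spans exactly 30 mm caudally (apex orientation is a
switch, default apex-caudal); the pulmonary-valve sphere radius is the
truncus-to-cone surface distance minus a 2 mm "almost touches" gap
(the source protocol gives no number; 2 mm is configurable).  The cone
base radius defaults to 21 mm so the default cone volume (~13.9 cm³)
matches the surrogate's observed mean size; the anatomical aortic-root
radius (~12 mm) remains a valid parameter choice.

Shell structures are built on an isotropic voxel grid (default 1 mm;
2 mm in routine tests) and converted back to watertight meshes by
marching cubes on the padded mask.  "Below the aortic valve" is
implemented as z below the cone's cranial cap — a reproducible planar
proxy for a visually defined instruction.  The anterior-wall split
uses two orthogonal planes through the heart centroid (anterior = +y
of the centroid, left/right by the left-right axis): the protocol
names the walls but defines their extent only pictorially, so planes
are the simplest reproducible stand-in and the axis is a parameter.

Nesting invariants hold at the mask level by construction: deep ⊂
heart, walls ⊂ myocardium ⊂ heart, myocardium ∩ 1 cm-core = ∅, deep ∩
myocardium = ∅.  Valves are never clipped by the heart; on the dose
grid all structures are clipped to the grid extent (dose is undefined
beyond it).

## Agreement metrics

DSC/JSC come from voxelized volumes on a grid covering both meshes
(default 1 mm; the oracle tests compare against 0.5 mm).  ASD and HD
are computed vertex-to-vertex, symmetrized: d(a→B) is each A-vertex's
distance to the nearest B-vertex, ASD the mean of the two directed
means, HD the maximum of the two directed maxima.  Vertex-to-vertex
distances are tessellation dependent, so both meshes are refined to
≤2 mm edges first; `resample_max_edge=None` disables this (used by the
brute-force oracle tests), and `verbose=True` exposes the two directed
means since the symmetrization convention is itself a choice.
Aggregation over observer pairs and patients is the unweighted mean;
undefined records (a structure missing for one observer) are counted
and excluded, never imputed.

## Dosimetry

The cumulative DVH is evaluated at every 10 cGy edge from 0; its value
is voxel volume × count of masked voxels at or above the edge.  DMEAN
is the plain mean over masked voxels (equal voxel volumes make this
volume-weighted).  D2CC reads the 2 cm³ crossing off the DVH by linear
interpolation between edges (a bin-floor variant is a flag, since the
choice is not dictated); structures smaller than 2 cm³ return their
minimum dose with a `volume<2cc` flag instead of erroring — synthetic
valves can drop below 2 cm³.  V5GY is volume-at-or-above 5 Gy divided
by total volume.  Dose is sampled at voxel centers with no intra-voxel
interpolation.

## Variability statistics

**Log-normal CV.**  log(value) = cell mean (one fixed effect per
structure×patient cell) + N(0, σ²ₛ).  With flat priors on the cell
means and an inverse-gamma IG(a=b=0.001) prior on σ²ₛ, the marginal
posterior is IG(a + df/2, b + SS/2) with df = n − #cells and SS the
residual sum of squares about cell means on the log scale.  CV =
√(exp(σ²)−1) is monotone in σ², so the posterior median and the
2.5/97.5% quantiles map directly to the point estimate and an exact
95% credible interval — conjugacy gives the credible-interval
semantics without an MCMC dependency.  Singleton cells are dropped
with a warning.

**Beta SD for V5GY.**  Per structure, a beta regression with
logit-linked cell means and one log-linked precision φ (statsmodels
`BetaModel`).  The reported SD is √(μ̄(1−μ̄)/(1+φ)) with μ̄ the
structure-level average of cell means — the protocol wording leaves
the level of μ ambiguous, and the structure-level average is the
quantity the summary tables report.  Because the saturated cell means
consume p of n degrees of freedom, the ML precision is biased upward
at 6 observers per cell; the estimator applies the df correction
(1+φ̂)·(n−p)/n − 1, which simulation shows is nearly unbiased (raw MLE
≈ 18.8 vs truth 15 at the 16×6 design; corrected ≈ 15.5).  Intervals
are percentile bootstrap over seeded parametric resamples (B = 1000
default; 200 in routine tests), refit with warm starts; measured
coverage at the study design is ≈ 0.93.  Values exactly 0 or 1 inside
an otherwise informative structure are squeezed by (y·(N−1)+0.5)/N; a
structure whose values are *all* 0 (or all 1) is flagged
"not calculated" — no variability model is identifiable for a
structure that is never exposed.

**ICC(2,1).**  Two-way random effects, absolute agreement, single
rater: (MSR − MSE)/(MSR + (k−1)MSE + k(MSC − MSE)/n) from the
patients×observers ANOVA, with the standard F-based confidence
interval (Satterthwaite df).  The implementation agrees with pingouin
digit for digit.  Two caveats are documented rather than hidden:
the interval is a *confidence* interval even where the summary tables
say "credible" (a Bayesian ICC is out of scope), and the standard
construction is approximate — its true coverage at 6 observers is
about 0.94 at n=16 but degrades toward 0.90 at n=100 and below as n
grows, because the observer component has only k−1 = 5 df.  Patients
with incomplete observer sets are dropped; more than 10% missing cells
is an error (no imputation).

## Synthetic cohort

The generator emulates the validation study's *statistical* structure,
not cardiac anatomy:

* **Truth anatomy** — per patient, an ellipsoid (axis ratios ~1 :
  0.85 : 1.15 with small random variation) with a smooth low-order
  radial perturbation (spherical harmonics, l ≤ 2, 2 mm scale),
  rescaled to a volume drawn uniformly from 550–850 cm³.  The aortic
  root sits 5 mm caudal of the cranial pole; the truncus point 25.1 mm
  anterior-left of it, placed so the default pulmonary valve comes out
  near 8 cm³.
* **Observer model** — zero-mean smooth radial deformation (real
  spherical-harmonic basis, l ≤ 3, coefficients scaled so the
  pointwise field sd equals `observer_sd`, default 2.5 mm); cranial
  and caudal extents independently shifted ~N(0, (t/2)²) and quantized
  to the t-mm CT slice planes; landmarks jittered per axis (aortic
  root sd 3.5 mm, truncus sd 5.0 mm — the truncus is the less visible
  anchor); and per-observer execution jitter of the geometric rules
  (cone base radius sd 1.5 mm, shell thickness sd 0.5 mm, deep margin
  sd 1.25 mm), because hand-executing "1 cm layer" or "2 cm margin"
  slice by slice is itself imprecise.  No observer has a systematic
  bias — the study designates no gold standard.  Perturbation scales
  were set from the reported deviation magnitudes and per-structure
  CVs of the validation study design, not fitted to any test.
* **Dose model** — dose(x) = 50 Gy · sigmoid(s/w) + base·exp(min(s,0)/λ)
  with s the signed distance to a field-edge plane whose normal points
  anterior-left (±5° jitter); w = 2.5 mm (a 6 MV-like penumbra),
  base = 1.2 Gy at the edge decaying over λ = 40 mm.  The plane offset
  is bisected per patient so the heart fraction ≥ 5 Gy hits a target
  drawn uniformly from 5–22%, giving realistic between-patient DMEAN
  variance (a fixed target would drive all dose ICCs to ~0).  Grid:
  2.5 mm spacing, heart bounds + 30 mm.
* **Seeding** — every draw comes from
  `SeedSequence([master_seed, purpose, patient, observer])`, so
  regeneration is byte-identical and independent of execution order.

What the generator does *not* emulate: real cardiac shape (no atria,
vessels, septum), CT appearance, per-observer systematic style, motion
or positioning error, and clinical beam models (the dose is a
plane-plus-penumbra surrogate, so the hottest heart voxels saturate
near the prescription, unlike measured D2CC values that sit in the
penumbra).  Passing tests therefore demonstrate that the *analysis
machinery* is correct and that the qualitative study findings (largest
structure most similar, pulmonary valve least, spatial noise
amplified/attenuated by the margin rules) follow from the stated
perturbation structure — not that real observers behave exactly like
the model.

A known property of the extent-quantization model: with the default
slice-thickness mix it contributes a heart-volume CV floor of roughly
4%, so the calibration loop (`calibrate_observer_sd`, bisection on the
perturbation scale) can dial in CV targets above that floor (tests use
5% and 10%) but not, say, 2%.

## Problem sizes in routine runs

Tests and the acceptance script run atlas construction and agreement
analysis on 2 mm isotropic grids with B = 200 bootstrap resamples and
the full 16 × 6 design; the package defaults are 1 mm and B = 1000.
At 2 mm, primitive-volume discretization error is ≈ 0.5–1%, an order
of magnitude below the ~5–20% effects under study.

## Known limitations

* Vertex-to-vertex ASD/HD slightly overestimates true surface
  distances at coarse tessellation; the ≤2 mm resampling bounds this
  at ~0.1 mm for heart-sized structures.
* D2CC from a 10 cGy binned DVH is exact only up to one bin; the
  interpolation/bin-floor choice matters at that scale.
* The beta-model bootstrap assumes the fitted model generates the
  data; mis-specified V5GY distributions (e.g. point masses at 0 from
  structures straddling the field edge) widen its true error.
* The F-based ICC interval undercovers when the rater component is
  both non-negligible and estimated from few raters (see above);
  treat its lower bound as optimistic at large n.
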