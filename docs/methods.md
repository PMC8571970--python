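# Methods

This note documents the models and procedures implemented in `toothkit`,
the parameters that matter, the numerical conventions, and what the
synthetic data can and cannot tell you about real tooth scans.

## Orientation conventions

Every mesh in the package follows one contract: **+Z is the occlusal
(apex) direction** and the XY plane is the horizontal reference. Compass
azimuth is measured from +Y (north) clockwise, so +X is east. Vertex
indices are 0-based internally; OBJ's 1-based indices are converted at
the file boundary. Supported formats are ASCII PLY, binary
little-endian PLY, and ASCII OBJ, triangles only. Winding is repaired to
a globally consistent, outward orientation at load; non-orientable
surfaces are rejected. One known limitation: a quadrilateral face inside
a *binary* PLY is triangulated by the parsing engine rather than
rejected — the strict triangles-only check covers the ASCII formats,
which are also the only formats the package writes.

## Standardization

Tooth size, scanner resolution and mesh density all inflate
orientation-patch counts, so every crown is normalized before
measurement:

1. quadric edge-collapse decimation to `first_target_faces`
   (default **10,000**, tolerance ±1 face); skipped with a warning when
   the input is already smaller;
2. `smooth_steps` (default **3**) uniform Laplacian smoothing steps —
   each step synchronously replaces every vertex by the arithmetic mean
   of its edge-connected neighbours (no cotangent weights, no shrinkage
   compensation);
3. a second decimation to `final_target_faces` (default **1,000**), the
   analysis resolution.

The decimation is Garland–Heckbert plane-quadric edge collapse with
area-weighted face quadrics. Numerical conventions:

- boundary edges carry high-weight constraint planes (weight
  `10³ · bbox_diag²`) so open rims cannot drift;
- the optimal contraction point solves the 3×3 quadric system with a
  relative ridge of `1e-12·tr(A)`; if the system is ill-conditioned the
  midpoint and both endpoints are tried and the cheapest kept;
- collapses that would flip a surviving face normal are rejected;
- the heap tie-break is deterministic — equal quadric error resolves to
  the lowest vertex-index pair — and a collapse that would overshoot
  below `target − tolerance` is skipped, so the final count always lands
  inside the tolerance or the routine raises with the achieved count.
  No randomness exists anywhere in this module; standardization is
  exactly reproducible.

Smoothing leaves isolated vertices unmoved (logged), and the whole
pipeline preserves the bounding-box diagonal to within 10% on all
generated fixtures.

## OPCR

Per rotation trial, each face's outward unit normal is projected into
XY; faces whose horizontal magnitude falls below **1e-9** have no
defined aspect, are labelled UNDEFINED, join no patch, and never connect
patches. Azimuths fall into 45° sectors *centred* on the eight compass
directions (boundaries at 22.5° + k·45°); a boundary azimuth resolves to
the clockwise-later bin via the floor rule. Patches are connected
components of the same-bin face-adjacency graph, where adjacency means
sharing a complete edge — faces touching only at a vertex are not
contiguous. Patches smaller than `min_patch_size` (3 or 5) are
discarded, not merged into neighbours. Trial k adds k·5.625° to all
azimuths — for a rotation about +Z this is mathematically identical to
rotating coordinates, cheaper, and exactly reversible — and the OPCR
value is the mean count over 8 trials. This is the full-3D polygon-mesh
variant of the statistic (the whole crown surface contributes), which is
not numerically comparable to 2.5D digital-elevation-model
implementations. Fine serrations are below the 1,000-face analysis
resolution and are not detected.

Non-manifold edges (shared by >2 faces, common in fossil scans) produce
a logged warning; all face pairs along such an edge are treated as
adjacent so patch contiguity degrades gracefully.

## Synthetic teeth

The generator builds closed crown surfaces on a cylindrical parameter
grid (azimuth × height) with a family-specific cross-section, taper and
feature field, closed by a base fan and an apex cap:

- **peg** — sub-circular elongate cone, rounded tip; no features;
- **spatulate** — broad elliptical cross-section (axis ratio 1:0.45)
  with a convex labial margin and enamel rugosity modelled as 5- and
  3-cycle sinusoidal folds (default amplitude **0.14** length units).
  Finer ripples would fall below the Nyquist limit of the 1,000-face
  analysis resolution (~22 faces around the crown) and vanish in
  standardization, so the folds are deliberately bold and few;
- **cusped** — labiolingually compressed leaf-shaped crown
  (ratio 1:0.35) with 0–10 Gaussian height bumps spaced evenly along the
  mesial–distal margin *in real space* (spacing them in azimuth would
  squeeze the cusps into the compressed sides); bump amplitude
  0.45·crown height, weighted toward the apex;
- **blade** — compressed cone (0.8:0.28) whose axis recurves distally.

Seeded Gaussian radial noise (default sd **0.01** length units)
emulates scan roughness. All randomness flows through explicit
`numpy` generators; generation is bit-reproducible per seed.

Wear is modelled as a planar facet: vertices above the plane are
projected onto it, which preserves connectivity and yields a flat
(vertical-normal, hence UNDEFINED) facet. A plane that misses the mesh
returns the input unchanged with a warning. There is no enamel/dentine
layering and no abrasion simulation.

`make_assemblage` draws balanced taxa over the four families with
±15% jitter on crown proportions, 4–10 cusps for cusped taxa and fold
amplitudes 0.10–0.18 for spatulate taxa. Each taxon receives a synthetic
**replacement interval in days** built from a family base rate
(peg 35, spatulate 62, cusped 96, blade 104 — the scale of published
histological estimates for the corresponding clades) with a monotone
link to the family's complexity-driving parameter plus lognormal noise
(`rate_noise_sd`, default 0.08). The interval in days *increases* with
complexity — simple teeth are replaced after fewer days — so complexity
and interval correlate positively; replacement *frequency* (1/days)
correlates negatively. `rate_link` inverts the construction for
effect-recovery tests. `assemblage_tree` builds the matching
time-calibrated phylogeny: families are monophyletic, arranged
(cusped, (blade, (peg, spatulate))) like their dinosaurian analogues,
with ladder topologies inside families and all tips at 152 Ma.

What passing tests on these fixtures do **not** show: robustness to
scanning artefacts (holes, islands, self-intersections), to segmentation
choices, or to real anatomical variation (serrations, carinae, enamel
texture at sub-millimetre scale). The generator produces closed,
manifold, noise-perturbed ideal crowns; conclusions about real scans
rest on the standardization step removing resolution effects, which the
resolution-insensitivity tests check only for this mesh family.

## Phylogenetics

Trees are rooted with branch lengths in Myr. The packaged fixture tree
covers thirteen Late Jurassic genera (four ornithischians, two
theropods, five diplodocoids, two macronarians) with all tips at 152 Ma
and a root at 235 Ma; its internal-node ages are package conventions,
not reconstructions, and `calibrate_tips` can re-age tips. The
calibration anchor fixes the root age at
`max(current depth) + min(requested tip age)`, which makes an
already-satisfied calibration a no-op, makes all-equal tip ages yield an
ultrametric tree, and raises (naming the tip) when a requested age
predates the tip's parent node.

Brownian covariance entries are shared root-to-MRCA path lengths.
Model transforms: Pagel's λ multiplies off-diagonals (diagonal kept),
with λ allowed above 1 up to the positive-semidefiniteness bound found
by bisection; the Ornstein–Uhlenbeck structure is the stationary
correlation `exp(−α·d_ij)` on patristic distances with unit diagonal,
chosen because it keeps GLS well-posed on ultrametric trees. Trait
simulation draws from the implied multivariate normal via Cholesky with
a `1e-12`-relative jitter. Trees with zero-length terminal branches give
exactly singular covariances; the statistics add a `1e-10`-relative
ridge with a logged warning rather than failing.

## Comparative statistics

- **Pearson**: r with t = r·√((n−2)/(1−r²)) on n−2 df. **Kendall**:
  τ-b, with z from the classical tie-corrected variance of the
  concordance score (the large-sample test R reports for tied data).
- **Blomberg's K**: the observed ratio of raw to GLS mean squared error,
  scaled by its Brownian expectation on the same tree; K=1 under BM.
  Significance permutes tip labels and counts permutations whose GLS
  MSE is at most the observed (observed included in numerator and
  denominator), one-tailed.
- **Pagel's λ (signal)**: ML over [0, λ_max] with profiled mean and σ²;
  endpoint candidates λ∈{0,1} are checked explicitly because the
  bounded optimizer avoids exact endpoints. p from a 1-df
  likelihood-ratio test against λ=0; near-boundary estimates make this
  p conservative.
- **PGLS**: GLS coefficients under σ²·C(model); λ or α estimated by
  profile ML jointly with the coefficients (α optimized on a log grid
  spanning `1e-4/depth̄` to `100/depth̄`). Slope t-test on n−2 df. With an
  identity correlation the estimates equal OLS to 1e-10. A response
  whose GLS residual variance vanishes (e.g. constant y) reports slope
  0, p=1 instead of a 0/0 statistic.
- **Phylogenetic ANOVA (RRPP)**: data whitened by the inverse Cholesky
  factor of C; type-I F compares the effect sum of squares of
  intercept+predictor against the full-model residual; significance
  permutes reduced-model residuals (default 999 iterations in the
  pipeline, 9999 in the analysis drivers), observed arrangement counted.
- **Group tests**: Kruskal–Wallis omnibus, then pairwise permutation t
  (pooled-variance statistic), Mann–Whitney U and two-sample
  Kolmogorov–Smirnov, all two-sided, unadjusted by default (Holm
  available, off by default, matching the reporting convention of
  unadjusted pairwise comparisons). The permutation t switches to exact
  enumeration whenever the number of distinct label assignments does not
  exceed the requested replicate count, so small-sample p-values are
  exact; Monte-Carlo p-values count the observed statistic
  ((1+hits)/(1+B)) and therefore never equal 0.
- **Imputation**: missing replacement rates are filled by explicit
  per-taxon rules — donor-mean (average of named donors' known rates) or
  constant, where a constant rule without a value resolves to **96
  days** for ornithischian recipients (the mean of published rates for
  the clade's relatives). Every imputation is logged; taxa without an
  applicable rule stay missing and are excluded from rate analyses with
  a warning.

## Pipeline

`run_pipeline` executes standardize → OPCR (both thresholds) →
aggregate → impute → per-scope statistics, where the dataset scopes are
the complete assemblage, the saurischian analogues (theropod +
diplodocoid + macronarian) and the sauropod analogues (diplodocoid +
macronarian). Analyses are isolated: one failure records an error row
without aborting the rest, because the mesh stage is expensive and the
statistics are cheap. Outputs (per-tooth CSV, taxon summaries, a flat
JSON/CSV report) embed the seed and config but no wall-clock times, so
a rerun with the same config is byte-identical. The config file is JSON
with documented defaults (`RunConfig`).

## Problem sizes

The test suite and the acceptance script run everything at desk scale:
assemblages of 3–4 taxa per family at generation resolutions of
1,500–4,000 faces (the 10,000-face first decimation stage engages only
for inputs above it and is exercised separately at 12,000 faces),
estimator calibrations on 50-tip simulated trees with 200 replicates,
and type-I calibrations with 1,000 null datasets (600 for the
phylogenetic ANOVA) of 20–30 observations at 199 permutations each.
Null group sizes are 20 and 30: with equal small groups the exact
two-sample KS test is conservative (measured rejection ~0.03 at
α=0.05), while unequal sizes restore near-nominal behaviour. These
sizes are the package's chosen study conditions; larger runs only
tighten the Monte-Carlo error.

## Known limitations

- Quadric decimation is plain Python with numpy kernels; a 40,000-face
  crown standardizes in seconds, but batch processing thousands of
  scans would want a compiled collapser.
- OPCR depends on the analysis resolution by construction; values are
  only comparable at a fixed final face count (1,000 here).
- The λ likelihood-ratio p-value is conservative when λ̂ sits at a
  boundary; the K permutation p uses one specific (MSE-based) tail
  convention.
- Binary PLY quads are triangulated, not rejected (see above).
- The synthetic replacement intervals are constructed, not measured;
  their family bases follow published histological estimates but the
  within-family structure is a modelling convenience.
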