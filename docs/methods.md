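# Methods

This note documents the models, numerical choices and limitations behind
`palatosym`, in the order the pipeline runs.

## Reference planes

**Gingival plane.**  Fitted to the most apical dento-gingival-junction
points (≥3, non-collinear) by total least squares: the plane through the
centroid whose normal is the smallest right singular vector of the centered
cloud.  An interpolating plane would be over-determined for more than three
non-coplanar points; TLS minimises the summed squared orthogonal residuals
and degrades gracefully with landmark noise.  The normal is oriented so the
vault (represented by the raphe midpoint) lies on the positive side; every
downstream half-space convention relies on that orientation.  Collinearity
is declared when the second singular value falls below 1e-9.

**Median palatal plane (MPP).**  Two raphe points under-determine a plane.
The MPP is taken to contain the raphe axis and a vertical hint direction —
by default the gingival normal — making it the sagittal plane through the
raphe perpendicular to the gingival plane.  This matches how a mirror plane
plus its perpendicular reference plane are used in cast-analysis software.
A hint within 1° of the raphe axis is rejected as degenerate.  The
construction is exactly equivariant under rigid motions of its inputs.

## Segmentation

The palate is clipped to the vault side of the gingival plane with exact
triangle splitting (crossing triangles are divided at the plane, new
vertices on it), so the segmented area is continuous in the plane position
— no whole-triangle keep/drop popping.  Clipping is delegated to
`trimesh.Trimesh.slice_plane`; the result is validated (no degenerate
faces, no unreferenced vertices) before analysis.

## Mirroring and registration

Mirroring reflects vertices (`v' = v − 2((v−p)·n)n`) and reverses face
winding so outward normals stay outward — the deviation sign convention
depends on it.  Reflection is an involution; applying it twice restores
coordinates to machine precision.

Registration is two-stage, as in surface-comparison practice:

1. **Plane-frame pre-alignment.**  The orthonormal frame spanned by the MPP
   normal, the (orthogonalised) gingival normal and their cross product is
   rotated onto the fixed model's frame and centroids are aligned.  Always a
   proper rotation; frames whose plane normals are within 5° of parallel are
   rejected.  In the mirror-vs-original case both models share the reference
   planes, so the pre-alignment reduces to a centroid shift.

2. **Point-to-plane ICP ("best-fit").**  Full-vertex, deterministic
   correspondences (closest point on the fixed *surface*, not nearest
   vertex); correspondences farther than 10× the median nearest-neighbour
   spacing of the fixed vertices are rejected.  Each iteration solves the
   linearised point-to-plane least squares for a 6-dof twist and re-maps it
   to a proper rotation via Rodrigues.  The point-to-surface RMS is
   evaluated after every step; a step that raises it is reverted and
   iteration stops, so the RMS history is monotone non-increasing by
   construction.  Convergence: RMS change below 1e-6 mm, at most 100
   iterations.  Random subsampling exists only behind an explicit
   config + seed; by default results are bit-reproducible.

On synthetic palates ICP undoes 5°/2 mm perturbations to ≈1e-14 mm —
the pipeline's registration error is far below the 0.5 mm tolerance band.

## Deviation analysis

The closest-point kernel prunes candidate triangles with two KD-trees: the
distance to the nearest mesh *vertex* bounds the surface distance from
above, and every triangle able to beat that bound must have its centroid
within bound + max centroid-to-vertex radius.  The pruning is therefore
lossless; results equal a brute-force scan over all triangles (asserted
against an independently coded exhaustive oracle in the tests).  Ties on
shared edges/vertices break to the lowest triangle index, keeping runs
deterministic.

Distances are **point-to-surface**, signed by the face normal of the
carrying triangle: positive = reference vertex on the outward-normal side
of the test surface (red), negative = inside (blue).  Point-to-point
distances would inflate deviations wherever the two tessellations disagree.
The deviation is one-directional (reference = original, test = registered
mirror), giving a single percentage per comparison; a symmetric
bidirectional mode that pools both directions is available but off by
default.  All reference vertices enter the statistics; an optional border
band (mm) excludes vertices whose closest point lies near a boundary edge
of the test surface (off by default — no exclusion rule is standard).

**Matching percentage** is the fraction of |d| within tolerance.  The
tolerance is a config value, default **0.5 mm**; 0.3 mm is the other value
in routine display use, and both are exercised in the tests (a tighter band
can only lower the percentage).  The color map is green inside ±τ, grading
linearly to pure red/blue at ±scale-limit (default 2 mm), clamped beyond.

## Arch measurements

ICW/IMW are 3D Euclidean distances between bilateral DGJ midpoints; whether
clinical studies measure them in 3D or projected into an occlusal plane is
rarely stated, so a projected mode (project landmarks onto a supplied plane
first) exists as an option.  Emi-lateral widths are unsigned point-to-plane
distances; laterality comes from landmark names and the declared crossbite
side, not from the sign — reported side gaps are magnitudes.  The
projection inequality `ICW ≥ eICW_L + eICW_R` holds with equality iff the
inter-landmark segment is perpendicular to the MPP.

## Cohort statistics

Long-format table, one value per (subject, group, timepoint, variable,
side).  Paired comparisons use per-subject differences; subjects missing a
pair member are excluded and listed, and on complete data the mean paired
difference equals the difference of cell means identically.  The unpaired
test defaults to pooled-variance Student's t with an automatic, logged
Welch correction when Levene rejects variance equality at α; two-sided
throughout; no multiple-testing correction by default (a Bonferroni option
exists).  Degenerate edges are explicit: zero-variance differences give
t = 0, p = 1 when the mean is zero and an infinite-t "degenerate" flag
otherwise.  ICC uses the ICC(2,1) form — two-way random effects, absolute
agreement, single measures, the standard choice for repeated digital-model
measurements by one or more operators — computed via `pingouin` and checked
against a from-scratch two-way ANOVA mean-squares oracle in the tests.

The report builder emits three tables: bilateral widths by group ×
timepoint with the T1−T0 change, emi-lateral CBS vs nCBS with side-to-side,
inter-timing and between-group tests on the per-subject side gaps, and the
matching-percentage table.  A consistency checker recomputes every reported
difference column from its own summary means and flags cells that disagree
beyond printing precision (half a unit in the last digit) — the bundled
reference tables contain exactly two such cells, which are flagged, logged
and never silently reconciled.

## Synthetic data

**Palate meshes.**  The surface is parameterised on u ∈ [0,1]
(anterior→posterior) × t (cross-arch): `x = R(u)·t`, `y = D·u`,
`z = H(u)·cos(πt/2)`, with arch half-width `R(u) = (W/2)(0.72 + 0.28u)`
(default W = 30 mm, D = 35 mm) and vault height
`H(u) = h(0.5 + 0.5 sin πu)` (default h = 12 mm).  |t| ≤ 1 is the vault;
|t| > 1 continues below z = 0 as a sub-gingival skirt so the gingival plane
genuinely cuts.  Landmarks are placed analytically (raphe points on the
exact midline 10 mm apart, canine/molar DGJ midpoints at the gingival
margin, apical DGJ points along both margins), so every arch width has an
exact stored ground truth, and the vault area is known independently of the
triangulation by quadrature of the first fundamental form.

**Asymmetry** is a lateral shift of the alveolar band (the lowest 5 mm of
the vault plus the skirt) toward the crossbite side: the crossbite wall
moves inward by the amplitude, the contralateral wall outward, fading
quadratically to zero at the top of the band.  This emulates the adaptive
dentoalveolar bending under a functional mandibular shift, localised at the
alveolar-process level while the vault dome stays symmetric.  Mirroring
doubles a lateral offset, so the original-vs-mirror deviation at the band
is 2a projected on the wall normal (measured ≈ 1.6a); the matching
percentage decreases strictly with amplitude.  The triangulation flips its
quad diagonal across the midline so that at amplitude 0 the surface — not
just the vertex set — is exactly its own mirror image; without this the
quad non-planarity (~0.02 mm) masquerades as asymmetry.

What the generator does **not** emulate: rugae, tooth crowns, scan noise
correlation, soft-tissue artefacts, or real biological shape variation.
Passing tests therefore demonstrate correctness of the geometry, the
registration and the statistics under controlled conditions — not clinical
accuracy on scanner data.

**Cohorts.**  Defaults encode a reference cohort of 25 treated and 14
untreated children (the reference summary tables in
`palatosym.synthetic_palate`).  Per variable, (T0, T1) values are
correlated normals (within-subject r = 0.9, a typical one-year tracking
correlation for arch dimensions) with the configured per-timepoint
means/SDs; for sided variables the nCBS value is drawn directly and the CBS
value is nCBS minus an independently drawn side gap with the configured gap
mean and SD, so side-difference statistics are controlled exactly.  Scaling
all SDs to zero yields the degenerate cohort in which every subject carries
the cell means — the worked-example input whose report columns reproduce
the reference differences exactly.  Printed per-timepoint SDs and printed
change-score SDs over-determine a bivariate normal; the generator honours
the per-timepoint SDs and the correlation, so simulated change-score SDs
need not match the reference change-SD columns.

All randomness flows through one seeded `numpy` generator per call; there
is no global state.

## Problem sizes

Synthetic palates default to an 80 × 80 vertex grid (~6400 vertices,
~12500 triangles), which resolves the 5 mm alveolar band with ~15 rows
while keeping a full pipeline run around one second; unit tests use coarser
grids (24–48) where only invariants, not resolution, are at stake.
Simulation-based checks use 4000 replicates for test-size calibration
(Monte-Carlo SE ≈ 0.0035) and n = 10⁴ subjects for parameter recovery.

## Known limitations

* Landmarks are inputs; there is no automatic landmark detection on meshes.
* No longitudinal T0→T1 superimposition on stable anatomy (rugae-based
  growth superimposition) — each model is compared to its own mirror only.
* The matching percentage counts reference vertices ("all surface points"
  read as all vertices), not densely resampled surface points; on very
  irregular tessellations the two can differ.
* ICP convergence is local; the plane-frame pre-alignment is assumed to put
  the models within its basin (true for mirror-vs-original comparisons).
* Statistics assume the parametric gates pass, mirroring the clinical
  workflow; non-parametric fallbacks are not implemented.
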