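# Methods

This note documents the models, conventions and numerical choices behind
`macrowear`, in the order the pipeline runs: geometry, orientation,
measurements, statistics, and the synthetic ground-truth generator that the
validation rests on.

## Geometry substrate

Crowns are triangulated surfaces in mm (`trimesh.Trimesh`). Three primitives
carry everything else:

* **Surface area** — sum of triangle areas (half cross-product magnitude)
  over a face subset.
* **Plane fit** — orthogonal-distance (total) least squares: the normal is
  the smallest principal axis of the weighted covariance of the points,
  computed from the SVD of the sqrt-weight-scaled centred cloud. Orthogonal
  rather than vertical regression is deliberate: the pipeline promises that
  every measured quantity is invariant under rigid motion, and only the
  orthogonal fit is rotation invariant. Collinear input (second singular
  value below 1e-7 of the first) raises rather than returning an arbitrary
  plane. Triangles with area below 1e-12 mm² are dropped at load with a
  warning for the same reason — they destabilise plane fits while carrying
  no measurable area.
* **Exact plane clipping** — for each triangle, the fraction of its area on
  the nonnegative side of a plane has a closed form in the signed vertex
  heights (similar-triangle ratios per sign pattern). This keeps *face
  identity* through the clip, so facet and tissue labels can be tallied
  over the occlusal region; it also makes the conservation identity
  `area(above) + area(below) = area(total)` exact to rounding. Vertices
  exactly on the plane count as above.

**Cross-section area.** The "2D area" of the occlusal surface is the area
enclosed by the plane-intersection contour (the slice footprint), not the
sum of projected triangle areas — the two differ on overhanging geometry and
only the contour definition keeps OR ≥ 1 on height-field crowns. The
enclosed area is computed as the line integral ½∮(x dy − y dx) over the
intersection segments of straddling triangles, each segment oriented by the
surface winding (face normal × plane normal). This avoids chaining segments
into loops entirely: chaining is numerically fragile where intersection
points crowd together (e.g. where a slicing plane grazes a carved planar
facet), whereas the line integral is a plain sum. Nested contours (holes,
basin islands) acquire opposite orientation automatically and subtract. The
mesh must be consistently wound, which loaders and the generator guarantee.
When the surface *touches* the plane without crossing it (a flat region
lying in the plane's closure — the flat-disc limit), the contour is empty
and the footprint falls back to the shapely union of the projected
above-side triangles.

## Orientation and reference planes

The cervical plane is fitted through the user-supplied cervical-line sample
(ordered or not), its normal flipped toward the side holding the majority of
mesh vertices (the crown); an exact tie is an error, not a guess. The rigid
map sending that plane to height zero defines the measurement frame; the
cervical normal is the height axis, and the occlusal plane translates along
it. The central fossa is the deepest point of the occlusal basin:

* a manually supplied point is used verbatim (in workflows of record this
  step is interactive, so the override is first-class and is what all
  ground-truth tests use);
* otherwise cusp apices are detected as 1-ring height maxima above 75% of
  the maximum height, and the fossa is the lowest vertex strictly inside
  the 2D convex hull of the apex projections. A monotone dome has no such
  vertex and raises, asking for the manual point.

The occlusal plane sits `1e-6 · |fossa height|` below the fossa. The offset
is invisible at measurement precision but keeps the deepest vertex strictly
above the plane: a plane passing exactly through a high-valence vertex makes
the intersection contour degenerate. Scaling the offset with the fossa
height keeps all metrics exactly scale invariant.

## Facet measurements

Relative areas divide each facet's absolute area by TWA (all facets
including tip crush). Two channels are independent per face: the facet
label and the tissue flag; a dentine face inside a facet contributes to both
that facet's area and the dentine tally — dentine exposed by wear is worn
surface, and this convention is what makes PDE ≤ PEW a theorem rather than
an observation. Tip crush merges into phase II for the area analysis and
stays separate for inclinations.

Facet inclination fits a plane over every vertex of the facet's triangles,
each vertex weighted by one third of its summed incident facet-triangle
areas — a deterministic, area-faithful analogue of an interactive
best-fit-plane pick — and reports the dihedral angle to the cervical plane
folded to [0°, 90°]. Phase summaries are area-weighted means of the member
facets' angles by default; an unweighted mean is available
(`weighted=False`) since either aggregation is defensible and published
tables do not always say which was used.

PDE counts only dentine above the occlusal plane (dentine below, e.g.
cervical abrasion, is excluded with a warning — the normaliser is the
occlusal area). PEW above 100% raises: it means the label map claims more
worn surface than the occlusal region holds.

## Statistical battery

All tests are nonparametric or permutation-based, reflecting small, heavily
unbalanced museum cohorts. Implementation notes:

* **Arcsine transform** `arcsin(√p)` is applied to area proportions before
  the variance gate (and, by default, before the rank tests, where it is
  order-preserving and hence harmless); unlike the logit it is finite at
  the exact zeros produced by absent facets.
* **Mann–Whitney** uses midranks; the exact two-tailed p comes from the
  full null distribution of U (computed by the standard counting
  recurrence) when the pooled sample is tie-free and `n_x · n_y ≤ 2000`,
  otherwise a normal approximation with tie and continuity corrections.
* **Levene-type variance test**: one-way ANOVA F on `|x − group median|`.
  Two optional refinements, both on by default, follow the robust variant
  used for unbalanced morphometric data: *structural zero removal* (an
  odd-sized group's median is one of its points, so exactly one deviation
  is structurally zero and is removed) and *O'Brien's small-sample factor*
  `sqrt(n_j/(n_j − 1))` multiplying each group's deviations, with `n_j` the
  group size entering the ANOVA. Setting both flags off gives the plain
  Brown–Forsythe test (verified against scipy).
* **Kruskal–Wallis / Dunn**: midranks with the usual tie corrections;
  Dunn's pairwise z statistics share the pooled-rank variance; p-values are
  Benjamini–Hochberg step-up adjusted. (BH is monotone, caps at 1 and never
  lowers a p-value, but it is *not* idempotent — re-adjusting adjusted
  p-values inflates them, so the pipeline adjusts exactly once per family.)
* **PERMANOVA**: one-way pseudo-F from the Gower decomposition —
  `SS_total = Σ_{i<j} d²_ij / n`, `SS_within = Σ_g Σ_{i<j∈g} d²_ij / n_g` —
  with p from label permutations, `p = (b + 1)/(n_perm + 1)`. When the
  number of distinct label arrangements is ≤ 10,000 the null is enumerated
  exactly instead (p = as-extreme fraction, identity included). On
  Euclidean distances of 1-D points the pseudo-F equals the classical
  ANOVA F, which the tests exploit as a closed-form limit check.
* **Dispersion (betadisper)**: principal-coordinates embedding of the
  distance matrix keeping negative-eigenvalue axes as imaginary
  coordinates; distance to the group *centroid* combines the parts as
  `d² = d²_real − d²_imag`, clipped at zero. The permutation F test
  relabels the distances-to-centroid; Tukey HSD runs on the same values.
* **Distance matrices** are complete-case: a specimen missing any
  inclination variable (e.g. no tip-crush facet) is dropped with a log
  record, because pairwise deletion breaks the metric.

Every permutation test takes `n_perm` (default 999) and an explicit seed and
is bit-reproducible. The cohort driver (`WearPatternModel`) encodes the
analysis plan: areas on the 2+3-pooled strata (pooling recovers workable
group sizes at intermediate wear, where compositions are stable), inclinations
per stage (wear strongly shifts angles), OR/PDE/PEW unstratified, a
Mann–Whitney sex track and an across-stage pairwise PERMANOVA within the
reference (largest) group.

## Synthetic ground truth

The generator emulates what the measurements need from a molar scan, not
tooth biology:

* **Crown** — a height field over a disc (radius 7 mm, the scale of a
  gorilla M2): a smooth dome, Gaussian cusps (five by default, arranged as
  two buccal, two lingual and a distal fifth), and a central depression
  whose minimum is the true fossa. The boundary ring is the cervical line
  at exactly height zero. Being a height field, the crown has no overhangs,
  so the contour and projection readings of the 2D area coincide and
  analytic relief oracles exist (flat disc → OR 1; a cone with flank angle
  φ → OR = 1/cos φ; hemisphere → OR 2).
* **Facet carving** — each planned facet is a truncation plane whose normal
  makes the target angle with the height axis, aimed azimuthally at its
  anchor cusp (outward for buccal phase I on the buccal cusps' outer
  flanks, inward for lingual phase I and phase II on inner flanks, a
  near-horizontal cap on the fifth cusp for tip crush — one facet per cusp
  window, so carvings never overwrite each other). Vertices above the plane
  inside the window are projected onto it; faces with all three vertices
  projected are exactly coplanar and take the facet label, so the measured
  inclination recovers the target angle to well under 0.5°. The cutting
  depth is bisected (≤ 60 iterations) until the facet's share of the
  occlusal 3D area is within 2% of target (relative, with a 0.002 absolute
  floor — facet area moves in whole-triangle steps). Dentine is painted as
  the faces nearest the facet centroid summing closest to the requested
  fraction of the facet area; with the default resolution (48 rings, 96
  segments, ≈ 9,000 faces) the face granularity keeps dentine fractions
  within 2 points of target.
* **Wear stages** — staged plans with total worn fractions
  {1: 0.09, 2: 0.15, 3: 0.20, 4: 0.25} and dentine shares
  {0, 0.08, 0.18, 0.35}, monotone by construction. The totals are capped by
  what a single cusp flank can supply before facets coalesce, which also
  mirrors why heavily worn teeth are excluded from facet-level analysis in
  practice.
* **Cohorts** — tabular mode draws phase compositions from Dirichlet
  distributions on the simplex (group mean × concentration), inclinations
  from truncated normals on [0°, 90°], and OR/PDE/PEW from truncated
  normals; the default three-group parameters are set at the published
  scale of gorilla molar cohorts (10/25/77 specimens; mountain gorillas
  phase-II-dominated with the lowest OR, Grauer's with the largest lingual
  phase I, western lowland intermediate with the highest OR). Mesh mode
  materialises each specimen through `generate_crown` + `carve_facets` and
  measures it with the real pipeline.

What the generator does **not** emulate: scanning noise and holes, facet
boundary irregularity, facets that cross cusp boundaries or coalesce,
enamel-thickness geometry, antagonist contact mechanics. Passing tests
therefore demonstrate that the measurement and statistical machinery is
correct on surfaces whose ground truth is known — not that real scans are
free of segmentation or registration problems.

## Simulation sizes and defaults

The validation suite uses: 20 seeded crowns (mixed stages) for ground-truth
recovery; 50 random rigid motions plus two uniform scalings for invariance;
1000 null cohorts of 3 × 15 specimens for type-I calibration of
Kruskal–Wallis, the Levene-type test and PERMANOVA (the latter at
n_perm = 199, whose 1/200 p-granularity is ample to score rejection at
α = 0.05); and 200 cohorts of 3 × 20 for the power check against a 0.10
lingual-phase-I shift at SD 0.05. Analysis runs default to n_perm = 999.

## Known limitations

* Facet label maps are consumed per triangle; facet boundaries that cut
  through triangles must be resolved upstream when labels are produced.
* Automatic fossa detection assumes a basined crown with ≥ 3 cusp apices;
  worn crowns whose deepest point lies on a facet will legitimately place
  the occlusal plane lower than an anatomist might — the manual fossa
  override exists precisely for this.
* The Levene-variant algebra (zero removal, O'Brien factor) is documented
  here as this package's definition; published descriptions of the combined
  procedure are informal and implementations differ in details.
* PERMANOVA is one-way only; no crossed or nested designs.
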