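# Methods

This note documents the models, numerical choices, and limitations of
`longicortex` at the level a maintainer or reviewer needs to interpret its
outputs.

## Surface representation and geometry kernels

Surfaces are closed triangle meshes `{V, F}` in world millimetres with
counter-clockwise faces and outward normals; all voxel↔world bookkeeping is
confined to the volume container's 4×4 affine (voxel centres at integer
indices). A longitudinal sequence shares one face array bitwise, so vertex
row `v` is the same anatomical point at every visit — the package's central
invariant, enforced by construction (deformation never touches connectivity)
and checked by fingerprints when checkpoints and templates are combined.

* **Vertex normals** are area-weighted averages of incident face normals;
  zero-area faces are skipped with a warning.
* **Discrete mean curvature** uses the cotangent Laplace–Beltrami operator
  with Meyer mixed-Voronoi vertex areas: `κ(v) = ½‖Δ x(v)‖`, signed positive
  where the surface bends away from the outward normal (a sphere of radius
  `r` gets `+1/r`). The choice of estimator is implementation-defined; the
  curvature-variance metric uses `|κ|`, so it is invariant to the sign
  convention, and the suite verifies first-order convergence of the estimator
  under sphere refinement. Boundary vertices of non-closed meshes are set to
  0 and flagged.
* **Surface sampling** picks faces proportional to area and barycentric
  coordinates uniform on the simplex (square-root construction), seeded.
* **Point-to-surface distance** is the exact closest-feature point–triangle
  distance, accelerated by a kd-tree on face centroids with a conservatively
  pruned candidate set — the result is identical (bitwise) to the brute-force
  minimum over all faces.
* **Self-intersection tests** are exact triangle–triangle interval tests on
  the intersection line of the supporting planes (2-D separating-axis test
  for coplanar pairs), with centroid-radius culling; faces sharing at least
  one vertex are never counted, which avoids false positives at shared edges.
* **Occupancy rasterization** classifies voxel centres by +z ray-crossing
  parity per lattice column, rasterizing each triangle in voxel space; a tiny
  irrational offset keeps lattice points off triangle edges. Labels are
  {background, gray between the surfaces, white inside the inner surface}.

## Deformation model

The flow `f_θ(t, X, V)` is realized as:

* **Image features.** A fixed multi-resolution filter bank: at smoothing
  scales σ ∈ {0, 1, 2} voxels, the intensity and its three spatial
  derivatives (12 channels), sampled at the current vertex positions by
  trilinear interpolation. A *learned* linear embedding of these channels
  lives in the graph network's input layer; since a 1×1×1 convolution
  commutes with trilinear sampling, this is exactly a learned projection head
  on the fixed pyramid. This design keeps the full pipeline in plain numpy
  with hand-derived gradients while leaving the deformation itself entirely
  learned. Out-of-grid queries clamp to the boundary (vertices may
  transiently exit the grid mid-integration) with a matching zero spatial
  gradient.
* **Graph network.** Nodes are the union of WM and pial template vertices;
  edges come from the shared face array, plus optional *virtual edges*
  joining WM vertex `v` to pial vertex `v` (on by default). Input per node:
  sampled image features ‖ coordinates (normalized by the grid half-diagonal)
  ‖ optional template features ‖ integration time `t` ‖ a surface-class
  indicator. Two residual blocks of neighbourhood-mean message passing with
  linear transforms and ReLU (width 64) follow; the velocity head is a linear
  map **initialized to zero**, so an untrained model is exactly the identity
  deformation — a stability aid and a free test anchor. The per-block 64-dim
  activations of the final flow evaluation are the "deep vertex features"
  (64×2 = 128) used to enrich templates.
* **Integration.** Five explicit Euler steps of size 0.2 on `t ∈ [0, 1]`
  (the product is constrained to 1). Divergence beyond 10× the grid diameter
  aborts with diagnostics.
* **Training.** Backpropagation through time across all five steps, including
  the trilinear sampler's spatial derivative, with Adam. Gradients are
  verified against central finite differences in the test suite. All
  computation is float64 except image pyramids, which training stores as
  float32 for memory.

### Losses

Per surface: a symmetric Chamfer loss on squared nearest-neighbour distances
between points sampled from the predicted mesh and reference points, the
reference→prediction direction weighted per reference point by
`1 + |κ|/mean|κ|` (normalized to mean 1, so uniform curvature reduces to
plain Chamfer); mean squared edge length; and mean `1 − cos` over adjacent
face-normal pairs. A multiclass voxel cross-entropy is provided for
segmentation supervision; because the image encoder here is a fixed filter
bank there is no learnable voxel head, and its default training weight is 0.
Default weights (1, 0.1, 0.1, ·) were tuned on the synthetic benchmark and
are non-canonical. The losses are applied to the final integration state
only; supervising intermediate states is possible but not default.

## Within-subject templates

Stage-1 outputs for all of a subject's visits are averaged element-wise over
generalized vertices (coordinates and features by the same operator — the
generalized-vertex view gives no reason to treat them differently). All
available visits always enter the aggregate; omitting later visits would bias
the template toward earlier anatomy. Coordinate-wise **median** aggregation
is available as an alternative but is expected to degrade surface quality
(more self-intersections); degenerate geometry after median aggregation is
not repaired — it surfaces in the SIF score. The first-order equivalence of
mean-of-solutions and solution-of-the-mean-field is verified numerically by
holding the number of Euler steps fixed and shrinking the step size: the
total deformation scales with `h` while the gap shrinks as `h²`, and the gap
vanishes identically for visit-independent or constant fields.

Stage 2 copies all stage-1 parameters except the input layer, which widens to
accept the 128 template features and is freshly initialized (seeded).

## Metrics

* ASSD: Eq.-style symmetric mean of point-to-surface distances with
  100,000 points per surface at full scale (tests and the benchmark scale
  this down; sampling noise on sphere pairs is below 1% SD across seeds).
* HDX: directed X-th percentiles by linear interpolation of the empirical
  CDF (type-7 quantile — fixed so reported values are bit-reproducible),
  maximum over directions. HD100 is the classical Hausdorff distance.
* Cortical thickness: bilateral — mean of (WM vertex → pial surface) and
  (pial vertex → WM surface) exact distances per corresponding vertex pair.
* MCVar / CThVar: per-vertex unbiased (ddof = 1) variance across visits,
  subject score = median over vertices; requires ≥ 2 visits. Curvature
  enters as `|κ|`.
* ParcF1: labels propagated by vertex identity; for every **ordered** visit
  pair, each vertex is matched to the spatially nearest vertex of the other
  visit and the per-class F1 is support-weighted; scores averaged over pairs.
  ("Pairwise" is ambiguous between adjacent-only and all pairs; all ordered
  pairs is the fixed choice here.)

## Synthetic cohort

The generator emulates the *structure* of a longitudinal aging/AD imaging
study, not MRI physics. Defaults (the study conditions of the benchmark):
20 subjects; visits ~ round(N(4.4, 1.9)) clipped to 2–5, spaced 0.5–1.5 yr;
48³ volumes at 1 mm; outer surface = sphere of radius N(14, 1) mm modulated
by a smooth random radial field (real spherical harmonics, degrees 2–4,
relative SD 0.08); thickness field 2.5 ± 0.4 mm (smooth, clipped ≥ 0.3 mm);
inner surface = outer eroded along vertex normals by the thickness field;
per-visit shape drift of SD 0.15 mm (diagnosis-independent); thickness loss
of 0.1 mm/yr in the disease group vs 0.01 mm/yr in controls (within the
range reported for AD vs normal aging); baseline ages uniform on 60–85;
groups balanced. Volumes are piecewise-constant occupancy images (white 1.0,
gray 0.6, background 0.05 — a T1-like ordering) plus Gaussian noise of SD
0.05. Parcellations are farthest-point-seeded geodesic regions on the
template. Generation is bitwise reproducible per seed; configurations whose
inner surface would cross the outer are rejected.

What passing on this cohort does **not** show: robustness to MRI contrast
and bias fields, to non-spherical topology of real cortical sheets' folding
depth, to registration errors, or to reference-surface noise — real cortices
are far more convoluted than the low-order harmonic shapes used here, and
the image model is trivially segmentable. The benchmark demonstrates the
*mechanics* of the method (correspondence, consistency gain of the template
composition, metric behaviour), not clinical performance.

## Group analyses

The vertex-wise mixed model uses an unstructured 2×2 random-effects
covariance (intercept, slope), falling back to a diagonal structure on
non-convergence (flagged, never silently dropped). P-values are uncorrected
two-tailed Wald tests; an optional Benjamini–Hochberg flag exists but is off
by default. When a vertex's data are an exact linear fit (zero residual),
the likelihood is degenerate; the coefficients are then recovered by least
squares and the test statistic reported as infinite — this is what makes the
noise-free recovery oracle exact. Normative Z-scores estimate per-vertex
mean/SD per 10-year age bracket from control subjects' *initial* scans only
(avoiding bias toward frequently-scanned subjects); every scan is scored
independently as the mean Z over unmasked vertices (the medial-wall analogue
can be supplied as a mask). A scan falling in a bracket with fewer than two
reference subjects is an error by default; nearest-bracket fallback is
opt-in. AUC uses the Mann–Whitney rank formulation with midranks.

## Scale choices

The end-to-end benchmark (tests and acceptance script) trains both stages for
20 epochs at learning rate 2e-3 with 3,000 reference / 1,500 predicted
Chamfer points per scan, a subdivision-3 icosphere template (642 vertices per
surface), and a 70/15/15 subject split; these sizes are the package's chosen
desk-scale operating point and reach held-out ASSD well below half a voxel.
Optimizer settings are not canonical to the method and are exposed in
`TrainConfig`.

## Known limitations

* The image encoder's learned capacity is a linear embedding of a fixed
  filter bank; a learned convolutional encoder would be strictly more
  expressive for realistic MRI contrast.
* Mixed precision and GPUs are out of scope; everything is CPU numpy.
* One WM/pial pair (a single-hemisphere analogue) per model by default.
* Self-intersections of outputs are measured (SIF), never repaired.
* Median aggregation is provided for comparison but not recommended.
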