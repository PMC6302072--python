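# Methods

This note documents the models, conventions and numerical choices the
package commits to, and what its synthetic benchmarks do and do not
establish.

## Coordinate and angle conventions

* x = AP axis (anterior→posterior), y = DV axis, units µm. The
  compartment boundary is vertical (parallel to DV), so "perpendicular
  to the boundary" means "along AP".
* Orientations are nematic (axes, not vectors): θ ∈ [0°, 180°),
  reported relative to AP. Acute angles measured against the boundary
  convert via α_AP = 90° − α_boundary. Differences between two axes are
  folded into [0°, 90°].
* The AP/DV division split puts α = 45° in the DV class.
* Angle histograms are binned at 15° for report output only; every
  statistic runs on unbinned angles.

## Polarity tensors

Both descriptors are symmetric 2×2 second-moment matrices about the
cell's **area centroid** (the pixel-mask centroid a tracker reports,
not the vertex mean), summarised by η = 1 − λmin/λmax and the principal
axis θ.

* **Vertex tensor**: `Σ û ûᵀ` over *unit* centroid→tricellular-vertex
  vectors. Using unit vectors makes the tensor a pure descriptor of the
  angular distribution of vertices, which is the quantity a
  vertex-anchoring spindle mechanism senses: η = 0 for any k-fold
  symmetric arrangement (k ≥ 3) regardless of distances, and η = 1
  exactly when all vertices fall on one axis through the centroid (two
  diametrically opposed groups).
* **Shape tensor** (default `method="area"`): the central second moment
  of the enclosed area, `∫∫ r rᵀ dA`, evaluated in closed form from the
  vertex list (signed fan triangulation; exact for simple polygons).
  A perimeter-sampling variant (`method="perimeter"`: `Σ r rᵀ` over
  points uniform in arc length, n ≥ 36) is provided; it converges as
  sampling densifies but weights elongation differently.

**Calibration.** The two conventions were fixed against the worked
straight-boundary construction (below), which this package treats as
its quantitative anchor: the straightened boundary cell must score
η_vertex ≈ 0.21 perpendicular to the boundary and η_shape ≈ 0.13
parallel to it. The unit-vector/area-moment pair reproduces both
(0.2120 and 0.1366); length-weighted vertex tensors and perimeter-
sampled shape tensors miss one or the other by more than the ±0.02
tolerance. This is a deliberate package-level design choice; the
perimeter variant remains available for sensitivity checks.

**Degeneracy.** When λmax − λmin < 1e-9·λmax the tensor is flagged
isotropic and θ is `None` — an η ≈ 0 tensor has no meaningful axis.
Eigenvalues are computed with the cancellation-free closed form
(half-gap = hypot((Mxx−Myy)/2, Mxy)), so η has no numerical floor above
~1e-15.

**Moment-equivalent ellipse.** `fit_ellipse` converts the area moments
to the ellipse with the same second moments: full axes 4·sqrt(λ) of the
covariance (moments/area). Elongation = log10(long/short); 0.3
corresponds to an axis ratio of 2 and is the default stratification
cutoff (a value exactly at the cutoff goes to the moderate group).

## The worked straight-boundary construction

Regular hexagons (circumradius R) are packed in columns with vertices
pointing toward the boundary, so a column interface is a zig-zag
through tricellular vertices at two alternating x positions (R/2 and R
past the column center). The straight boundary is the mean line of the
zig-zag (x = 0.75R past the column center); straightening s ∈ [0, 1]
moves each interface vertex toward its projection on that line (s = 1:
all interface vertices collinear). The worked-example cell is an
interior boundary cell (all six vertices tricellular). The construction
is noise-free and fully deterministic; both η values rise strictly
monotonically with s.

## Synthetic world

The generators state a world once; their defaults are not tuned to any
test outcome.

* **Epithelium**: hexagonal lattice, default circumradius 2.5 µm
  (≈ 16 µm² cells, embryonic-epidermis scale). Optional Gaussian vertex
  jitter (shared consistently across neighbouring cells). Cells
  flanking the straightened interface are flagged BC.
* **Division mixture**: a boundary cell divides boundary-perpendicular
  (angle ~ N(0°, 15°) folded) with probability p = 0.7, otherwise — and
  always for NBCs — along its own interphase long axis plus N(0°, 15°).
  The long-axis orientation is uniform; elongation is a truncated
  normal log10 axis ratio (mean 0.25, SD 0.12, floor 0.02), putting
  roughly a third of cells past the 0.3 cutoff, as in mid-embryogenesis
  epidermis.
* **Division tracks**: frames every 30 s; mothers carry 16 min of
  history. Area grows 35 % over the final 10 min; the axis ratio ramps
  up 60 % over the final 3 min (anaphase elongation, axis snapping to
  the division axis); the outline pinches to a 0.35 neck within the
  last minute; daughters split the mother area 45–55 % (20/80 for the
  uneven-split distractor) with their centroid axis laid exactly along
  the latent division angle. Distractors reproduce the signature minus
  exactly one criterion (uneven split / shrinking mother / no anaphase
  elongation / no dumbbell). Mothers are free-floating outlines placed
  at lattice-cell centroids — the generator does not maintain tissue
  topology through division, which detection does not need; six
  pseudo-tricellular vertices at fixed outline positions stand in for
  real vertex data (labelled synthetic by construction).
* **Centrosome walks**: isotropic Gaussian steps (SD 0.25 µm per 20 s
  step) plus optional drift; a tether pulls each new position toward the
  tether point by strength ∈ [0, 1] (1 = pinned).
* **Kymographs**: d(t) = d0 + v0·τ·(1 − e^(−t/τ)) + N(0, σ), defaults
  v0 = 0.5 µm/s, τ = 10 s, dt = 1 s, d0 = 0.5 µm, σ = 0.05 µm — the
  scale of boundary-junction ablations. d0 is a package addition (the
  model needs an initial separation); the derivative at t = 0 is v0.

What a green synthetic benchmark does **not** establish: the real-data
effect sizes (correlations, U statistics, fold changes) depend on the
deposited microscopy data and are mirrored here only qualitatively —
shape-following worlds give high shape-division correlation,
boundary-biased worlds give none, detection is exact on noise-free
signatures. Segmentation error, neighbour exchanges, z-projection
artefacts and unequal friction in ablations are all outside the stated
world.

## Detection

All four criteria must hold; trend criteria use the sign of the OLS
slope over their window rather than endpoint differences (robust to
single-frame noise). A window is evaluable only if the track actually
spans it (first frame within two frame intervals of the window start)
— otherwise the candidate is reported unevaluable, never silently
rejected. The neck ratio measures chord widths along the principal
axis and takes the minimum between the widest stations of the left and
right halves, so tapering ellipse tips do not read as necks; the
threshold 0.6 sits between true dumbbells (≈ 0.35) and convex outlines
(≳ 0.9). BC labelling requires a full edge (both endpoints and
midpoint) within 0.1 µm of the boundary polyline; a single touching
vertex does not qualify. Manual curation is replaced by an explicit
exclusion list.

## Recoil fitting

The velocity is the OLS slope over the first 5 samples strictly after
the cut frame, using actual timestamps (frame delays differ across
experiments). The pre-cut point is excluded; note that for an
exponential relaxation the 5-point slope understates the true v0
(curvature inside the window), so comparisons should always be made
between identically fitted conditions — the package reports the
noise-free fitted value alongside ensemble means for exactly this
reason. The kymograph-to-image step (Fiji reslice) is out of scope; the
module consumes separation series.

## Centrosome metrics

Persistence = displacement / total distance, set to 0 for a zero-length
path. Average speed = total distance / elapsed time; per-interval
speeds are exported for time-resolved curves. pCen/dCen assignment uses
the whole-track mean xy distance to the boundary (the cable is apical,
z is ignored), tie-broken by first-frame distance then id, so the
labelling is deterministic; NBC cells are left unassigned. Inputs are
assumed drift-corrected.

## Determinism

Every generator is a pure function of (spec, seed); the pipeline splits
one root seed per stage via `SeedSequence.spawn`, never touching global
RNG state, and rerunning a config reproduces every output byte for
byte. Configs round-trip losslessly through YAML.

## Known limitations

* The epithelium generator produces geometry, not mechanics: no force
  balance, no neighbour exchange, no curvature.
* Synthetic division events all abscise at the same nominal time;
  staggering would only relabel frames.
* The worked-example construction fixes one reading of the
  straight-boundary figure (single straightened interface, mean-line
  placement); the generator exposes the straightening fraction and
  boundary position so other readings can be built.
* Exact Mann-Whitney p-values are used only for small tie-free samples
  (n ≤ 8); larger samples use the tie-corrected normal approximation.
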