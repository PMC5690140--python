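# Methods

This note records the models, conventions, parameters and design choices
behind `tiletrack`, in the order the data flows through the pipeline.

## Geometry and coordinate conventions

World coordinates are physical millimetres with the isocenter at the
origin and +z superior. The imaging system is a pinhole: the source sits
at SAD (default 1000 mm) from the isocenter, the flat detector at SDD
(default 1876 mm) from the source, perpendicular to the central ray. The
*imaging angle* (gantry + imager offset) rotates source and detector
about z; at angle 0 the source is at (0, −SAD, 0). Detector axes are
u = columns (rotated +x direction) and v = rows (+z); pixels are 0-based
pixel centers with the central ray at ((rows−1)/2, (cols−1)/2). The
magnification of an object in the isocenter plane is SDD/SAD = 1.876, and
a detector offset converts to isocenter millimetres as
Δmm = Δpx · pitch · SAD/SDD (0.2132 mm/px at the clinical 0.4 mm pitch).
These conventions are fixed so geometric tests can be bit-exact; the
`project_point` implementation is cross-checked in the tests against an
independently coded homogeneous-matrix projection.

## DRR engine

A DRR pixel is the line integral of trilinearly interpolated voxel
attenuation along the source-to-pixel ray, computed by midpoint sampling
at a fixed step (default 1 mm — sub-voxel against the 3 mm CT slices)
between the ray's entry and exit of the volume bounding box (slab test);
rays missing the volume give 0. Pixel values stay on the raw
density·mm scale rather than exponentiated transmission: the downstream
matching is deliberately intensity-map agnostic (CLAHE plus per-tile
linear fits absorb any monotone display map), and raw integrals keep the
engine exactly linear in the volume, which makes the
background + tumor = composite decomposition testable to tight tolerance
and lets the simulator compose moving-tumor frames cheaply.

`split_volume` excises the tumor using the planning contour. The fill for
the excised voxels is configurable: a constant, or (default) the mean CT
value over a 2-voxel shell just outside the contour — inside lung the
shell mean is the surrounding lung density, so background DRRs show no
hole. Accuracy notes: the midpoint rule halves its error when the step is
halved on smooth volumes (<0.5 % per halving in the tests); comparisons
between differently cropped volumes agree only to the discretization
error, since cropping shifts each ray's sampling phase.

## Synthetic torso phantom and projection simulator

The phantom emulates a humanoid torso with analytic primitives rasterized
at voxel centers, so all ground truth is exact: an elliptical soft-tissue
body, two lung ellipsoids, elliptical bony rib rings, a water-density
heart sphere, a cylindrical tumor (default 30 mm diameter × 30 mm height,
axis superior-inferior) centered in the right lung, and three 5.5 mm
marker spheres implanted around the tumor. Default attenuation values
(unitless per mm): air 0, lung 0.2, soft tissue/water 1.0, tumor 1.1,
bone 1.8, marker 8.0 — only the contrast ordering matters to the
algorithm. Default voxel spacing is 2.5 × 2.5 × 3 mm (3 mm axial slices).

Tumor motion shifts the masked moving unit — tumor plus markers, which
ride the same motion platform — by trilinear resampling of its excess
attenuation over a shell-filled background, mirroring the
background/tumor separation of the method itself. Zero displacement
returns the untouched CT, so the undistorted simulated projection is
bit-identical to the CT's DRR. Motion patterns: per-axis sinusoid
A·sin(2πt/T + φ), the flattened end-exhale waveform A·cos⁴(πt/T + φ), or
a cyclic piecewise-linear table.

The projection-vs-DRR discrepancy model applies, in order: a monotone
gamma map on the max-normalized image (default γ = 1.3), a multiplicative
low-frequency bias field (coarse seeded Gaussian noise upsampled with
cubic splines, default amplitude 10 % at 64 px scale), and additive
Gaussian noise (default SD 2 % of the dynamic range). Every component
switches off at its neutral value and is bit-reproducible given a seed.
What the simulator does *not* model: anatomical CT texture, Monte-Carlo
scatter, detector lag/glare, cardiac motion, and nonrigid deformation of
the background anatomy — so passing the synthetic suite shows the
algorithm tolerates global intensity mismatch, structured overlap (ribs,
heart), noise and tumor motion, but not deformable-anatomy effects.

A fast multi-frame simulator caches the static background DRR per imaging
angle and ray-traces only the cropped moving excess per frame; by
linearity this equals the composed-volume DRR to the ray-march
discretization error (≤0.5 % near the sharp marker edges).

## CLAHE

Contrast-limited adaptive histogram equalization is implemented directly:
the image is divided into a grid of contextual regions (default 8×8),
each region's histogram (default 256 bins over the image's min–max range)
is clipped and the excess redistributed equally over all bins, and the
resulting CDF mappings are bilinearly blended between region centers
(clamped outside the outermost centers), eliminating region seams. The
clip limit is expressed as a fraction of the region pixel count (the
adapthisteq convention, default 0.01) and floored at the uniform bin
height so redistribution always converges; a clip limit of 1.0 disables
clipping, and with a single region the transform reduces exactly to
global histogram equalization (verified against a direct CDF oracle).
An exactly constant image maps to an exactly constant output, making the
operation idempotent there.

## Tile matching and tile-shift optimization

Per-tile NCC is the mean-subtracted, variance-normalized correlation over
congruent tiles; a zero-variance tile scores 0 by convention (a constant
tile carries no matching evidence, and 0 is neutral in the average). The
total similarity S is the mean over tiles; under bad-tile exclusion the
single minimum tile (ties: first in row-major order) is dropped and the
mean runs over U·V − 1 tiles. The default configuration is a 3×3 grid
with tile size ≈ 1.35× the projected tumor extent, clamped to the
1.2–1.5× guidance band and to the image.

The optimizer exhaustively scores tile-grid start offsets over one tile
period (default step: tile/8) and returns the argmax of the
bad-tile-excluded S, with deterministic lexicographic tie-breaking. The
searched offset shifts the grids of *both* images together: the tile
boundaries move over the registered projection/DRR pair until the tumor
discrepancy falls inside a single tile, while tile correspondence is
preserved. An optional flag additionally searches an independent DRR-grid
offset, which scans relative (registration) shifts for imperfectly
aligned pairs; it is off by default since the simulator produces
pixel-registered pairs. Candidate grids that would extend past either
image are dropped, never padded. Equivalence with a brute-force scan, the
isolation of a constructed disc discrepancy into exactly one low tile,
and monotone improvement over the unshifted grid are all asserted in the
tests.

## Background subtraction

Each tile's intensity transform P ≈ a·D + b is an ordinary least-squares
closed form (deterministic; a constant DRR tile degenerates to a = 0,
b = mean(P) and is flagged). The transform is intensity-only: geometric
alignment is carried entirely by the rigid first-step registration. The
bad tile's own fit is contaminated by the tumor and is replaced by the
inverse-distance-weighted mean of its non-degenerate 4-neighbors — for an
interior tile this equals the bilinear interpolation of the four
surrounding centers; more than one degenerate neighbor is rejected.
Coefficients are then bilinearly interpolated from tile centers to
pixel-level gain/offset fields, clamped constant outside the outermost
centers (avoiding runaway extrapolation at borders), which makes the
fields continuous — no tile-induced boundaries — and exact at tile
centers. The residual is P − (a·D + b) pixelwise, with the DRR first
aligned by the matched configuration's relative tile offset. When P is
globally an affine map of D the residual is numerically zero (<1e−10 of
the dynamic range).

## Marker removal

Markers are detected by NCC template matching (FFT-based) with greedy
non-overlap suppression; the ideal template is the projected sphere
chord-length profile at the detector magnification. Inpainting follows a
shrinking-radius scheme: the disk is peeled outermost-ring first, each
pixel seeded with the mean of its already-valid 8-neighbors (3D: 26) in a
fixed raster order, and the neighborhood averaging is then iterated to
convergence, so the fill is the discretely harmonic — smooth —
interpolant of the surrounding intensities. A reference-shift makes a
constant image an exact fixed point, pixels outside the disks are
bit-identical, and fills never leave the range of the boundary ring
(convex combinations). The same algorithm removes markers from the
planning CT (sphere neighborhoods, 26-neighbor means) before DRR
generation; CT-side marker positions come from intensity thresholding
above the bone/marker midpoint.

In the tracking pipeline the three markers are matched jointly as one
rigid constellation template projected from the planning-CT marker
centers, searched on a high-pass copy of the frame (markers are
small-scale; smooth anatomy flattens out) in a window anchored on the
current tumor estimate — the previous frame's location, or a provisional
first-pass localization with the markers still in place on the first
frame. Joint matching with a position prior proved far more robust than
independent per-blob detection, which misses markers that project onto
the tumor and locks onto rib/chest-wall edges. The generic per-blob
detector remains available for images without a planning prior.

## Tumor localization

The second registration evaluates NCC at every integer placement of the
tumor template inside a search window (first frame: the bad tile expanded
by half a tile per side; later frames: a window of half-width 0.75× the
tile size centered on the previous location; a peak pinned to the window
border or below the confidence floor triggers a full-image re-match).
Ties resolve to the smallest row-major placement. Optional sub-pixel
refinement fits separable quadratics to the 3×3 NCC neighborhood of the
peak and never moves it more than 0.5 px per axis; it is off by default
in the library and enabled in the validation experiment, whose isocenter
pixel scale (0.85 mm) would otherwise quantize the error.

Two template constructions are provided. `make_tumor_template` crops the
raw tumor DRR to its support. `make_residual_template` — used by the
validation experiment — builds the template in the residual-image domain
from planning data only: CLAHE(background + tumor DRR) minus
CLAHE(background DRR), cropped to the tumor support. Since the residual
is formed from CLAHE'd images, the tumor appears there modulated by the
local slope of the equalization mapping; the raw-integral template left a
systematic 1–2.5 px bias at angles where heart or rib edges underlie the
tumor, which the residual-domain template removes.

The tracking error is the per-frame 2D Euclidean distance between the
estimated and true tumor center in the isocenter plane, summarized per
(gantry, imager) set by maximum and mean and pooled overall. Per-axis or
detector-plane alternatives would differ only by the fixed magnification.

## Validation experiment (desk scale)

The end-to-end experiment mirrors the physical phantom study as a
simulation twin: the default phantom, 12 gantry angles (0°–330° in 30°
steps) with two imagers at gantry ± 45° (24 sets), 20 frames per set at
5 Hz of sinusoidal motion with amplitude (3, 2, 20) mm — dominant
superior–inferior, one full 4 s cycle — and the full distortion model
with per-frame seeds derived from the master seed. The detector is
256×256 at 1.6 mm pitch: the same physical field of view as a 1024×1024
panel at the clinical 0.4 mm pitch, downsampled 4× so the 480-frame
experiment runs in a few minutes on one CPU. All 480 frames are tracked;
the suite asserts the overall maximum error ≤ 2.2 mm and overall mean
≤ 0.9 mm against the exact simulated ground truth.

## Numerical and degenerate-input conventions

* Zero-variance NCC tiles score 0; a window smaller than the template, a
  grid mismatch between volumes, tiles overflowing the image, or a 1×1
  grid with bad-tile exclusion are rejected with errors.
* All stochastic elements (bias fields, noise) draw from
  `numpy.random.default_rng` seeded per frame from the experiment's
  master seed; repeated runs are byte-identical, which the pipeline tests
  assert on the emitted CSVs.
* A failed pipeline stage flags the frame and carries the previous
  location forward; no frame is silently dropped.

## Known limitations

* The background anatomy is rigid; deformable motion of ribs/diaphragm
  relative to the tumor is not simulated and the method as implemented
  has no nonrigid correction.
* Only one imager is processed at a time; no 3D fusion of the dual
  orthogonal views, temporal filtering, or gating logic.
* The marker constellation removal assumes planning-CT marker positions
  and a tumor-position prior; fully blind marker removal falls back to
  the less robust per-blob detector.
* The simulator's discrepancy model is global and smooth; real scatter
  and detector effects are not guaranteed to be absorbed equally well by
  the per-tile linear maps.
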