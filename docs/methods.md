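# Methods

This note documents the models and procedures implemented in `odontometry`,
the parameters that matter, what the synthetic phantoms do and do not
emulate, and the numerical choices made where the design was genuinely open.

## Coordinate conventions

Array index order is `(x, y, z)` with x the frontal axis (patient
left–right), y the sagittal axis (anterior–posterior) and z the axial axis
(inferior–superior). All indexing is zero-based half-open. Distances in
millimetres always go through the per-axis voxel spacing; voxel-space
arithmetic is used only for indexing, so anisotropic spacing is honoured
everywhere. Hue lives on [0, 1) with circular distance
d_h = min(|Δh|, 1 − |Δh|), which removes any degree/fraction ambiguity from
color-space radii. "Left" means the half-arch at negative x in the
phantom's own frame.

## The synthetic dental phantom

The phantom is the package's study condition, not a tuning knob. Two
arches of 12 teeth each (right first molar to left first molar) are placed
tangentially along the parabola y = a·x², at arc-length positions given by
the cumulative mesio-distal widths plus a 0.6 mm interproximal spacing.

* **Tooth widths** default to clinical mean values per position:
  7.25, 6.74, 7.63, 7.66, 7.36, 11.03 mm (central incisor … first molar),
  identical in both jaws.
* **Tooth shape** is a superellipsoid (exponent 4) whose mesio-distal
  extent equals the specified width exactly, so ground-truth landmarks —
  the two points at the mesial/distal equator — are analytic. Crown height
  defaults to 8 mm; bucco-lingual depths are 7–11 mm by position.
* **Arch coefficient** a = 0.055 mm⁻¹ was chosen once so that the phantom's
  arch widths (inter-canine ≈ 29 mm, inter-premolar ≈ 40.6 mm,
  inter-first-molar ≈ 53.5 mm) fall in the clinically reported range.
* **Intensities** follow a Hounsfield-like ordering: background 0, soft
  tissue 300, alveolar bone 900, teeth 1600, metal streaks 3000 — enough
  contrast structure for a classical segmenter, with no claim of HU
  fidelity. Additive Gaussian noise (σ = 60 by default) is applied last and
  never alters ground truth.
* **Voxel spacing** defaults to 0.3 mm, the typical CBCT export
  resolution; the inter-jaw gap defaults to 4 mm, with 0 (closed bite) and
  negative (overlap) values as stress cases.
* **Head rotation.** The in-plane rotation parameter emulates head yaw and
  is applied about the cranial yaw axis, placed 45 mm posterior of the
  incisors (condylar/odontoid level): in practice, in-plane misalignment is
  the patient's head rotating in the scanner, which both rotates and
  translates the dentition relative to the image frame. The
  mandibular-inclination angle α rotates about the frontal axis through the
  arch-band centre and is recorded in truth so both the supplied-α and
  estimated-α paths can be tested.
* **Scan phantom.** The occlusal surface of one jaw is sampled as a point
  cloud (0.15 mm step): crown height fields plus Gaussian cusp bumps
  (amplitude 1.6 mm, σ 1.1 mm) at canine tips, premolar buccal/lingual
  cusps and the four molar cusps; cusp apices are included as explicit
  samples so the true cusp tip is exactly the arg-max of z over the tooth's
  points. Teeth are colored near-white (s ≈ 0.06, v ≈ 0.95), gum pink
  (h ≈ 0.97, s ≈ 0.55), with seeded HSV jitter.

What the phantom does **not** emulate: partial-volume blur, beam hardening
and scatter, root anatomy below the crown band, anatomical crown shapes,
scanner color calibration, saliva/reflection artifacts. Passing tests
therefore demonstrate the pipeline's geometric and algorithmic correctness
under controlled conditions, not clinical-grade accuracy on patient data.

## Arch curve and panoramic image

The arch curve is initialised from per-column weighted y-centroids of the
supra-Otsu mean axial projection and a weighted quartic polynomial fit
(quartic rather than quadratic to capture molar flare). Column centroids
are biased wherever the arch runs steeply, so the fit is refined
iteratively (5 passes): every curve point moves to the midpoint of the
bright run sampled along its local normal (±18 voxels, exact for a band
symmetric about the arch), and the quartic is refit through the moved
points. Refitting — rather than free-form point updates — is what keeps
the curve smooth at arch scale: per-tooth structure cannot wiggle it and
the open ends cannot hook into the last molars. On the default phantom the
refined curve passes within half a voxel of every true tooth centre.

The panoramic image realises the integral along the normal as a *mean* of
2K+1 trilinear samples over t ∈ [−w, w] (K = w by default, 1-voxel steps),
keeping panoramic intensities on the input scale so one threshold serves
both views. The normal half-width w defaults to 15 voxels (≈ 4.5 mm),
chosen from typical crown depth. Normals are oriented buccally (away from
the curve centroid) point-by-point. Out-of-grid samples are excluded from
the mean.

## Jaw separation

Sagittal (constant-y) slices are segmented by the classical reference
segmenter: threshold at the teeth level (two-stage "bright-tail" Otsu by
default — a second Otsu above the global split separates enamel from
bone), morphological opening, connected components, and an
h-maxima-seeded distance-transform watershed that splits fused components
(e.g. upper and lower crowns in a closed bite). Watershed seeds are merged
below a minimum separation and capped by how many teeth the component's
extent can hold, which prevents oversplitting. The segmenter is injected
through a behavioural contract so a learned model can replace it without
touching anything else; the shipped test path is entirely classical.

Each slice mask's bounding-box centre is projected to the panoramic frame
(nearest curve point; beyond w → unassigned) and looked up in the
upper/lower panoramic mask sets, with a 3-pixel nearest-mask tolerance for
points that fall just outside thin masks. The panoramic segmentation
computes its threshold from the panoramic image's own histogram — the
normal-averaging dilutes thin teeth, so the volume-level threshold would be
too high. The upper/lower boundary line is regressed through midpoints of
vertically adjacent mask-centroid pairs (the regression inputs are not
specified by the underlying method description; adjacent-pair midpoints are
the natural choice). The upper and lower label volumes never intersect, by
construction and by test.

## Tooth identification

Per jaw, the MIP (max over z; depth = first z attaining the max, with the
upper jaw z-flipped so depth is always occlusal-first) is segmented by the
same reference machinery. Detection fragments closer than 80% of the
minimum anatomical tooth spacing (5 mm default) are merged — two real
teeth cannot be that close, but a cracked footprint can.

The jaw profile is the outer (buccal/anterior) border of the
morphologically closed MIP foreground, traced by casting rays from the
region centroid and keeping the farthest foreground pixel per ray; the
largest angular run of misses (the posterior opening) defines the two ends
of the open curve.

The adaptive midline restricts candidates to the anterior (middle
arc-length) third of the boundary and takes the contiguous run of points
whose distance from the posterior centre is within Δd of the maximum,
returning the run's coordinate mean. Two numerical choices matter here:

* The "distance to the centre" is computed, by default, as the projection
  onto the arch's anterior symmetry direction (minor principal axis of the
  boundary points, oriented away from the distal ends) — equivalent to a
  posterior centre at infinity. A finite centre estimate tilts the
  distance profile across the flat incisor face, which can tie the apex
  against its own corners on wide, shallow arches; the projection form is
  insensitive to that. An explicit centre point can still be supplied.
* Δd defaults to 2.4 mm (8 voxels at 0.3 mm): larger than the combined
  sagitta and inter-central notch of the anterior face (up to ~1.6 mm once
  pixelation under rotation is included), still well below the canine
  drop-off (~6 mm), so the run averages the whole anterior face and never
  admits canines.

The *fixed* midline baseline — the comparator that motivates the adaptive
estimator — is the image's mid-sagittal column with the sagittal direction
as axis. It lives in the scanner frame, which is exactly what "fixed"
means clinically; under head yaw the dentition translates across it and
the numbering chain shifts by one or two positions on both sides, while
the adaptive midline tracks the arch. On the phantom the adaptive
estimator numbers every tooth correctly for |θ| ≤ 15°, and the fixed
baseline fails from |θ| ≥ 10°.

Numbering signs each detection left/right by the side of the midline axis
its centre falls on, orders each side by arc-length position along the
boundary (nearest to the midline first), and assigns 1…6; extras are
flagged unnumbered, shortfalls are flagged but numbered.

## Landmarks, widths, cusps

Per numbered tooth, the ROI is the detection box dilated by 1.5 mm. The
local mesio-distal axis is the chord through the two neighbouring
detection centres in arch order — for a parabolic arch this chord is
exactly parallel to the tangent at the tooth, it is rigid-motion
equivariant, and it is far more stable than a local tangent of the
pixelated boundary. The geometric reference backend returns the mask's
extreme points along that axis, averaging near-tie pixels perpendicular to
it and pushing the estimate outward by the mask's *edge offset*: 0.5 cells
for voxel masks (cell-centre sampling is inward-biased by half a cell per
side), 0.0 for point-raster scan masks (any-hit marking is already
unbiased). An axis-aligned rectangle yields exactly the midpoints of its
edges.

The cascade contract runs any stage sequence coarse-to-fine: stage k sees
a window of shrink^k times the ROI (shrink 0.6, 3 stages by default where
a cascade is requested) centred on the previous estimate; estimates
leaving the ROI are clamped and flagged. A single reference stage is
identical to the plain backend. The trainable stage is a linear regressor
on a 16×16 resized, peak-normalised crop, predicting the landmark as a
fraction of the window extent, fitted by seeded minibatch SGD with
momentum: v ← μv + ∇L, θ ← θ − ηv, with batch 64, η = 10⁻³, μ = 0.95, and
L the mean squared landmark error. With zero momentum one step reduces to
θ − η∇L exactly.

Landmarks are lifted to 3D through the occlusal depth map (nearest valid
cell within a 3-cell radius; farther → "landmark off tooth surface").
For CBCT the depth map is the occlusal-surface z of the separated jaw mask
(max z for the lower jaw, min z for the upper), which is robust to
intensity noise in a way the arg-max-of-intensity depth is not. Note that
the *absolute* lifted z at a mesial/distal landmark is geometry-limited:
the crown surface has a vertical tangent at the equator, so the surface
height rises ~1.7 mm within one voxel of the edge. The width is unaffected
because the two ends of a pair land at matching heights; tests assert
exactly that pairing property.

Cusp profiles are sampled along the bucco-lingual direction
(perpendicular to the mesio-distal axis) through the landmark midpoint —
for the first molar through the point a quarter of the way from the mesial
landmark, targeting the mesio-buccal cusp; the offset fraction is
configurable. Peaks need ≥ 0.5 mm prominence; the buccal tip is the peak
on the side away from the arch centroid; canines return their single
highest peak. Arch widths are 3D distances between paired buccal tips; a
missing side leaves that parameter absent rather than failing the run.

## FRNN color classifier

Candidates are training samples strictly within radius R (default 0.15 HSV
units) of the query under circular-hue Euclidean distance. Each candidate
contributes σ/d² with σ = −1 for teeth and +1 for gum and d floored at
ε = 10⁻⁶ (exact color matches must not divide by zero); a negative sum
labels teeth, and ties — including an empty candidate ball — go to gum.
The signed mapping is the only reading under which a "negative total
force → teeth" decision rule can function; unit masses are used since no
mass model is specified for color samples. The default training set is
drawn from the phantom's color model; real scans supply a labeled
h,s,v,label CSV. The classifier is exact (no approximate spatial index)
and is verified against a brute-force implementation.

## Agreement statistics

ICC is the two-way random-effects, absolute-agreement, single-measure form
ICC(2,1) — the standard inter-method choice — computed from the mean
squares, with the F-based 95% confidence interval (Satterthwaite degrees
of freedom); the implementation is cross-checked against an independent
one in the tests. ANOVA is one-way fixed-effects with the critical F at
the chosen α reported alongside the p-value. Bland–Altman reports the mean
difference and mean ± 1.96·SD (sample SD, n−1). Success-rate curves use a
strict inequality ("deviation smaller than the threshold"), so the rate at
threshold 0 is 0.

## Problem sizes

Default phantoms are 240×214×147 voxels at 0.3 mm (a 72×64×44 mm tooth
ROI); scan clouds hold ≈ 58 000 points. The test suite and the acceptance
script use single phantoms per condition, a 7-angle rotation battery, 200
training crops from nine phantoms, and a 20-case batch (per-case
width jitter ±0.8 mm) for the pipeline-vs-truth ICC — sizes chosen so the
whole validation runs in minutes on one CPU while every stage is exercised
end to end.

## Known limitations

* No individual 3D tooth segmentation: widths come from 2D landmarks
  lifted by a depth map, so strongly tilted teeth project foreshortened.
* Second and third molars, deciduous dentition and mixed dentition are out
  of scope (12 teeth per jaw).
* The classical slice/MIP segmenters assume CBCT-like intensity ordering;
  heavily artefacted clinical data would need a learned backend, for which
  the segmenter and cascade contracts are the intended seam.
* Arch-width measurement needs scan data; CBCT crowns at 0.3 mm are too
  coarse for reliable cusp tips, mirroring clinical practice.
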