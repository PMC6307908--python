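# Methods

This note documents the quantitation procedures implemented in `xenovasc`,
the conventions and parameters they depend on, what the synthetic-data
generator does and does not emulate, and the design choices made where the
original interactive workflow left details open.

## Geometry conventions

Axis order is `(z, y, x)` with 0-based voxel indices, matching
microscopy-stack page order. A physical position is the voxel-centre
coordinate: `position = (index + 0.5) × voxel_size` per axis, in µm. Voxel
size is anisotropic — the assay images static stacks at 5-µm optical
sections and time-lapse at 8-µm sections, while xy sampling is
sub-micrometre — and all volume arithmetic carries the anisotropy in the
voxel volume `dz·dy·dx` rather than resampling. Volumes are exact voxel
counts times the voxel volume; there is no sub-voxel interpolation, which
keeps every volume assertion exactly testable.

## Object detection

A fluorescent object is a connected component of voxels with intensity
**≥** the channel's threshold, retained when its volume is **≥** the
minimum object volume. Defaults follow the workflow being reimplemented:
graft channel 250 intensity units and 100 µm³, vessel channel 100 units and
100 µm³. Both comparisons are inclusive: the original description says only
"minimum", and the inclusive reading makes an object of exactly 100 µm³
(80 voxels of 1.25 µm³) the smallest accepted size, which the tests pin
down. Intensity units are raw detector counts at whatever bit depth the
file carries; the original instrument's scale is unknowable, so thresholds
are configuration, not constants.

Connectivity defaults to 26 (diagonal-touching voxels connect), the
behaviour of commercial 3D object counters; 6 and 18 are available for
sensitivity analysis. Components are labelled 1..K in decreasing volume
order with ties broken by smallest centroid z, then y, then x, so label
assignment is deterministic under permutation of the input.

The area of interest (AOI) for vessel detection is, by default, the minimal
axis-aligned bounding box of all graft objects — mirroring the box drawn
around the graft in the interactive workflow — with a stricter `mask` mode
(union of graft voxels) available. Vessel detection masks the channel to
the AOI *before* labelling, so objects straddling the boundary are clipped
and only in-AOI voxels count. With the bounding-box AOI the vessel volume
can in principle exceed the graft volume; percentages above 100% are
reported with a warning, never clipped.

## Percentage vascularisation and the regional partition

Percent vascularisation is `100 × ΣV_vessel / ΣV_graft` over detected
objects. The regional breakdown projects each graft voxel centre onto the
annotated CCV axis (`s = (p − p_CCV)·û`), sorts by `s` (ties by z, y, x
index), and cuts the sorted sequence into three runs whose sizes differ by
at most one voxel, remainder voxels going to the proximal-most regions.
This is the "equal sections by volume" reading; an equal-length alternative
(cutting the `s` range into thirds) and a radial-distance mode are exposed
as options since the original description fixes neither. Vessel voxels
outside the graft mask (possible with the box AOI) count toward total
vessel volume but are excluded from regional percentages, which are defined
on graft voxels.

Macrophage counting is centroid-in-AOI with inclusive boundary faces, and
the per-volume normalisation defaults to counts per 10⁵ µm³ (the original
figure axis does not state its unit; the unit is a configuration constant
echoed in output headers). The VEGFA secretion index is concentration
divided by total protein, computed per well and then averaged — the mean of
per-well indices equals the index of means only when protein contents are
equal, so the per-well order of operations matters and is tested.

## Time-lapse association scoring

The angiogenic region is a 10-µm-radius disc in xy centred on the annotated
vessel tip, replicated over the optical sections occupied (under the disc
footprint) by the vessel object nearest the tip — a 2D disc plus a
z-section set, not a sphere, because the original scoring combined a
"circular region" with an explicit same-z-section rule. If no vessel voxel
lies under the disc, the tip's own section is used.

The control disc has the same radius and z-sections and sits 25 µm away
centre-to-centre (an edge-to-edge option exists; the centre-to-centre
reading leaves a 5-µm gap between 10-µm discs, matching the published
schematic). Placement is deterministic: candidate centres at 15° steps are
admissible when the whole disc lies inside the graft's xy footprint on the
region's z-sections, and the admissible candidate farthest from any vessel
voxel wins, ties to the smallest angle. The original workflow placed this
control by hand; the deterministic rule makes runs reproducible and is the
only part of the scoring with no direct textual anchor.

A macrophage is scored present when its centroid lies within the disc
(distance ≤ radius, inclusive) *and* its object occupies at least one of
the region's z-sections. Whether the original analysis required
co-sectioning with the whole vessel or specifically its tip is not stated;
this implementation uses the vessel sections under the disc and flags the
choice here. Summaries per region are the percentage of frames with ≥ 1
macrophage and the mean count per frame.

## Tracks, tip-cell classification, speed

Automatic track linking is a convenience for synthetic and pilot data (the
original tracks were manual, and externally curated tracks are accepted via
CSV): per frame pair, the assignment minimising total displacement is
solved exactly, links longer than `max_step` are forbidden, unmatched
detections start new tracks, and tracks never contain gaps.

Contact with a tip is 3D distance ≤ 10 µm (defaulting to the
angiogenic-region radius — no separate contact distance is stated
anywhere). Contact duration is the time *spanned* by a maximal run of
consecutive contact frames, `(run length − 1) × frame interval`: a
single-frame sighting should not count as 10 min of association, so at
10-min sampling a ≥ 40 min (tip-cell) contact needs five consecutive
contact frames, and classification at exactly 40 min is inclusive.

Speed comparison uses path length over time: the during-window is the
contact interval, the after-window the same number of frames immediately
following; when the track ends early both windows are truncated equally
(the during-window keeping its tail) so the comparison stays matched, as in
the original "identical periods of time" design. Speeds are in µm/min (the
original figure does not state units). The revisit fraction counts, among
tip-cell macrophages, those whose tip-cell intervals touch at least two
distinct tip identities.

## Statistical routing

Two groups: Shapiro–Wilk on each sample at the gate level (default 0.05 —
the original protocol states no level; it is configurable). Both normal →
two-sided F-test on variances; p below the gate selects Welch's t-test,
otherwise the pooled t-test. Either sample non-normal → two-sided
Mann–Whitney U (exact when both n ≤ 20 without ties, otherwise the normal
approximation with tie correction). Normality is required of *both* samples
for the parametric branch — the source wording is ambiguous, and requiring
both is the conservative reading. Degenerate cases are routed explicitly: a
constant sample fails the normality gate (Shapiro–Wilk is undefined on it);
two constant samples short-circuit to the pooled-t convention (t = 0, p = 1
for equal means). Multi-group: Shapiro–Wilk per group; all pass → one-way
ANOVA with Dunnett's many-to-one comparisons against an explicit control
group (critical values from the equicorrelated multivariate-t
distribution, via `scipy.stats.dunnett`); any fail → Kruskal–Wallis. The
full gate sequence is returned as a machine-readable decision path.

## Synthetic data generator

The generator emulates the assay's geometry, not its optics. A static
stack is (24, 96, 96) voxels at (5, 0.6, 0.6) µm — the z-spacing the assay
uses; the 0.6-µm xy pixel is this package's choice since the original
reports only z — holding an ellipsoidal graft (semi-axes 40 × 20 × 20 µm,
~37 000 voxels ≈ 6.7 × 10⁴ µm³), vessels, and ~8 well-separated spherical
macrophages (radius 5 µm, so a cell always intersects at least one optical
section even at 8-µm spacing). Channel intensities (graft 1000, vessel
800, macrophage 600 arbitrary units) sit above the detection thresholds by
construction. The noisy preset adds Gaussian noise with σ = 5% of each
channel's foreground intensity; the clean preset is noise-free so recovery
tests can assert exactness.

Vessels are capsule-shaped tubes rooted on the CCV plane (x = 0) growing
along +x. To realise a planted vascular fraction f exactly, the generator
orders graft voxels by a deterministic growth rule — voxels inside a tube
radius fill by distance from the CCV plane (elongation), remaining voxels
by distance to the nearest centreline (thickening) — and takes the first
`round(f·N)` voxels. Any prefix of that order is a connected, tube-like
vessel system, so the realised fraction equals the target to within one
voxel quantum and is recorded exactly in the ground truth.

Time-lapse movies use (10, 144, 144) voxels at (8, 0.6, 0.6) µm, 24 frames
at 10 min, with one designated vessel elongating 1 µm/frame (tip trajectory
recorded, capped inside the graft). Macrophages perform a persistent random
walk (AR(1) velocity, memory 0.4, per-axis step σ_f = 1.5 µm/frame)
confined to the graft ellipsoid by rejection. Within 15 µm of the tip a
free macrophage is captured with probability 0.75 per frame, then dwells —
anchored at the capture-time tip position with σ_d = 0.2 µm jitter,
modelling the observed cessation of migration during tip contact — for
70 min (the observed contacts averaged ~69 min, motivating the default).
On dissociation it departs radially at twice σ_f, modelling resumed
directed migration; this keeps contact ends crisp so planted dwell
durations are recoverable from measured contact intervals to within about
one frame interval (a walker can genuinely wander back into contact, so a
small fraction of intervals extend further — the tests assert a ≥ 90%
recovery rate rather than universality). The `null-dwell` preset disables
dwelling *and* velocity memory: with a memoryless Gaussian proposal and
reject-outside-the-graft, the walk is a Metropolis chain whose stationary
distribution is exactly uniform on the graft, making
angiogenic-vs-control scoring a true null for the symmetry tests.

What the generator does **not** emulate: point-spread-function blur,
photobleaching, vessel branching or anastomosis, macrophage shape change,
z-drift, or segmentation-confounding background structures. Passing the
recovery tests therefore shows the *quantitation* is correct given
detectable objects; it does not validate detection against real optics.

## Problem sizes and numerical choices

The test and verification runs use the generator's default problem sizes:
200 random grids up to 16³ against the flood-fill oracle, 5 planted
fractions plus 20 noisy seeds for recovery, 100 seeds per association
preset, 50 dwell tracks for speed ordering, and 10 000 replicates for the
type-I error of the routing. Distance and radius comparisons use a 1e-9
absolute tolerance so that boundary cases (a centroid exactly on a disc rim
or AOI face) resolve inclusively rather than by floating-point accident.
The CCV axis is renormalised on input and rejected below 1e-9 norm.
Deterministic tie-breaks are fixed throughout (component labels by volume
then centroid; control placement by smallest angle; track linking by the
assignment solver's stable ordering), so identical inputs and seeds
reproduce outputs byte for byte.

## Known limitations

* Thresholds are global per channel; there is no adaptive thresholding,
  watershed splitting of touching objects, or deconvolution, none of which
  the reimplemented workflow used.
* Touching macrophages merge into one object and count once.
* Track linking has no gap closing or division handling; occlusion splits
  a track.
* The analysis window and the vessel to analyse are deliberately explicit
  inputs (annotations), since the original selection ("greatest lengthwise
  growth", "period of fastest growth") was a manual judgement; an automatic
  selection helper is out of scope.
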