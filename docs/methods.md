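# Methods

This note documents the models, the synthetic data, the numerical choices
and the limitations of `seegaudit`. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Coordinate conventions

Every image is a `VolumeGrid`: a 3D scalar array plus a 4×4 affine mapping
0-based voxel indices to world millimetres, with a voxel's world position at
its center. All distances, radii and arc lengths are world mm, so
anisotropic grids (e.g. 0.43 × 0.43 × 0.75 mm angiography) are handled
exactly. Rigid transforms are world-to-world 4×4 matrices; registration
*solving* is out of scope — transforms are inputs, and phantoms use the
identity. Out-of-field samples read 0 rather than raising, so probe-eye
review tolerates trajectories near the volume edge.

## Vessel extraction filter

The filter is the standard multiscale Hessian tube measure. At each scale
`s` (default scales 0.25, 0.5, 1.0, 1.5, 2.0 mm; scales below half the
finest voxel are dropped with a warning) the image is smoothed with a
per-axis Gaussian of σ = s/voxel, the Hessian is formed in mm units and
multiplied by s², and its eigenvalues are computed with a closed-form
trigonometric solver vectorized over the volume (checked against
`numpy.linalg.eigvalsh` in the tests). Bright tubes require the two
large-magnitude eigenvalues negative; α = β = 0.5.

Two deliberate choices:

* **DC removal.** The truncated second-derivative Gaussian kernel does not
  sum exactly to zero, so a constant intensity offset would leak into the
  Hessian; the image mean is subtracted first, making the response exactly
  invariant to constant offsets.
* **Study-level structure sensitivity.** The constant `c` defaults to half
  the volume's robust intensity range (0.1–99.9 percentile). In the
  multi-modal pipeline one `c` is derived from the *reference* volume and
  shared across modalities: a modality that shows no vessel must not
  normalize its own noise floor into apparent structure, which is exactly
  what any per-volume normalization (including the common per-scale
  max-Frobenius rule) does on a vessel-free volume. The default
  segmentation threshold, 0.05, sits an order of magnitude above the
  measured noise-floor response and several-fold below the weakest on-axis
  response of a resolvable (≥ 2 voxel) vessel under this calibration.

## Distance fields and the overlap convention

Distance fields are exact Euclidean distance transforms in world mm
(`scipy.ndimage.distance_transform_edt`, sampling-aware; brute-force
nearest-voxel search is the test oracle). An empty segmentation yields an
explicit +∞ sentinel field, which propagates as a "no vasculature" profile.

The per-sample trajectory distance is

    d(s) = max(0, EDT(x(s)) − r_electrode − c_boundary),

with electrode radius 0.4 mm by default (0 reproduces pure-axis behaviour)
and `c_boundary` = 0.3 × the mean voxel size. The boundary term exists
because the EDT measures to segmented voxel *centers*, not to the segmented
surface; for voxelized tubes in 3D the mean overshoot is ≈ 0.3 voxel
(0.5 voxel is the 1D normal-incidence bound — the parallel-tube geometry
test in the suite measures the 3D value). Without the term, an electrode
touching a segmented vessel reads a spurious 0.3–0.6 mm clearance and
grazing conflicts are systematically missed relative to a voxel-overlap
detector.

Two thresholds are deliberately distinct: a *conflict* is overlap
(d ≤ 0, threshold 0), whereas the 3 mm *safety margin* is a planning
quantity used only in the displayed profile and the risk score
(1/N) Σ max(0, (SM − dᵢ)/SM). The risk score is a documented stand-in that
preserves the "cumulative distance from vasculature" semantics; it is not
the canonical published planning metric, whose exact formula is not
restated in the literature this package operationalizes. Below-threshold
runs closer than `merge_gap` = 2 mm along the arc merge into one conflict
(one vessel crossed obliquely, or a bifurcation straddled, must not count
twice); the event sits at the *center* of the run's minimal-distance
samples, which removes a half-run-width bias that taking the first minimum
would introduce.

## Conflict characterization

* **Diameter** is measured on a *caliber mask* — the raw reference volume
  normalized and thresholded at half maximum — rather than on the
  vesselness segmentation, mirroring manual practice of reading calibers
  off the raw angiogram; extraction filters dilate small vessels, and that
  dilation is a known false-positive mechanism, not a caliber. The
  estimator walks from the nearest mask voxel uphill on the interior EDT to
  the local medial ridge and reports twice the inscribed radius there. No
  boundary correction is applied: calibration on rasterized tubes of known
  diameter at random orientations showed the EDT's outward overshoot (to
  background voxel centers) cancels the ridge voxel's off-axis undershoot
  to well under a voxel at the median. A configurable capture radius
  (2 mm) turns measurements away from any vessel into an explicit
  "unresolved" marker instead of a number.
* **Depth** is the arc length from the brain-mask entry point — the paper
  trail for "distance from the cortical surface", with the brain-mask
  boundary as the operative surface definition. The trajectory is extended
  proximally beyond the shallowest contact so the entry is always sampled.
* **Sulcal membership** is a nearest-voxel lookup in the sulcal model.

## Sulcal exclusion model

Mean cortical thickness is estimated by casting rays inward from uniformly
sampled brain-surface voxels along the smoothed-mask gradient normal
(σ = 1 voxel); each ray's thickness is the chord from first gray-matter
entry to first exit (step = ¼ voxel, 30 mm range), and rays that never meet
gray matter are excluded but counted. The intracerebral mask is then eroded
by `margin_factor` × mean thickness — implemented as thresholding the
distance-to-surface field, i.e. exact world-metric erosion, correct on
anisotropic grids where structuring-element iteration is not — and
intersected with the gray-matter mask. `margin_factor` defaults to 1.0
("one cortical thickness below the gyral crown"); the construction order is
fixed but the depth itself is exposed because no canonical value exists.
An erosion deeper than the deepest gray matter yields an empty model with
an explicit warning.

## Electrode reconstruction

Contacts are intensity-weighted centroids of supra-threshold components in
the post-implant CT. Grouping uses spacing-aware chain growing: every
unclaimed pair at ≈ one contact spacing seeds a chain that is extended in
both directions by predicting the next contact one spacing ahead along the
local direction (one missing contact may be skipped); the longest chain is
claimed first. Requiring candidates to occupy a predicted *slot* — not
merely to be near the line — makes the grouping robust to contacts of
crossing electrodes; leftover centroids are reported, never dropped. With a
brain mask, contacts are ordered tip first: the proximal end is the end
carrying extracerebral contacts (the shaft continues through the skull),
with mean half-chain depth as the fallback. Trajectories are piecewise
linear through the contacts — electrode bending is honored only at
contacts, no spline — sampled at 0.5 mm arc steps.

## The phantom: what it emulates, and what it does not

The generator builds, from one seeded `numpy` generator (no global state,
bit-identical reruns):

* **Anatomy.** A spherical brain (radius 0.75 × the grid half-extent;
  24 mm at the default 128³ × 0.5 mm) whose cortical sheet is a
  sinusoidally folded shell: the pial radius is R − A·(1 − cos(2πRθ/λ))/2
  with fold amplitude A (6 mm) and wavelength λ (12 mm), so the gyral
  crown, the sulcal depths and gray/white membership are closed-form
  (`n_folds=1` gives the single-fold phantom used by the exact-equality
  sulcal test). White matter fills the interior; a 3 mm spherical shell
  outside the brain stands in for the skull.
* **Vessels.** Capsule trees: root segments with diameters drawn from a
  lognormal law (median 1.3 mm; σ = ln(1.5/1.0)/(2·0.6745) from the IQR
  ratio — median and IQR as printed are not exactly consistent with one
  lognormal, and the median is honored), bifurcating once with radius decay
  0.79 (≈ Murray's cube root). Half the trees seed in the deep sulcal band
  (down to 0.35 R — deep conflicts require deep vessels, since the chord
  remaining past a conflict at depth D on a vessel at radius p is
  (R² − p²)/D) with calibers capped at 1.25 mm, emulating the observation
  that sulcal vessels are usually the smaller ones; the rest hug the
  cortex. A vessel is rendered into a modality volume iff its diameter
  reaches that modality's visibility threshold (defaults: DSA-like 0.5 mm,
  MRV-like 2.0 mm, T1+Gad-like 2.5 mm — chosen to reproduce the *ordering*
  of modality sensitivities, not any exact percentage). Rendering is
  antialiased max-composited capsules at contrast 100 over Gaussian noise
  (σ = 2).
* **Electrodes.** Straight trajectories planted so the axis crosses a
  chosen reference-visible vessel exactly, at a conflict depth drawn with
  median 31 mm (IQR-ratio σ = 0.850), solved on the cone of directions
  whose spherical-brain entry lies that far from the crossing and refined
  against the actual mask by bisection. Planted trajectories respect
  implantation practice: pairwise axis separation ≥ 2.5 mm (electrode-
  electrode avoidance), tip ≥ 2.5 mm below the surface (no grazing
  chords), tip oblique to the target vessel (≥ 20°), and contact chains of
  adaptive length (up to `contacts_per_electrode`, 12 × 5 mm by default)
  spanning from beyond the entry to the tip, as implanted electrodes of
  varying length do. Contacts render as Gaussian blobs of σ = 1 voxel at
  intensity 1000 — σ = half a voxel would let a blob centered between
  voxel centers drop below half its nominal sampled amplitude and vanish
  at the 50 % detection threshold.
* **Ground truth.** The manifest is built by an analytic arc-length sweep
  that mirrors the detector's semantics exactly: contact runs (axis
  distance ≤ electrode radius + vessel radius) along each trajectory,
  merged below 2 mm, one conflict per run at the closest surface approach,
  flagged `planted` when it contains a deliberately targeted crossing and
  otherwise recorded as an incidental crossing. Every entry satisfies the
  point-to-segment conflict condition by construction (verified by brute
  force in the tests). The *reference* conflict set — the stand-in for
  conflicts a reviewer could verify on raw reference images — is the
  manifest restricted to vessels visible on the raw reference modality.

Features of real data the phantom does **not** emulate: MR/CT physics and
artifacts, contrast kinetics, deformable anatomy, vessel tortuosity beyond
piecewise-straight capsules, arterial/venous distinction, and real cortical
folding geometry. Passing tests therefore demonstrate the correctness of
the *audit machinery* under known geometry — not clinical performance on
patient images.

Scale matters for depth statistics: the phantom brain is ≈ 4× smaller than
life, so although conflict depths are *drawn* from a law with median 31 mm,
feasibility (a straight chord must reach that depth and still bury its tip)
rejects the deepest draws and realized planted depths have a smaller
median. All recovery checks compare recovered statistics against the
*realized* planted values on the same phantom, so the comparison is
unaffected by the truncation.

Incidental crossings can graze a vessel by arbitrarily little; contacts
shallower than ≈ 0.1 mm are below what any voxel-overlap detector (or
reviewer at 0.4 mm imaging resolution) resolves, and they remain in the
manifest as honest false negatives of the automated detector. Deliberately
planted conflicts pass through the vessel axis and carry no such ambiguity.

## Problem sizes

The acceptance pipeline runs at 128³ voxels × 0.5 mm with 40 vessels and 40
electrodes (≈ 2 minutes on one CPU); unit tests use 48³–96³ grids. These
sizes were chosen so the full study-shaped workflow — three modality
filters, distance fields, sulcal construction and the audit — exercises
every code path at realistic voxel resolution while medians stabilize over
≈ 40–55 conflicts.

## Known limitations

* The diameter estimator is voxel-quantized (inscribed-sphere radii live on
  the lattice-distance set), so recovered diameter *medians* jump between
  lattice values such as 1.0 and √2 at 0.5 mm voxels; accuracy is ± one
  voxel, not better.
* Greedy nearest-pair conflict matching is not globally optimal; on
  conflict sets denser than the 3 mm tolerance it can differ from optimal
  assignment (the tests include a case where greedy and exhaustive
  matching agree by construction).
* The χ² comparison uses the plain 2×2 statistic without continuity
  correction by default (a Yates toggle exists); expected-cell warnings are
  attached to results rather than raised.
* Electrode labels assigned by the reconstruction are arbitrary and do not
  match planted labels; cross-referencing is positional.
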