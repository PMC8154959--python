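# Methods

## Problem and model

Serial coronal sections of an embryonic mouse head, H&E-stained and
photographed individually, lose two things that must be restored before 3D
morphometry: the mutual in-plane pose of consecutive slices (each section is
placed on its slide with an arbitrary shift and rotation) and the physical
scale along the cutting axis. `palate3d` models each section as a 2D rigid
motion of a slowly varying anatomical cross-section and reconstructs the
stack as an anisotropic voxel volume: in-plane spacing is the camera's
µm/px, axial spacing the section thickness (7 µm by default).

The segmentation target is the oral-cavity silhouette: in the green channel
the unstained lumen is bright and H&E tissue dark (both dyes absorb green),
so a fixed mid-scale threshold separates them once noise has been averaged
out. The cavity is taken to be the largest 8-connected bright component;
smaller bright regions on a head section are noise or unrelated lumina.

## Pipeline parameters

| parameter | default | unit | role |
|---|---|---|---|
| `filter_window` | 15 | px | mean-filter side; 225 px per interior mean |
| `threshold` | 0.5 | — | binarization level on [0, 1] green intensity |
| `connectivity` | 8 | — | component adjacency (4 available for tests) |
| `min_area_px` | 64 | px | floor below which a "cavity" is degenerate |
| `pixel_size_um` | *required* | µm/px | in-plane scale; no safe default exists |
| `section_thickness_um` | 7.0 | µm | axial scale |
| `reference` | middle | — | alignment anchor slice |
| `max_rot_deg` | 10 | ° | rotation beyond which moments alone decide |
| `smooth_iterations` | 10 | — | Taubin passes |
| `spike_iqr_factor` | 3.0 | — | outlier cutoff: median + f·IQR |

Thresholding is strictly greater-than: after normalizing 8-bit values to
[0, 1] no pixel can sit exactly at 0.5, so `>` vs `>=` differ only on
synthetic inputs, and the strict form is what the tests pin down. The mean
filter replicates edges rather than zero-padding, because zero padding
darkens the ROI border and can carve a false cavity boundary there. Area
ties in component selection go to the component whose first raster-scan
pixel comes first — deterministic and independent of label numbering.

## Registration

The estimator is intensity-free, operating on the binary cavity masks:

1. **Translation** — difference of mask centroids, sub-pixel by
   construction.
2. **Rotation** — difference of principal-axis angles from second central
   moments. The axis is defined modulo π; the angle is wrapped into
   [−90°, 90°], the only branch physically possible for sections cut 7 µm
   apart. The π-complement is deliberately *not* scored against the overlap
   objective: cavity cross-sections are nearly 180°-symmetric, and letting
   a hair-thin Dice margin decide the branch flips entire stack halves.
3. **Polish** — a soft-Dice (bilinearly warped mask) grid search over θ in
   ±0.5° at 0.05°, two rounds with the second 10× finer, translation
   re-derived from centroids at each candidate. The window is narrow on
   purpose: the moment initializer is accurate to a small fraction of a
   degree whenever the mask is elongated, whereas a wide overlap search can
   be pulled degrees off-pose by asymmetric change of the anatomical
   cross-section between neighboring slices. A zero-rotation candidate is
   scored only when the mask is nearly isotropic (second-moment eigenvalue
   ratio < 1.5), where the principal axis is meaningless.

Pairwise transforms between consecutive non-degenerate slices are composed
outward from the middle slice, halving worst-case drift relative to
anchoring at slice 0. Degenerate slices inherit the nearest non-degenerate
neighbor's composed transform (predecessor on ties) and are filled from
that neighbor's plane during volume assembly.

On phantom stacks with i.i.d. per-slice jitter of 5 px translation sd and
3° rotation sd, alignment recovers slice poses with ≈0.4 px / 0.3° mean
residual (the acceptance suite asserts ≤ 1 px / 1°, over 10 seeds).

## Surfaces

Meshes come from marching cubes on the 0.5 iso-level of a label's indicator
field, zero-padded by one voxel so boundary-touching structures close, with
vertices scaled into µm (anisotropy is honored in vertex coordinates, not
resampled away — resampling would only interpolate, never add, axial
information). Spike removal snaps vertices whose one-ring-centroid distance
exceeds median + 3·IQR of that statistic back onto the centroid; the
criterion is scale-free and leaves regular meshes untouched. Smoothing is
Taubin's two-step scheme (λ = 0.5, µ = −0.53), which damps surface noise
without net shrinkage — on a noisy sphere 10 iterations remove >50% of RMS
radial noise while moving the enclosed volume <5%. The proprietary mesh
clean-up steps of commercial reverse-engineering suites that inspired these
two operations are GUI buttons without published definitions; the
replacements here are explicit, deterministic algorithms of equivalent
intent. STL output is geometry-only (binary); PLY carries the structure's
display color (shelves orange `(255,165,0)`, tongue pink `(255,192,203)`,
other structures gray).

A single voxel meshes to the octahedron through its cell-edge midpoints
(volume 1/6 voxel); mesh volume converges to the voxel count as resolution
grows, and the two agree within 5% at working resolutions.

## Phantom

The generator is the package's ground-truth instrument. It voxelizes
ellipsoids, cuboids and extruded polygons (µm-parameterized; later shapes
overwrite earlier on overlap), renders each z-plane with green-channel
levels 0.15 (tissue) / 0.85 (cavity) — symmetric about the 0.5 threshold,
so straight boundaries land sub-pixel under the mean filter — adds seeded
Gaussian intensity noise (sd 0.08, clipped), and warps each slice by a
seeded rigid jitter recorded in the truth object, exactly what registration
must invert. Red/blue channels mimic H&E hue and are provably cosmetic
(tests scramble them). A spec is rejected unless the tissue/cavity gap is
at least 3 noise sd (threshold separability by construction) and every
shape stays in frame under 3-sd-clipped jitter.

Two presets emulate a palate/tongue series in a 1 × 2 mm field at
2.5 µm/px and 7 µm sections: `pre-elevation` (160 base slices; midline
tongue ellipsoid, two vertical shelf slabs) and `elevating` (200 base
slices; one shelf horizontal above a laterally shifted tongue, one still
vertical). `size_factor` scales the scene — image, slice count, shapes and
the µm-denominated translation jitter (12.5 µm ≈ 5 px at full scale) — so
desk-scale runs keep the same relative geometry. Tests and the acceptance
script run at size factors 0.25–0.5, a deliberate compromise between
fidelity and runtime; at 0.25 an `elevating` stack is 50 slices of
100 × 200 px and the full pipeline takes a few seconds.

What the phantom does *not* emulate: sectioning tears and folds, stain
batch variation, uneven illumination, out-of-plane (banana) distortion,
and anatomy whose cross-section changes faster than the slice spacing.
Passing the phantom suite therefore demonstrates correctness of the
algorithms under the stated imaging model, not robustness to every failure
mode of real histology; on real data the per-slice QC table (areas,
centroids, degeneracy flags) and the transform table are the intended
first-line diagnostics.

## Numerical and degenerate-input choices

- Rasters are 8-bit RGB internally; grey images float64 in [0, 1].
- Mask warps use nearest-neighbor (masks stay binary); grey/RGB warps are
  bilinear; off-frame regions fill with background (phantom rendering fills
  with tissue level instead, so jitter does not create false bright
  borders).
- An empty mask is a value, not an error: it is flagged degenerate,
  skipped during registration, inherits a neighbor transform, and its
  volume plane is copied from the nearest good slice. Only an
  all-degenerate stack aborts.
- Volume measurement is exact arithmetic (count × voxel volume); additive
  over labels and invariant to axis permutation with permuted spacing.
- Reruns with identical config are bit-identical; artifact checksums are
  part of the run manifest and asserted in tests.

## Known limitations

- Rigid-only alignment: no correction for section stretching or the
  cumulative curvature ("banana") artifact of chain registration.
- A structure entering the cross-section abruptly between two adjacent
  sections shifts the mask centroid in a way no pairwise mask registration
  can separate from true translation; on the phantom presets this costs
  up to ~1 px at shelf onset/offset and is inside the 1 px recovery budget.
- Rotation is unobservable for genuinely isotropic cross-sections; the
  estimator then returns the overlap-best small rotation, which is also
  the case where rotation does not affect the reconstruction.
- Separating tongue from shelves on real data requires user-supplied
  per-slice label rasters; image analysis alone cannot name structures,
  and phantoms carry their labels in the ground truth instead.
- The published workflow's in-plane pixel size is unknown; real-data
  volume measurements are only as good as the `pixel_size_um` the user
  supplies.
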