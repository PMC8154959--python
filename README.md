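# palate3d

Reconstruction of 3D surface models of the embryonic palatal shelves and
tongue from serial 2D histological sections.

During mouse secondary-palate development (~E12.5–E13.5) the paired palatal
shelves reorient from vertical, flanking the tongue, to horizontal above it.
Studying this elevation in 3D requires turning stacks of 150–250 H&E-stained
coronal sections (7 µm thick, photographed individually) back into measurable
3D geometry. `palate3d` is a tested, scriptable pipeline for that task,
aimed at developmental biologists and image-analysis engineers working with
serial-section brightfield histology.

## Method

For each section image *I* (RGB, bright unstained lumen on dark H&E tissue):

1. **Greyscale** — keep the green channel, *g = G/255 ∈ [0, 1]*: both
   hematoxylin and eosin absorb strongly in the green band, maximizing
   tissue/cavity contrast.
2. **Denoise** — 15×15 square mean filter (225 pixels per interior value),
   edge-replicated borders.
3. **Binarize** — threshold at 0.5 (strictly greater), bright = foreground.
4. **Segment** — label 8-connected foreground components and keep the
   largest as the oral cavity; components below `min_area_px` count as
   degenerate (damaged slices are carried, not fatal).
5. **Register** — estimate a per-slice rigid transform
   *T(p) = R(θ)(p − c) + c + t* from binary-mask moments (centroid +
   principal axis) polished by a soft-Dice rotation search; pairwise
   transforms between consecutive slices are composed outward from the
   middle reference slice.
6. **Reconstruct** — stack the aligned masks into an anisotropic labeled
   voxel grid (e.g. 2.5 × 2.5 × 7 µm), measure volumes as
   voxels × voxel volume, extract the 0.5 iso-surface with marching cubes,
   snap spike vertices to their one-ring centroid, apply Taubin smoothing
   (λ = 0.5, µ = −0.53, 10 iterations) and export binary STL and/or
   colored PLY (shelves orange, tongue pink).

A phantom generator (`palate3d.phantom`) renders synthetic section stacks —
a lumen body, tongue and two shelf silhouettes with seeded Gaussian noise
and recorded per-slice rigid jitter — so every stage is validated against
exact ground truth.

## Worked example

```python
import palate3d as p3

spec  = p3.embryo_preset("elevating", size_factor=0.25, seed=1)
truth = p3.build_truth(spec)              # exact labeled volume + volumes
stack = p3.render_stack(truth, spec)      # noisy, jittered RGB sections

masks   = p3.segment_stack(stack)         # per-slice cavity masks
aligned = p3.align_stack(masks)           # rigid alignment to mid-slice
vol     = p3.assemble_volume(aligned, spec.spacing)

v_rec  = p3.measure_volume(vol, 1)
v_true = truth.cavity_volume_um3
print(f"true cavity volume  {v_true/1e6:.3f} x10^6 um^3")
print(f"reconstructed       {v_rec/1e6:.3f} x10^6 um^3")
print(f"error               {100*(v_rec-v_true)/v_true:+.2f}%")

mesh = p3.smooth_mesh(p3.remove_spikes(p3.extract_surface(vol, 1)))
p3.export_mesh(mesh, "cavity.stl")
print(f"mesh volume         {mesh.enclosed_volume_um3/1e6:.3f} x10^6 um^3")
```

Output:

```
true cavity volume  8.418 x10^6 um^3
reconstructed       8.316 x10^6 um^3
error               -1.21%
mesh volume         8.315 x10^6 um^3
```

The reconstructed voxel volume sits ~1% below truth (boundary rasterization
under the fixed threshold), and the cleaned, smoothed mesh agrees with the
voxel count to within 0.1%.

The same flow runs from the shell on real data:

```sh
palate3d phantom --stage elevating --seed 7 --size-factor 0.25 --out demo/
palate3d run -c config.yaml          # input_dir, roi, pixel_size_um, ...
palate3d qc transforms out/transforms.csv
```

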