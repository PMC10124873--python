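# Methods

## Problem and model

An ASD occluder is a woven nitinol double-disk implant; after implantation,
neo-tissue grows over its faces. In an ex-vivo micro-CT reconstruction
(16-bit AU scale, isotropic voxel size, 41.7 μm in the motivating setting)
the metal is the brightest class, covering tissue is mid-intensity, and
background is dark. Coverage of a disk is defined *per XY pixel column*: a
column counts as covered when tissue voxels are encountered before the first
occluder voxel while traversing z from the atrial cavity inward, uncovered
when the occluder is reached first, and as background when the column holds
no occluder. The disk's coverage percentage is the covered share of
occluder-bearing columns, and tissue thickness per column is the number of
tissue voxels seen before the surface times the voxel size. This definition
requires a *solid* occluder surface — a raw wire segmentation would let rays
pass through mesh gaps — which is what the distance-fill stage provides.

## Pipeline stages and their parameters

**Wire segmentation.** `metal_threshold` (AU, default `"auto"`): Otsu's
method restricted to intensities strictly above the 90th percentile, with
the cut placed mid-gap between Otsu's two classes so inclusive (≥)
thresholding cannot swallow the lower class. The auto rule presumes the
non-device bulk (sample container, most myocardium) is outside the ROI, as
it is after the usual manual trim of a scan; for phantoms, where the known
class intensities make a fixed cut exact, the phantom-scale configuration
passes 40000 AU explicitly. Only the largest 26-connected component is
kept, removing supports and bright specks without manual editing.

**Alignment.** The device axis is the eigenvector of the wire-voxel
coordinate covariance with the *smallest* eigenvalue (the two disk planes
carry the large variances). The minimal rotation mapping it to +z is applied
about the volume center — linear interpolation for intensities, nearest
neighbour for masks. Degenerate covariances (fewer than three voxels, or
collinear voxels) are rejected. Axis sign follows the +z convention; which
atrial side sits at low z is metadata (`flip_z`).

**Solid-surface estimation.** The chamfer distance transform uses the
classic two-pass sweep with integer weights (face, edge, corner) =
(3, 4, 5)/3 augmented by the knight-type step (2, 1, 1) at weight 7/3. The
augmentation bounds the worst-case deviation from Euclidean distance to
+5.4 % / −5.7 % (a Dijkstra sweep over all directions; the plain (3,4,5)
mask errs up to +10.6 % toward (3,1,1)), while face steps stay exact so a
threshold expressed in voxels keeps its axial physical meaning. An exact
Euclidean backend (`scipy.ndimage.distance_transform_edt`) is selectable
and serves as the oracle in tests. Thresholding the distance map at
`distance_threshold_vox` (default 70 ≙ 2.919 mm at 41.7 μm) bridges every
mesh gap of pitch below twice the reach. The subsequent **erosion** uses
radius equal to the fill threshold, making fill + erosion a morphological
closing of the wire mask in the same metric: the result provably contains
the wire and returns to the original wire thickness along face directions.
(An erosion radius reduced by half the wire thickness, sometimes suggested
by analogy with centerline distances, leaves a slab of roughly *twice* the
wire thickness, because the distance map measures from the wire *material*,
whose fill is already w + 2T thick.) A **closing** of radius
`closing_radius_vox` (default: the wire thickness) removes pinholes; its
erosion half uses the open ball (keep distance ≥ r) because discretized
face pits over mesh gaps sit at exactly the closing radius from the dilated
complement and a strict comparison would never reclaim them. Structuring
elements are metric balls realized by distance thresholding, for isotropy
and for speed at large radii.

**Tissue segmentation.** Voxels inside the reduced occluder are zeroed;
tissue is every remaining voxel ≥ `tissue_threshold_au` (default 15000 AU on
the raw 16-bit reconstruction scale; applied inclusively so results are
bit-reproducible). By default the mask is intersected with the fill-reach
envelope (distance ≤ threshold from the wire) so bright structures far from
the device cannot count as covering tissue; myocardium *inside* the
envelope but behind the disk faces is harmless because the column scan
stops at the first occluder voxel. An optional minimum-component filter is
off by default to stay close to the plain thresholding pipeline.

**Splitting and scanning.** The split plane is the z index of minimum
cross-sectional area between the two largest area peaks — evaluated on the
*wire* mask: the filled occluder has no such minimum, since a fill reach
far exceeding the inter-disk separation necessarily closes the space
between the disks (true for the real device geometry as well). Ties resolve
to the middle of the minimal plateau, so symmetric devices split into equal
halves. The low-z half scans +z, the high-z half −z; thickness counts all
tissue voxels before the surface, contiguous or not. Disks with no
occluder-bearing column report *missing* (NaN) coverage, distinguishing
"no device" from "0 % covered". Cohort tables give median, mean and
population SD (ddof 0, so a single-device group reports 0) per side and
follow-up group.

## The phantom generator

`PhantomSpec` defaults define the standard study-like phantom: a
128×128×96 grid at 41.7 μm, two mesh disks of radius 40 voxels (two
orthogonal straight-spline families at pitch 10 plus a rim ring, wire
4 voxels ≈ 170 μm) joined by a tubular waist of radius 8 across a 30-voxel
separation; tissue caps on the outer faces with a per-side coverage
fraction and pattern (annulus from the rim, disk from the center, or a
thresholded smooth random field); a myocardium annulus in the inter-disk
plane; intensities metal 60000 / tissue 25000 / myocardium 18000 /
background 5000 AU (the intensity ordering metal > tissue > 15000 >
background is enforced — the absolute values are configurable choices, as
no reference nitinol AU value is available); optional additive Gaussian
noise (clipped to 16 bits) and rigid rotation with linear interpolation.
Ground truth — wire/tissue masks, the ideal solid occluder, per-disk
coverage percentages (a direct pixel count of covered footprint pixels over
footprint pixels, i.e. the same definition the scanner applies) and
thickness maps — is stored in the unrotated, noise-free frame, and the
applied rotation matrix is kept so alignment can be validated against it.

**Scaled fill reach.** At this phantom scale the fill reach is 18 voxels
(`PHANTOM_FILL_REACH_VOX`), not 70: the reach must exceed the mesh
half-gap diagonal (≈ 4.2 voxels) to bridge gaps, and must stay below the
29-voxel margin beyond the outer faces so the fill retains an in-grid
background complement for the erosion — a 70-voxel reach from any wire
voxel would cover the entire 96-deep grid and leave the erosion undefined.
The printed full-scale constant (70 voxels × 41.7 μm = 2.919 mm) is checked
analytically from the default `FillParams`, which are unchanged.

**What the phantom does not emulate.** No projection/reconstruction
physics: no beam hardening, ring artefacts, or metal blooming beyond what
interpolation produces; noise is i.i.d. Gaussian rather than correlated
reconstruction noise; the mesh is a woven lattice of straight splines, not
the true braid (the quantification only needs gaps below the fill reach);
orientation markers are carried as metadata, not simulated. Passing the
phantom suite therefore validates the geometry and logic of the pipeline,
not its robustness to acquisition artefacts. One consequence observed in
testing: when a phantom is rotated and then re-aligned, the double
interpolation smears metal into mid-range intensities just outside the
recovered surface, which can inflate apparent coverage by tens of points on
a sparsely covered disk — axis recovery itself stays below 1°. Real scans
are reconstructed once, but the analogous partial-volume/blooming halo is a
known limitation of intensity-threshold tissue segmentation near metal.

## Numerical and design choices

* Volumes are `(y, x, z)` arrays with slices stacked on the last axis;
  voxel size always travels as explicit metadata (μm), never read from TIFF
  tags. Slice files order by natural-numeric filename sort.
* Distance-based morphology treats out-of-grid as foreground for erosion
  and background for dilation, avoiding spurious border erosion.
* The tissue threshold is inclusive; the metal threshold is inclusive.
* The coverage percentage is pixel-based (physical-area weighting is
  identical at isotropic resolution).
* The synthetic 8-device cohort fixes per-device coverage fractions so the
  cohort medians match the reported distribution of the motivating study
  (left 93 %, right 55 %, 1-month right 41 %), with edge-only right-disk
  coverage on devices 1–5 and near-full coverage on 6–8; thickness is
  4 voxels on left caps vs 2 on right, echoing the thicker left-side
  healing response. These are generator inputs, not fitted values; the
  recovered medians (≈ 91 / 54) carry the pipeline's ~1–2-point rim bias.
* Problem sizes in the validation runs — 128×128×96 phantoms, 200 random
  ≤16³ masks for the distance oracle, 8-device cohorts — were chosen so
  each check isolates one property at a size where the brute-force oracle
  is exact.

## Known limitations

* Coverage near the disk rim carries a ±1-voxel discretization band from
  the closing (≈ 1–2 percentage points at a 40-voxel disk radius).
* The erosion/closing kernel sizes of the original description are not
  published; the regime here is one consistent realization validated
  against its stated goal (wire-thickness restoration with gaps kept
  filled), not against the original implementation.
* Whether the 15000 AU tissue threshold applies before or after any
  rescaling of the reconstruction is unstated upstream; it is treated here
  as the raw 16-bit scale.
* Meshes whose pitch exceeds twice the fill reach are out of scope, as are
  DICOM/NIfTI input, marker-based anatomical orientation, and multi-class
  tissue typing (micro-CT cannot resolve the histological layers).
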