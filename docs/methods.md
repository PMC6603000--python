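# Methods

This note records the models, conventions and design choices behind
`rosellapipe`: what each stage computes, the parameters that matter, what
the synthetic fields do and do not emulate, and the numerical policies at
the edges.

## Imaging model and geometry

All quantities live on the 16-bit camera graytone scale.  A voxel is
0.2152 µm × 0.2152 µm laterally and 400 nm axially, so volumes convert as
`voxels × 0.2152² × 0.4 = voxels × 0.018524 µm³`.  Rosella-LC3 fields have
5 z-planes, ATP5C1-Rosella and lysotracker fields 11.  Because the stacks
are so anisotropic, every convolution and grayscale-morphology filter runs
plane-by-plane with a 2D kernel, while connected components, size filters
and volume statistics are 3D with 26-connectivity (8-connectivity in 2D).
Kernels written "size s, sd σ" are square s × s truncated Gaussians
normalised to unit sum; the spatial border policy is symmetric
(edge-repeating) padding.  Thresholds stated as strict inequalities are
applied strictly; size-window bounds are inclusive.

## Preprocessing

**Flatfield.** The correction divides by the adjustment-plate reference
(Gaussian-smoothed, σ = 20 px, to keep reference shot noise out of the
data) and rescales by the reference mean, so a uniform reference is a
no-op.

**PSF.** A scalar Gaussian-approximation PSF: lateral FWHM 0.51 λ/NA,
axial FWHM 1.77 n λ/NA², sampled on the voxel grid and normalised.
Emission wavelengths default to the instrument's bandpass filters (520 nm
pHluorin, 600 nm DsRed, 690 nm lysotracker deep red), NA 1.2,
water-immersion n = 1.33.  The PSF only initialises deconvolution, whose
consumers are threshold-based masks, so a vectorial high-NA model would
change nothing downstream; only the Gaussian model is implemented.

**Deconvolution.** Richardson–Lucy, 10 iterations, implemented directly
with circular FFT convolutions on a mirror-doubled volume.  The mirror
tiling is exactly periodic, so the updates see no boundary discontinuity:
a constant image is an exact fixed point and flux is conserved to within a
few percent for interior objects.  The default keeps the PSF fixed
(bit-reproducible); an optional blind mode alternates a multiplicative PSF
update with each image update.

## Channel masks and classification

The mask cascade follows the platform's reference parameter set exactly (all
of them live in `PipelineConfig`, and the frozen copy in
`rosellapipe/data/reference_defaults.yaml` is diffed against the code defaults
in the test suite).  Conventions that the original workflow description leaves open:

* **Overlap fraction** is always `|component ∩ mask| / |component|`.
* **Watershed splitting**: the Euclidean distance transform is computed on
  the complement of dsRedMask1, markers are dsRedMask1 components,
  watershed lines are excluded, and the resulting region stencil is ANDed
  with the confirmatory second band-pass mask.  The final red pool is the
  OR of dsRedMask1 and that stencil, so it can never lose seed voxels.
* **Ratio image**: both raw channels are blurred (5 px / σ 2) before the
  element-wise division; the red denominator is clamped at 1 graytone.
  The complement is taken against the per-field maximum.
* **Autolysosome rescue**: candidates are top-hat (disk 15) of the
  complemented ratio above 1.5 (on the ratio scale); retention requires a
  neighbourhood (in-plane dilation ring, disk 7) at least 50% brighter in
  mean raw green (ties retain) and more than 100 voxels.
* **Late-autolysosome Case 1** is read as: at least 25% DsRed-mask overlap
  AND (pHluorin overlap < 10% OR median ratio ≤ 2).  Distributing the red
  requirement over the alternative keeps the early-autolysosome class and
  the rescue-mask route reachable for acidified vesicles, which is the
  mask's stated purpose; the alternative reading (a bare `ratio ≤ 2`
  branch) would swallow every acidified vesicle into the late class.
* **Centre/surface comparisons** use mean raw green in the 1-voxel-eroded
  interior (3D ball) versus the surface shell; "25% brighter" means
  centre ≥ 1.25 × surface.  On components too thin for the 3D erosion an
  in-plane disk(1) erosion is used; if that is empty too, centre and
  surface are set equal so neither strict comparison can fire.
* **Eccentricity** (> 0.9 → non-circular) and lysosome major axes are
  measured on the z-maximum projection via normalised second central
  moments — five-plane stacks are too thin for 3D ellipsoid fits.
* **"3rd quantile"** is the 75th percentile of raw voxel intensities;
  "median ratio" the median ratio-image voxel within the vesicle.
* Vesicles failing every rule are kept as `unclassified` rather than
  dropped, so counts always sum to the total.
* The autophagy rate-constant is phagophores / autophagic vacuoles (the
  stated order of the defining ratio); a field without vacuoles reports 0 with
  `rate_defined=False`.
* The 0.0–2.0 well heatmap divides each well's count by its category mean
  and clips to [0, 2]; min–max rescaling into the same interval is
  available as a config option.

**Sphericity indices.** The exact index formulas are an open choice here, so the package adopts
its own definitions, isolated in `autophagosomes.sphericity_indices`: Idx1 is
projected circularity `1.2 · 4πA/P²` (Crofton perimeter), scaled so an
ideal rendered sphere scores ≈ 1.2, which cleanly separates compact bodies
(> 1) from filaments (≪ 1); Idx2 is the border-to-centre intensity ratio
of the deconvolved green channel (mean over the in-plane
distance-to-edge ≤ 2 px band over mean around the distance maximum), which
scores hollow bright-rim/dim-lumen profiles well above the 1.5 threshold
and solid or flat profiles below it.  An earlier interior-over-shell
variant was rejected because on 5-plane slab geometry it cannot
distinguish a filled candidate of a hollow vesicle from a solid body.

## Mitophagy and the resource split

Mitochondria are segmented on the raw DsRed channel (no deconvolution is
involved in this branch).  Event seeds are 26-connected components of the
mitochondrial mask with mean ratio below 0.6; the event mask is the binary
reconstruction of the band-pass limit (> 50) from those seeds, so every
event lies inside the limit and touches a seed — both asserted invariants.
The resource split subtracts the ATP5C1 event frequency from the LC3
autophagic-vacuole frequency to model non-mitochondrial autophagy and
expresses both against their basal references as percentages; negative
post-subtraction frequencies clamp to zero with a warning, zero basal
denominators yield NaN.  Frequencies are per-field means within a
condition; both count-based and volume-based event measures are computed.

## The synthetic fields

The generator renders what the decision tree is designed to read, at the
acquisition geometry of the real instrument:

* phagophores: small solid bodies (r 2–3.2 px), green 9000 / red 3000
  over a cytosolic background of green 1200 / red 150;
* autophagosomes: rings (outer r 6–8.5 px, rim 2.8 px) bright in both
  channels (green 1300 / red 2500), rendered as an annulus in every plane
  the equator spans — a thin confocal slab through a large hollow vesicle
  images as rings, so no polar caps are drawn;
* early autolysosomes: large solid bodies (r 7–8 px), red 900, diffuse
  green 1100 plus a residual non-acidified cargo patch (+1700 green,
  0.40 r) that produces the class's defining partial pHluorin-mask
  overlap with an overall median ratio just above 2;
* late autolysosomes: solid red 4000, green quenched 600 below cytosol;
* ATP5C1 fields: red tubules (random walks, radius 1.4 px) with matching
  green (healthy ratio ≈ 1), and detached event bodies (red 6000, green
  quenched) over a green-dark cytosol — the reporter sits on mitochondria,
  so unlike the LC3 construct there is no bright cytosolic green.  Tubules
  are kept clear of event bodies: a tubule brushing an event would fuse
  the two into one connected component and dilute the ratio seed.
* optics and noise: per-channel Gaussian PSF blur, a radial vignette
  (amplitude 0.15), Poisson noise at 4 photons per graytone (a bright
  spinning-disk acquisition) and Gaussian read noise (σ 5).

Intensity levels are a fixed calibration, chosen once so that each class
sits on the correct side of the pipeline's decision thresholds at this reference
signal-to-background; `scripts/calibration.py` prints the per-threshold
margins.  Identical spec + seed gives bit-identical stacks.

What the simulator does **not** emulate: cell boundaries and cytoplasm
texture, object shape irregularity, vesicle clustering and partial
overlap, depth-varying PSFs, photobleaching and stage drift.  Passing the
ground-truth-recovery tests therefore shows that the implemented decision
tree and mask cascade are internally consistent and recover the signatures
they were designed for — not that the thresholds are optimal for any
particular microscope's data.

## Problem sizes

The validation batteries use 10 fields per condition at 256 × 256 × 5 (11
for mitochondrial fields) in the test suite, and 8 fields per condition in
`scripts/acceptance.py`; one Rosella-LC3 field takes roughly 15–20 s
single-threaded, dominated by the deconvolution FFTs and the Hough sweep.
The basal mixture (9 phagophores, 4 autophagosomes, 4 early and 14 late
autolysosomes per field) mirrors the reported pattern of abundant pathway
endpoints and transient intermediates and gives a designed basal
rate-constant of 9/22 ≈ 0.41; the chloroquine-like condition elevates
phagophores + autophagosomes, the CCCP-like condition raises mitophagy
events (3 → 8 per field) while reducing LC3 vacuoles.

## Known limitations

* The circle-Hough route's red-dimness validation (0.9-quantile < 300)
  rejects circles over red-bright vesicles by construction, so on the
  synthetic fields — where every autophagosome is DsRed-positive — ring
  recovery is carried almost entirely by the Fourier/Euler route; the
  Hough route contributes for green-only rings.
* Very bright thin rims produce Butterworth side-lobes that can register
  as concentric one-hole components; the shape filter rejects the merged
  giants, which can cost the enclosed true ring.  The simulator's rim
  intensities keep side-lobes below the 150 graytone mask threshold.
* Deconvolution inflates apparent volumes relative to pre-optics geometry
  (z-spread especially); detection metrics against ground truth are
  therefore voxel recall and object counts, not absolute mask volumes.
* Field-level statistics only: the platform deliberately does not segment
  single cells.
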