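# Methods

This note records the models behind `scoutrange`, the parameters that
matter, the numerical conventions, and what the synthetic benchmark does
and does not demonstrate.

## Coordinate conventions

Volumes are `(slice, row, col)` with slice 0 most superior; `z` is in
millimetres at slice centres and increases caudally. Scan ranges are
inclusive limits at slice centres, so a single-slice range has equal
superior and inferior `z`. Every 2D projection carries an affine
`z(r) = z0 + r·dz`; resizing updates `(z0, dz)` with the pixel-centre
convention, so limits read off a 256×256 image refer back to patient
millimetres without bookkeeping by the caller.

## Synthetic thorax phantom

The phantom is a deliberately simple but adversarial geometry: an
elliptical soft-tissue cylinder (default AP×lateral diameters
23.3 × 31.1 cm, a typical adult habitus), a posterior bone column, and two
lung ellipses whose

* apices taper to a point over `apex_taper_mm` (default 30 mm), and whose
* inferior border is slanted by `costophrenic_slant_mm` (default 40 mm),
  posterior recesses reaching further caudally than the anterior border.

The slant is the clinically hard feature: the most inferior lung slices
contain only a thin posterior sliver, which projects to a depression of a
few per mille of the image intensity — the reason human operators overshoot
inferiorly. Tissue values are air −1000, lung −800, soft tissue +40, bone
+700, consolidation −100 HU; only the contrasts matter downstream.
Pathology is modelled as random consolidation blobs replacing a configured
fraction of lung voxels (the ground-truth mask still covers them); noise is
additive Gaussian HU noise (default SD 15). No beam hardening, scatter,
respiratory motion or non-thoracic anatomy is simulated.

The ground-truth mask is exactly the voxel set assigned lung HU before
pathology and noise, so generator self-consistency (mask ↔ stored range)
is testable bit-exactly.

Tube-current modulation uses the attenuation-power law
`mA_i = base · (A_i / mean A)^γ` with `A_i` the slice sum of
`max(HU+1000, 0)`, clipped to `[0.2, 3]·base` (defaults 150 mA, γ = 0.8) —
the craniocaudal rise over denser slices that real TCM produces.

### Operator model

Operator-selected ranges are the true lung range extended cranially and
caudally by independent Normal draws. Defaults (superior 25.7 ± 12.3 mm,
inferior 37.3 ± 21.9 mm) reproduce single-centre clinical summary
statistics for technologist-selected chest ranges. Draws are truncated at
zero by default, since clinical audits find overscan rather than missed
lung in the overwhelming majority of cases; `allow_negative=True` gives the
untruncated model used for statistical parameter-recovery checks. The
Normal form is an assumption — clinical reports publish only means, SDs and
quartiles, not a distribution.

## Projections

Scout views are emulated as line integrals of `max(HU + 1000, 0)` along the
AP or lateral axis (air contributes zero, pixels are non-negative, as on a
radiograph), multiplied by the step along the ray. Raw HU sums would give
negative pixels and were rejected. Masks are projected by logical OR, which
guarantees exactly that a slice contains lung iff its projection row does —
the property that makes 2D range reading equivalent to 3D range reading at
native resolution.

Normalization is per-image min–max to [0, 1], applied after resizing so the
output range is exactly [0, 1]; the record of method and parameters is kept
on the projection. Resizing is bilinear (anti-aliased when downsampling)
for intensity and nearest-neighbour for masks; non-square inputs are
resized anisotropically to 256×256 without padding.

Scout magnification is modelled as a pure transverse scaling
`M = SDD/(SDD − y)` about the image centre, `y` the object plane's offset
from isocenter along the beam axis. Rows are untouched because scout
acquisition translates the table along z; consequently craniocaudal range
limits are invariant under the distortion. Masks are forward-splatted
(never inverse-sampled) so a one-pixel sliver cannot vanish.

## Segmentation network

The learned segmenter is a 2D residual dilated network: a 1×1 lift to the
trunk width, ten residual blocks of two 3×3 convolutions each (20 trunk
layers, residual connection every two layers), per-block dilation factors
(1,1,2,2,4,4,8,8,4,2) to grow the receptive field without pooling, and a
1×1 sigmoid head. Loss is soft Dice plus binary cross-entropy; the
optimizer is Adam at lr 1e-3; the probability threshold is 0.5.

The engine is a self-contained numpy implementation with manual
backpropagation (`scoutrange.nn`), deterministic given the seed. Two sizing
choices keep a 200-image, 10-epoch training run at roughly 3–4 minutes on
one CPU core: a trunk width of 8 channels, and an internal stride of 2
(average-pool after the lift, nearest upsampling before the head), which
quarters the arithmetic at the cost of ~1-pixel boundary quantization —
negligible against the lung area that dominates Dice. On the synthetic
benchmark this configuration reaches held-out Dice ≈ 0.97 for AP
projections; scout-mode fine-tuning (magnified views, a few epochs at
lr 3e-4 from the projection-trained weights) stays above 0.85. Those
numbers characterize the phantom benchmark, not clinical imaging: phantom
lungs are high-contrast ellipses, and passing here shows the pipeline's
plumbing and training loop are sound, not that clinical-grade accuracy
would follow.

### Classical fallback

A deterministic, training-free segmenter provides an independent oracle:
body = largest connected component above a small intensity threshold; the
lung-free background of each craniocaudal intensity profile is estimated as
the per-column maximum over rows (exact for the z-invariant phantom body);
lungs are pixels whose deficit against that background exceeds
`max(0.008, 6σ̂)` with σ̂ the out-of-body noise level; holes are filled and
the two largest components kept. The 0.008 floor corresponds to ≈2.5 mm of
lung along the ray, which is what makes the one-voxel apex and recess
slivers detectable on noiseless phantoms. The per-column background is a
phantom-specific simplification: real scouts have shoulders and abdomen in
the field and would need a sliding or model-based background.

## Range selection and errors

Mask→range takes the first/last occupied row through the mask's affine,
with a default margin of one voxel each way, clipped to the image; removal
of sub-`min_pixels` components (default 50 at 256×256) precedes it. AP and
lateral ranges combine by averaging the limits by default (union and
intersection are available); averaging makes each combined error lie
between the single-view errors.

Errors are signed: superior error = truth − selected superior limit,
inferior error = selected − truth inferior limit; positive means overscan.
Accuracy is scored against the exact lung boundary with margin 0 on both
sides — the one-voxel margin is part of the *prescribed* exact-coverage
scenario, not of the error metric, which would otherwise carry a built-in
+1-voxel bias.

On 20 noiseless phantoms at 256×256 the classical segmenter keeps every
superior error within 2 mm and the median absolute inferior error within
3 mm; the residual errors come from resampling quantization (~1 resized
row) and sub-threshold slivers at the extreme recess.

## Dosimetry

The accounting chain is standard: `D_eff = sqrt(D_AP · D_Lat)` from the
body extents at the mid-lung slice; SSDE = f(D_eff) · CTDI_vol with the
AAPM report 220 conversion for the 32 cm phantom,
`f = 3.704369 · exp(−0.03671937 · D_eff)` on the tabulated domain
6–55 cm (f is strictly decreasing; it crosses 1 near 35.7 cm);
DLP = CTDI × length summed over the lung / superior / inferior regions.

TCM is honoured by averaging the recorded per-slice mA over each region and
scaling the regional CTDI by `mA_region / mA_acquisition`. The
normalization is the acquisition-wide mean — one constant shared by all
scenarios of a patient — which is what makes the decomposition
`ED_exact + ΔED_superior + ΔED_inferior = ED_human` hold exactly;
normalizing per scenario would break it.

Organ doses use a declared 1-D surrogate instead of Monte-Carlo transport:
on a reference phantom (lung spanning 0–240 mm; patient overscans are
rescaled by `reference/patient` lung-length ratio), each organ receives the
regional SSDE over its in-field extent plus an exponential scatter tail
`SSDE_edge · exp(−d/λ)` beyond the outer field edges (λ = 30 mm by default,
chosen to give non-zero but rapidly decaying out-of-field doses), averaged
in closed form over the organ's extent. ED is the ICRP-103 tissue-weighted
sum; the bundled table carries all 27 tissues (weights sum to 1.0, checked
at load, file checksummed) with synthetic z-extents — configuration, not
clinical anatomy. The surrogate reproduces the structure of the accounting
(additivity, monotonicity in field length, exact/DL/human ordering) but not
clinical dose magnitudes; the ~20–30% ED reductions it reports for
automated vs simulated-human ranges are properties of the phantom cohort
and operator model, not clinical claims.

## Numerical choices and degenerate inputs

Projections are float64 so total-attenuation conservation holds to 1e−9
relative. Constant-intensity images normalize to zeros with a warning; an
empty 3D mask projects to an empty 2D mask with a warning; an empty 2D mask
raises on range conversion ("no lung found"). Dice of two empty masks is
defined as 1. Regions with zero slices yield absent (None) TCM averages
that propagate without fabricating values. All randomness flows from one
root seed through SHA-256-derived per-stage child seeds (< 2³¹).

## Known limitations

* The phantom's z-invariant body makes the classical segmenter's background
  model exact; real localizers violate it.
* Network results are desk-scale (200 images, 10 epochs, 8 channels); no
  claim transfers to clinical data volumes or vendor-specific scout
  post-processing.
* The organ z-table and scatter length are synthetic configuration; organ
  doses and ED are comparable *across scenarios*, not with clinical
  dosimetry software.
* NIfTI ingestion assumes the package's own (slice, row, col) axis order;
  arbitrary clinical orientations would need reorientation logic.
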