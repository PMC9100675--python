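# Methods

`thoraseg` implements an experimental pipeline for studying how annotation
coherence (data correction, DC) and domain-knowledge nodule augmentation
(DA) affect supervised lung segmentation in CT. This note documents the
models, the defaults and the numerical choices, and what the synthetic
phantoms do and do not show about clinical data.

## Data model and conventions

All volumes are `(z, y, x)` arrays of Hounsfield units (HU) with strictly
positive mm spacing; voxel indices are 0-based and physical position is
`origin + index × spacing`. Masks are binary arrays on the same grid; any
nonzero value read from a mask file maps to 1, which tolerates
annotation-tool label dialects. NIfTI is the canonical interchange format
(NRRD read/write, DICOM series read-only, single-frame CT sorted by slice
position).

## Synthetic thoracic phantoms

The phantom generator (`thoraseg.phantom`) renders the gross radiological
layout of an axial chest acquisition rather than a photorealistic CT: a
soft-tissue body ellipse (−60..80 HU) in air (−1000 HU), two low-density
lung ellipsoids (−900..−700 HU), a central airway at −1000 HU (trachea plus
short main bronchi carved into the medial lung border so the carved channel
never forms an enclosed in-slice hole), bright hilar vessel disks (30..90
HU) strictly interior to the lung, and spherical nodules of −50..100 HU and
8–20 mm diameter, a configurable fraction of them peripheral (touching the
pleural border). Additive Gaussian texture noise (σ = 30 HU) is applied and
values are rounded to integer HU. Nodule HU defaults are a generator choice
— solid nodules are clearly denser than parenchyma — and are exposed on
`PhantomSpec`.

Each case carries coherent ground truth (lung includes nodules and hilar
vessels, excludes the airway) plus an "original-protocol" lung label with a
cohort-style defect:

- `nodules_excluded` — nodules carved out of the lung label;
- `trachea_included` — airway merged into the lung label;
- `auto_noisy` — both defects plus vessel-shaped holes (an
  automatic-segmentation artefact);
- `coherent` — no defect.

Five dataset profiles bundle a protocol with per-cohort voxel spacings
(e.g. the tumour-cohort profile uses 1.02 mm pixels / 2.65 mm slices and the
nodules-excluded defect; the clinical profile is already coherent), so a
heterogeneous multi-cohort corpus with realistic label noise derives from a
single seed.

What the phantoms do **not** emulate: interstitial/emphysema texture,
scanner physics, lobar anatomy, real pleural geometry, inter-annotator
variability beyond the four deterministic defects. Tests passing on
phantoms therefore demonstrate the *mechanics* of the pipeline (exact mask
algebra, metric correctness, the direction of the DC/DA effects), not
clinical-grade segmentation accuracy.

## Mask-correction protocol

`thoraseg.coherence` replaces a manual, medically supervised annotation
review with three deterministic operators applied in a fixed order:

1. **exclude airways** — set difference with an explicit airway mask;
2. **include nodules** — union with nodule masks; with the adjacency rule a
   nodule is merged only when it overlaps or face-touches the lung
   (6-connectivity in 3D, 4 in 2D — a conservative pleural-attachment
   criterion, exposed as a parameter);
3. **fill hilum** — in-slice enclosed background holes with equivalent
   diameter ≤ `max_hole_mm` (default 15 mm; hilar vessels and bronchi are
   centimetre-scale) are filled.

Airway exclusion precedes nodule inclusion so a nodule overlapping an
airway label is retained as lung. The composition is idempotent, and on
phantom data it recovers the generator's coherent truth exactly (DSC = 1.0)
for every defect the generator produces. A `CorrectionReport` tallies
voxels added/removed per rule, preserving the audit spirit of a manual
review.

## Nodule-insertion augmentation

ROIs (HU patch + mask, bounding box dilated by a 2 mm margin) are extracted
from donor cases; the ROI bank defaults to 40 nodules. Insertion samples a
paste centre inside the recipient lung (rejection sampling, bounded
retries, seeded), copies donor HU inside the mask (`replace` blending, hard
edge; `max` blending available) and leaves every voxel outside the pasted
footprint bit-identical. One nodule per augmented case by default, and a
`rate` fraction (default 0.5) of cases is augmented; insertion rate,
blending and multiplicity are deliberately exposed because no single
convention is canonical. Pasting does not resample the donor patch to the
recipient spacing; with matched-profile donors this bias is small, and it
mirrors direct pixel-paste augmentation.

Ground-truth masks are always updated coherently (pasted mask becomes a new
nodule instance and is unioned into the lung). The *defective* label of an
augmented case is updated the way its own annotation protocol would have
annotated the new image: a protocol that excludes tumour masses carves the
inserted nodule out of its lung label. This is what makes the DA-without-DC
condition structurally incoherent — the image shows a nodule the training
label excludes.

## Preprocessing

Min-max HU windowing with fixed clinical bounds −1000..400 HU (clipped,
then scaled to [0, 1]) and in-plane bilinear resize to 128×128; masks use
nearest-neighbour resize to preserve binarity; the z axis is never
resampled. The effective pixel spacing after resizing
(`source_dim/target_dim × source_spacing`) is carried for mm-based metrics.
Clipping before scaling is the standard reading of fixed-window
normalization — unclipped scaling would leave values outside [0, 1].

## Segmenter

A residual-encoder U-Net: 7×7 stride-2 stem, 2×2 max pool, four residual
stages with (3, 4, 6, 3) units at (f, 2f, 4f, 8f) channels (the ResNet34
pattern) with batch normalization and PReLU; a decoder of five 2×2
transpose-convolution upsampling stages with skip concatenations and
ReLU conv blocks; a 1×1 convolution + sigmoid head emitting a per-pixel
lung probability map. Total downsampling is 32×, so input sides must be
multiples of 32. The network, its backward pass and the Adam optimizer are
implemented directly on numpy (im2col convolutions, float32), which keeps
the package self-contained and CPU-reproducible; `base_filters` defaults to
16 as a CPU-scale width (64 reproduces the full-width original), and the
2×2 pool is a simplification of the classical 3×3 stride-2 stem pool.

Training uses the soft Dice loss `1 − (2Σpt + s)/(Σp + Σt + s)` with
smoothing constant `s = 1.0` (the unsmoothed form divides by zero on empty
masks), Adam at learning rate 1e-4, batch size 8, a seeded 30% validation
split, and best-validation-epoch checkpointing (epoch count is
configurable; there is no canonical value). Binarization threshold is 0.5.
Weights are He-initialized from a seeded generator; no pretraining. With a
single CPU thread and fixed seeds, training histories reproduce to
floating-point tolerance.

**Desk-scale training configs.** The bundled sanity and factorial runs are
deliberately small: the learning-sanity check trains on 50 phantom slices
at 128×128 for 20 epochs, and the factorial trains each condition on 8
phantom cases (48 slices) at 64×64 with a (1, 1, 1, 1)-block, 8-filter
encoder for 18 epochs. At a handful of gradient steps per epoch the
full-scale learning rate of 1e-4 cannot move a freshly initialized network
appreciably, so these desk-scale runs use 1e-3; the full-scale defaults
remain on `TrainConfig`.

## Evaluation metrics

DSC, Hausdorff distance and average symmetric surface distance, with
explicit conventions:

- border points are foreground voxels with ≥1 background face-neighbour
  (array edges count as background);
- distances are Euclidean over `index × spacing`, computed exactly with a
  KD-tree over border points and verified against an all-pairs brute force
  in the tests (≤1e-9 mm on random masks up to 16×16);
- `DSC(∅, ∅) = 1`, `DSC(∅, nonempty) = 0`; HD/ASSD are *undefined* for
  empty masks — such cases are flagged and excluded from dataset means
  rather than reported as 0, which would bias means downward;
- per-slice 2D metrics are averaged within a case, then aggregated across
  cases (a 3D per-volume mode is provided); dataset tables report mean ±
  sample (n−1) standard deviation;
- the conventional reporting range of the distances on a 128×128 unit-
  spacing grid is 0 to the image diagonal √(128² + 128²) ≈ 181.0193 mm
  (`distance_range`); both unit-pixel and rescaled-physical-spacing modes
  are available because reported distances in the field are frequently in
  pixel units of the evaluation grid.

## The DC × DA factorial

Four conditions from identical training cases: (1) defective labels,
no augmentation — the baseline; (2) corrected labels; (3) augmentation on
defective labels (structurally incoherent, see above); (4) corrected labels
plus coherently labelled augmentation. All conditions are evaluated against
the same coherent ground truth. Every stochastic stage — phantom geometry,
augmentation, validation split, weight init — derives its seed from one
master seed, so a factorial rerun is reproducible and the (dc, da) flags
are the only difference between conditions of one run.

Because nodules are small relative to the lung, mean DSC barely separates
the conditions; the factorial therefore also reports **per-nodule coverage**
— the fraction of each true nodule's voxels inside the prediction, with a
nodule counted as "included" at ≥0.5 coverage. This is an invented
quantitative surrogate for a visual nodule-inclusion read, and is labelled
as such in reports. On desk-scale phantom runs, mean DSC of all four
conditions typically agrees within a few points while coverage separates
the corrected-label conditions (≈0.6–0.8) from the defective-label ones
(≈0.2–0.4), and the DC+DA condition's coverage is at least the baseline's.

## Known limitations

- The phantom is geometric; no claim about clinical accuracy transfers.
- The numpy segmenter is CPU-bound; widths and image sizes far beyond the
  defaults become slow.
- 2D per-slice training and evaluation only; 3D context is out of scope.
- The correction operators require explicit airway/nodule masks — they
  unify annotations, they do not detect structures from raw HU.
- Apex/base disambiguation in real annotation reviews is qualitative
  guidance and has no programmatic counterpart here.
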