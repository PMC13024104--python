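# Methods

## Problem and scope

`hsinucdb` builds *hyperspectral databases of cell nuclei* from stained
histopathological samples imaged with a wedge line-scan hyperspectral
camera. The pipeline has four stages: (1) turn raw line-scan frames into
calibrated, spatially aligned hyperspectral cubes; (2) segment cell nuclei
with one of three methods that use spectral information, spatial
information, or both; (3) evaluate segmentations at the pixel level and —
critically — at the instance level, because a database of *per-cell*
signatures needs correctly separated cells, not just accurate pixels;
(4) average each nucleus's spectra into one signature record and label it
with the patient's diagnosis.

Real acquisitions of this kind are proprietary clinical data, so the
package ships a phantom generator that emulates the whole acquisition
chain with exhaustive ground truth. All quantitative claims made by the
test suite and the acceptance script are claims about these phantoms.

## Sensor model and phantom generator

A wedge line-scan sensor observes, in each frame, a different wavelength
channel ("virtual band") per sensor row; as the motorized stage sweeps the
sample, every scene line is eventually seen by every band. The
`SensorModel` makes this explicit: frame *t*, sensor row *r* carries scene
line `t·scan_step + row_offset(r)` of virtual band `row_to_band(r)`. The
generator and the stitcher share this model, which makes stitching exactly
invertible. The desk-scale default is 16 spectral bands expanded to 20
virtual bands; the full camera layout (145 spectral / 192 virtual,
470–890 nm, 2048-px lines) is supported but not the default — tests run
entirely on the desk scale.

The vendor's spectral correction matrix is unavailable, so a synthetic
stand-in maps each spectral band to a normalized average of at most three
adjacent virtual bands (columns sum to one). The generator expands ideal
cubes to virtual bands with the exact replication right-inverse of that
matrix, so a noiseless render→preprocess round trip is limited only by
8-bit quantization (observed max error ≈ 0.006, tolerance 2/255).

Tissue scenes are two-chromophore H&E-like fields: a bright
eosin/glass background spectrum (transmittance 0.75→0.90 across
470–890 nm) and a darker hematoxylin-like nucleus spectrum with a broad
absorption dip near 600 nm. Nuclei are rotated ellipses (semi-axes 4–9 px
and 3–7 px) placed by rejection sampling; the count is Poisson at the
configured density. Two regimes reproduce the tissue contrast the methods
are meant to expose:

* **tumor**: 8 nuclei per 10⁴ px² — dense; candidate nuclei may touch,
  and up to 5% of a candidate's area may overlap already-placed nuclei.
  Touching pairs merge in any pixel-class mask, which caps achievable
  instance recovery at roughly −5% even for a perfect three-class
  predictor; this mirrors the intrinsic difficulty of crowded tumor
  fields.
* **healthy**: 1.5 nuclei per 10⁴ px² — sparse, with a ≥3-px enforced gap.

Sensor effects: additive Gaussian noise on transmittance (default
sd 0.01), low-amplitude multiplicative chromatin texture inside nuclei
(default sd 0.01), per-band integer spatial shifts (default none; tests
inject up to ±120 px), slightly non-flat white references, and 8-bit
quantization. Shift injection uses a circular roll so that integer
phase-correlation recovery is exact on noiseless scenes; the correction
side never wraps (constant fill + crop), so wrapped content never
survives into an aligned cube. What the phantom does **not** model:
optical point-spread, stain variability, chromatin substructure, nucleoli,
out-of-focus tissue, vignetting beyond a smooth white-reference profile,
and compression artifacts. Passing tests therefore demonstrate that the
algorithms are implemented correctly and behave as designed under the
stated contrasts — not that the trained desk-scale models transfer to real
tissue.

Multi-cube suites assign one synthetic patient per cube and split at the
patient level (train/validation/test), mirroring the 10-tumor/20-healthy,
20/4/6 design of the full-scale study at configurable scale; per-cube
seeds are spawned from one master seed via `numpy.random.SeedSequence`.

## Preprocessing chain

1. **Calibration**: transmittance `(frame − dark) / (white − dark)`;
   dead pixels (white = dark) are set to 0 and logged; negatives clamped.
2. **Stitching**: inverse of the sensor forward model; only lines sampled
   by every band are kept.
3. **Spectral correction**: tensor contraction with the correction
   matrix; attaches the wavelength grid.
4. **Shift correction**: every band is registered to the *first* band
   (the anchor) by phase correlation, rounded to integer pixels,
   translated with constant fill, and the cube is cropped by the extreme
   estimated shifts per axis — exactly the filled margins. When all
   shifts share a sign the spatial loss equals the max |shift| per axis;
   mixed signs cost the sum of the two extremes. If any component
   exceeds the threshold (default 100 px) the cube is marked *discarded*
   and carries no aligned data. Shift estimates are only meaningful when
   the image extent exceeds twice the true shift (phase correlation is
   cyclic); at the default threshold this requires cubes larger than
   200 px, which both the phantom acceptance scenes and the full-scale
   camera satisfy.
5. **Normalization**: min–max to [0, 1] with a single global (min, max)
   per cube, preserving relative band intensities that signatures depend
   on; per-band normalization is available behind a flag.
6. **RGB synthesis**: channels pick the band nearest 605.61 (R), 543.65
   (G) and 462.14 nm (B). The blue target lies below the camera range,
   so it clamps to the first band.

## Segmentation methods

**Method 1 — spectral-only.** Pixels are independent spectra. The
training table pools all training-cube pixels, maps any border-class
ground truth to background (this method is strictly two-class), and
undersamples the background majority to class balance. An XGBoost
classifier (histogram tree method, fixed seed) predicts per pixel;
hyperparameter tuning is a random search over estimators 100–2000, depth
5–15, learning rate 0.01–0.5 (log-uniform), maximizing validation nuclei
Dice computed per cube and averaged. Desk defaults: 300 estimators,
depth 5, learning rate 0.1, 25 trials when tuning.

**Method 2 — spatial-only.** Input is the synthetic RGB image. Ground
truth gains an auxiliary *border* class: every non-nucleus pixel within a
3-px disk of a nucleus boundary. Nucleus pixels are never relabeled, so
the class-2 pixel count is invariant under border construction; the
border band fills gaps of up to ~6 px between nearby nuclei and teaches
the network to separate them. Patches (training default 64 px desk /
640 px full scale, no overlap, floor tiling) are augmented with rotations
in [−45°, 45°] (p = 0.5, nearest-neighbour for masks), horizontal and
vertical flips (p = 0.5 each) and brightness/contrast jitter on the image
only (p = 0.2). The network is a compact one-skip U-Net (two conv
blocks, width 8) trained with class-weighted cross-entropy (inverse
pixel frequency, normalized to mean 1) by Adam; the checkpoint with the
best validation nuclei Dice is kept. Inference tiles the image at the
training patch size with reflective padding where needed and averages
class probabilities over overlaps; ties argmax to the lowest class index.

**Method 3 — spatial–spectral.** The cube is a 3-D volume over
(y, x, λ). Patches are 64×64 with full spectral depth, extracted at 25%
overlap (stride 48). The network applies 3-D convolutions with
spatial-only pooling (the spectral axis is never downsampled, so small
band counts remain valid); after the last decoder convolution an adaptive
average pool collapses the spectral axis to length 1 and a 2-D 1×1
convolution emits three-class logits — so ground truth stays 2-D. The
spectral axis is padded in *edge* mode: a cube constant along wavelength
stays constant through every convolution, making the collapse an exact
identity on such inputs (a tested invariant). Training matches Method 2;
desk defaults width 4, 12–15 epochs, batch 4, learning rate 3·10⁻³.

The conv-net engine itself (`nn.py`) is a compact CPU implementation —
stride-1 same convolutions computed as one BLAS contraction per kernel
tap, average pooling, nearest-neighbour upsampling, weighted softmax
cross-entropy, Adam — with hand-written gradients verified against finite
differences to ~1e-8 relative error.

## Evaluation conventions

Pixel precision/recall/F1 are pooled over all test pixels (one-vs-rest
per class). Region Dice (DSC) is computed per image and averaged; a class
absent from both maps of an image contributes Dice 1 (this matters for
border-free healthy cubes). These two conventions are deliberately
different — pooled F1 and averaged DSC only coincide when test images are
homogeneous. Macro averages cover the two main classes (background,
nuclei) only; the border class is auxiliary. Instance counts are
8-connected components of nuclei-class pixels (equivalently, closed
external contours); count deviation is `(pred − gt)/gt · 100`, averaged
arithmetically across cubes.

## Signature database

Instances are labeled 1..K in raster order of first pixel. Each record
stores the per-band arithmetic mean spectrum over the instance's pixels
of the *normalized* cube (normalization precedes extraction in the
pipeline order), area, centroid, cube and patient ids, and the diagnosis
joined from the clinical table (unresolvable patients are a hard error
naming the offenders). Border pixels never contribute: they are boundary
markers, and including them would contaminate nuclear spectra with
background mixture. The default minimum instance area is 1 px (no
filtering). Storage is wide-format CSV (one `band_<λ>nm` column per band,
schema version column) with a Parquet option.

## Problem sizes and numerical choices

Desk-scale runs — the test suite and the acceptance script — use
256×256×16-band phantoms: small suites that train on one tumor and one
healthy cube, validate on one healthy cube, and test on two to three
tumor cubes plus one healthy cube (the acceptance script uses three tumor
test cubes so the mean count deviation is estimated from more
replicates); width-8 2-D and width-4 3-D networks, 12–15 epochs, and a
300-tree boosted classifier. These sizes were chosen so the whole recovery study runs on a
single CPU in minutes while preserving every qualitative contrast of the
full-scale design; full-scale settings (640-px patches, 145 bands, the
published hyperparameter ranges) remain configurable.

Numerical details worth knowing: shifts are rounded to integers before
translation so crop margins are well-defined; probability ties at
inference resolve to the lowest class index (background); Dice of an
empty class on an empty image is 1; undersampling, network
initialization, batch shuffling and the hyperparameter search all draw
from explicitly seeded generators, so every reported number is
bit-reproducible for a fixed seed; xgboost runs single-threaded with
`tree_method="hist"` and a fixed seed for the same reason.

## Known limitations

* The phantom's nuclei are smooth ellipses; none of the morphological
  irregularity that drives real segmentation errors is present, so
  desk-scale Dice values are far higher than any realistic tissue score
  and must not be read as performance claims about histology.
* Touching tumor nuclei merge in pixel-class ground truth; instance
  recovery on dense scenes is bounded by the generator's touching rate
  (about −5% at defaults) independent of model quality.
* The three-class border formulation cannot separate nuclei whose masks
  actually overlap — only nuclei separated by at least one background
  pixel gain a separating border band.
* Phase-correlation registration assumes pure translation per band and
  breaks on aliasing when shifts exceed half the image extent.
* The clinical join is a plain patient-id lookup; no ontology or
  grading-criteria modeling is attempted.
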