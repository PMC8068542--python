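# Methods

`fundustex` detects two diabetic-retinopathy symptoms — hard exudates and
the retinal vessel tree — in fundus photographs, by combining
multi-resolution quantized texture descriptors, a correlation-based
segment score, a small recurrent regressor, and a rho-driven
multi-resolution binarization. This note records the model, its
assumptions, the parameters that matter, and the design decisions taken
where the design was genuinely open.

## Texture encoding

A gray window (the green channel of the fundus image, which carries the
best vessel/lesion contrast) is quantized at the ladder
L_Q ∈ {128, 64, 16, 8} using the window's own intensity extrema
[i_min, i_max]:

    bin(v) = clip( ceil( (v − i_min)/(i_max − i_min) · L_Q ), 1, L_Q )

Local extrema stretch every window over the full bin range, so the
encoding is exactly invariant to additive intensity shifts of a window.
A constant window maps to bin 1 everywhere (logged), which propagates to
the point-mass descriptor block [1, 0, 1, 0, 0].

Per level a gray-level co-occurrence matrix (GLCM) is accumulated over
the four canonical unit offsets (0°, 45°, 90°, 135°), symmetric (both
directions counted), out-of-bounds neighbors skipped. The normalized
GLCM p yields five Haralick descriptors — homogeneity, entropy
(0·ln 0 ≡ 0), energy (angular second moment; a `energy_sqrt` flag selects
the square-root variant), correlation (defined as 0 when a marginal
variance vanishes), contrast — indices running over gray levels 1..L.
Concatenating the four levels in ladder order gives the 20-component
feature vector of a window.

## Segment scoring (rho)

Images are tiled into non-overlapping 64×64 windows (zero-padded
bottom/right), traversed in raster order. Expert-marked (or synthetic
ground-truth) windows whose lesion coverage exceeds 5% are ROI training
windows; the benchmark feature F_ROI is their mean. A window's symptom
score is the Pearson correlation ρ of its feature vector with F_ROI,
mapped to ordinal labels: none (ρ < 0.5), mild [0.5, 0.7), strong
[0.7, 0.9), very strong [0.9, 1].

**Feature standardization.** The raw descriptors live on wildly
different scales: contrast at L = 128 is two to four orders of magnitude
above the unit-scale descriptors and grows ≈ L² for *every* window, so
raw 20-vectors are nearly collinear and the raw Pearson score saturates
at ≈ 1 for all windows (we measured both lesion and clean windows at
ρ = 1.000 on synthetic batches). All features are therefore z-scored per
component with statistics fitted on the training window population; the
scaler is stored in the model checkpoint and applied identically at
inference. The correlation formula itself is unchanged.

**Aperture masking.** Fundus photographs have a bright circular retina
field inside a dark camera aperture. The retina field is estimated by
thresholding the raw RGB channel sum at 100 (range 0–765). Windows
straddling the aperture rim would otherwise be texture-dominated by the
rim gradient — on synthetic data roughly a third of planted lesion
pixels sit in such windows and become unreachable. Non-field pixels are
therefore excluded from a window's extrema and from GLCM pairs, from the
Otsu histograms below, and from all final masks. The vessel pipeline
additionally zeroes background pixels before quantization.

## The recurrent regressor

A single LSTM layer (100 hidden cells; gates f, i, o and candidate, each
with separate input and recurrent weights plus bias) followed by one
biased linear output neuron predicts a segment's ρ from the raw
correlation signals of nearby segments. With per-step input dimension 3
the network has 4·100·(100+3+1) + 101 = 41,701 trainable parameters.

Sequence encoding: let s_t be the raw benchmark correlation of segment t
in raster order. The sample for segment t is a 3-step sequence over
positions p = t−2..t whose step input is [s_{p−2}, s_{p−1}, s_p]
(zero-padded before the image start); the target is ρ_t. The first
3 segments of each image are skipped during training; sequences never
cross image boundaries. The regressor thus learns a smoothed,
context-aware version of the correlation score; at inference every
segment receives a prediction (clamped to [−1, 1]).

Training is full truncated backpropagation through time with
hand-derived gradients and Adam (learning rate 1e-3, batch 32,
100 epochs by default), mean-squared-error loss, RMSE logged per epoch.
Initialization and shuffling are seeded; runs are bit-reproducible. The
vectorized trainer forward pass is held to the reference `cell_step`
implementation to 1e-12 in tests. Checkpoints are single `.npz` files
with named weight arrays, the benchmark vector, the feature scaler and a
versioned JSON header.

## Pixel classification

Only segments with ρ > 0.5 are processed; all pixels of other segments
are non-candidates. Within a retained segment, each of the four
quantized versions is enhanced with a power-law (gamma) transform whose
exponent is 1 − ρ, binarized with Otsu's global threshold (candidates
strictly above), and the four masks are intersected: a candidate pixel
must separate from background at every quantization resolution.

The power law is applied to the bin values x ∈ {1..L} and the attainable
range [1, L^(1−ρ)] rescaled to [0, 255]; the multiplicative constant c
cancels under this rescaling and Otsu's threshold location. On this base
the spacing converges, as ρ → 1, to a logarithmic compression — well
behaved for thresholding. (Applying the exponent to bins rescaled to
[0, 1] instead maps the minimum bin to exactly 0; the transformed
histogram then degenerates into a zero outlier plus a compressed mass
and Otsu isolates the minimum bin, which empirically marks almost the
whole segment for bright structures and almost nothing for dark ones.)
At ρ = 1 exactly the transform is constant and the segment yields an
empty mask.

Because the power law stretches the *low* end of its domain, a polarity
flag decides which end carries the structure: vessels (dark) use the
bins as-is; exudates (bright) reverse the bin order first. The output is
always structure-bright, so Otsu's upper class is the candidate class.
For dark polarity this is identical to transforming and then inverting.

**Contrast enhancement placement.** CLAHE (clip limit 0.03, 8×8 tile
grid; the parameters are not fixed by the method definition) is applied
to the whole image, but only in this pixel-classification stage, where
the added local contrast sharpens lesion rims (measured blob-rim
sensitivity rose from ≈ 0.64 to ≈ 0.93 at high ρ). Texture *scoring*
uses the unequalized green channel: adaptive equalization whitens the
second-order statistics the gate discriminates on, roughly quadrupling
the number of falsely gated clean windows in our measurements.

The vessel pipeline is the same chain with dark polarity on the
background-zeroed green channel; final masks are clipped to the retina
field.

## Evaluation

Predicted and ground-truth masks are compared pixel-to-pixel into
TP/TN/FP/FN, from which sensitivity, specificity, accuracy, PPV and NPV
are computed (a zero denominator means the condition is vacuous and the
ratio is defined as 1, logged). The sixth measure is the structural
similarity index in its global form (whole-template population moments,
stability constants c1 = (0.01·255)², c2 = (0.03·255)²), computed on the
masks rescaled to {0, 255}. Per-image results are written as a
six-column percentage CSV.

## Synthetic data

The generator emulates the ingredients of a fundus photograph that the
pipeline's stages react to: a circular retina field (radius 0.45 of the
image side, center intensity 110 with a gentle radial falloff, intensity
5 outside), dark random-walk vessel curves (6 per image, width 2–4 px,
40 gray levels below the field) emanating from near the disc center,
bright exudate blobs (5 per image, radius 4–10 px, Gaussian profile with
peak lift +70, placed inside 0.8 of the field radius, never overlapping
vessels), and additive Gaussian noise (σ = 5). Ground-truth masks record
the exact pre-noise geometry. The default 256×256 size keeps a batch of
20 images (320 windows) encodable in seconds while exercising every
pipeline stage; generation is pure given the seed.

What the generator does *not* emulate: the optic disc, macula and
vessel-crossing geometry, non-uniform illumination and color variation,
camera noise correlations, microaneurysms and hemorrhages, and the soft,
irregular boundaries of real exudates. Passing the synthetic recovery
tests therefore demonstrates that the pipeline's machinery is correct
and self-consistent under controlled contrast conditions; it does not
certify clinical performance on real datasets, where preprocessing
robustness and the LSTM's training data dominate.

## Numerical choices and degenerate inputs

- Quantization uses exact ceiling arithmetic; extrema endpoints clamp to
  bins 1 and L_Q. Degenerate (constant) ranges map to bin 1 with a
  warning at the stack level; the low-level op raises.
- Otsu's threshold is the smallest maximizer of between-class variance
  over the 256 integer thresholds; constant images yield all-zero masks.
- The ρ label bins close the printed gap between 0.89 and 0.9 by
  extending *strong* to ρ < 0.9.
- Pearson correlations guard against rounding with a final clip to
  [−1, 1]; zero-variance vectors score 0.
- The LSTM forget-gate bias is initialized at +1 (standard practice for
  gradient flow over short sequences); other weights are seeded Gaussians
  scaled by 1/sqrt(fan-in).
- Checkpoint format is versioned; loading rejects unknown versions.

## Known limitations

- The look-back sequence couples a segment's prediction to its raster
  neighbors, which is a weak spatial prior; 2-D context is not modeled.
- The ρ gate at 0.5 is hard; lesions in windows whose texture the gate
  rejects are unrecoverable downstream.
- Windows are axis-aligned and non-overlapping; a lesion split across a
  window corner contributes diluted texture to all four windows.
- Real-data use (STARE, DIARETDB1) is supported through the CLI but not
  validated here; those datasets require downloads and expert masks.
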