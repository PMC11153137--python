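# Methods

`gigaslide` implements a two-stage whole-slide modeling stack — tile-level
embedding followed by slide-level sequence modeling with dilated attention —
together with the three training regimes that make such a stack useful:
slide-level masked-autoencoder (MAE) pretraining, attention-MIL fine-tuning
for slide classification, and CLIP-style slide–report contrastive alignment
with prompt-based zero-shot prediction. Every stage is exercised end-to-end
on synthetic pseudo-slides with planted, recoverable signal; this note
records the model assumptions, the defaults and why, what the synthetic data
does and does not emulate, and the numerical choices.

## Preprocessing

A slide image is segmented into tissue vs. background by Otsu thresholding
on the grayscale luminance of a downsampled rendering (long side 1024 px by
default); tissue is the darker side of the threshold. A constant image has
no threshold and yields an all-background mask with a warning. The slide is
then resampled bilinearly to a standard physical resolution of 0.5 microns
per pixel (≈20× magnification); output side lengths are
`round(side · source_mpp / target_mpp)` with round-half-even. Tiles of
256×256 px are cropped on a non-overlapping grid anchored at pixel (0,0);
partial edge tiles are dropped so all tiles batch uniformly. Occupancy is
the fraction of tile pixels covered by the nearest-neighbour-upsampled
mask; tiles below 0.1 occupancy are discarded. The Otsu channel
(luminance vs. HSV saturation) and all thresholds are config-exposed.

## Serialization and augmentation

Retained tiles are ordered row-major — sorted by (grid_row, grid_col), with
0-based (col, row) coordinates in tile units — and coordinates are
discretized on a d_grid = 256 px grid under an n_grid = 1000 overlay of
rows and columns (a coordinate ≥ n_grid is an explicit overflow error).
Training-time augmentations act on coordinates only, in the order
crop → shift → flip → re-sort:

- **crop** keeps tiles inside an axis-aligned window spanning a 0.875
  fraction of the occupied bounding box per axis, uniformly placed within
  the box (cropping empty grid space would be a no-op); if the window
  captures no tile, the tile nearest the window centre is kept so the
  sequence never empties;
- **shift** adds one uniform integer offset per axis, sampled so every tile
  stays inside [0, n_grid);
- **flip** (probability 0.5) reflects columns about the slide's own
  occupied extent, `col → max_col − col`, which keeps the slide in-frame
  without a compensating shift.

Each slide draws from its own random stream keyed by (global seed,
CRC32(slide_id)), so augmentation is reproducible per slide per epoch.

## Tile embedding

The tile encoder is pluggable behind `embed_tiles`. The bundled baseline
embedder is deterministic and training-free: per RGB channel it computes
block means and standard deviations on a 64 px grid plus the mean absolute
horizontal difference at lags {1,2,3,4,6,8,12,16,24,32}, normalizes each
channel's lag profile by its own mean (the profile *shape* carries local
texture period independently of tissue fraction), and projects the feature
vector through a fixed seeded Gaussian matrix. This is not a learned
encoder and is not meant to rival one; it exists so slide-level machinery
has informative, reproducible inputs without GPU pretraining.

## Dilated-attention slide encoder

The slide encoder is a pre-norm transformer (GELU feed-forward, width
ratio 4, no final norm so a depth-0 encoder is the identity over inputs
plus positional terms) whose attention is dilated: for each branch
(segment length w, dilation r), the sequence is partitioned into contiguous
segments of length w and, within a segment, positions of the same residue
class mod r attend only to each other. All r phases of every branch are
computed, so each position receives one output per branch; branch outputs
are mixed with weights proportional to each branch's softmax normalizer.
Cost per branch is O(N·w/r) score entries, never O(N²) (instrumented and
tested). Padding to a segment multiple is masked: pad keys receive no
attention mass and pad queries are discarded.

Choices this architecture family leaves open, fixed here as config defaults:

- branch schedule: geometric doubling, default ((128,1),(512,4),(2048,16)),
  capped at the padded length; desk-scale tests use ((8,1),(32,4));
- at least one branch must have r = 1 (guarantees local full coverage), and
  w must be divisible by r;
- a learned classification token sits at position 0 and falls in every
  branch's first segment; its output is the global slide embedding;
- coordinates enter as two learned lookup tables (column and row, n_grid
  rows each) summed onto the tile embeddings; the classification token
  carries no coordinate term.

Correctness is anchored to an independent oracle that materializes each
branch's N×N boolean attendance mask, runs masked dense attention, and
mixes by normalizers; the implementation must agree to 1e-5 in float64
(observed agreement is at machine precision).

## MAE pretraining

Tile embeddings are precomputed and frozen. Per slide and epoch the
sequence is augmented (above), a uniform random 75% of tiles is masked, the
encoder sees only visible tiles with their coordinates, and a light
transformer decoder (depth 2, width 64 by default) receives the encoded
visible tokens, learned mask tokens carrying the masked coordinates, and
the encoded classification token as an extra position-free input — the
last so the global summary receives a direct reconstruction gradient. The
loss is mean squared error against the frozen tile embeddings at masked
positions only (reconstruction targets are embeddings, not pixels, forced
by the two-stage design). Optimization: AdamW (weight decay 0.05), lr
5e-4, batch of 4 slides via gradient accumulation, 30 epochs with the
first epoch as linear warmup then cosine decay. Training is fully
reproducible given the seed; non-finite loss aborts with a diagnostic.

## Fine-tuning and evaluation

Contextualized tile embeddings are pooled by gated attention-MIL
(two-branch tanh/sigmoid scoring, softmax weights over tiles) and a linear
head predicts the task output: per-label binary cross-entropy for
multi-label mutation panels, cross-entropy for subtyping. Protocol
defaults follow the standard regime: one slide per patient (the largest by
pixel area, ties broken by slide id), batch size 1 with 32
gradient-accumulation steps, 20 epochs, frozen tile embeddings; subtyping
additionally uses layer-wise learning-rate decay 0.9 and a tile shortcut
implemented as per-tile concatenation of raw and contextualized embeddings
before pooling (the mechanism behind "attend to tile-level features" is an
open design point; concatenation is the simplest faithful one). Folds are
patient-level and stratified (scikit-learn StratifiedKFold; classes
smaller than k fall back to round-robin within class with a warning), and
every fold run asserts the train/test patient intersection is empty.
AUROC is the rank statistic and AUPRC the step-interpolated average
precision (scikit-learn), cross-checked in tests against exhaustive
concordant-pair counting with mid-rank ties; macro averages skip
undefined (single-class) label columns with a warning.

## Vision–language alignment

The slide side of the alignment is the encoder's global embedding through
a learned linear projection; the text side is a pluggable encoder plus its
own projection. The bundled test text encoder is a seeded signed
character-n-gram hashing embedder (n = 3–5, 96 buckets), so the whole
stage runs without downloads. Training minimizes the symmetric
cross-entropy over the in-batch cosine-similarity matrix scaled by a
learnable temperature (init 0.07): lr 5e-4, batch 32 pairs, 10 epochs,
first 100 iterations warmup; 20% of patients are held out for zero-shot
evaluation. Zero-shot classification renders prompt templates per class,
averages each class's projected prompt embeddings, and softmaxes cosine
similarities to the projected slide embedding; this repeats over 50 random
template draws with per-draw metrics (mean ± s.e.m.) and an optional
majority-vote aggregation flag. Binary "gene" calls use a two-way softmax
over mutant vs. wild-type rendered prompts.

## Synthetic pseudo-slides

The generator emulates the one property of whole slides that the stack
depends on: a large, mostly-bright image (background gray 235, so Otsu
separates reliably) containing dark textured regions whose statistics carry
a recoverable label. Blobs are disks striped sinusoidally along x; the
stripe period encodes the class, with optional per-blob Gaussian period
jitter to create genuine class overlap. A second variant plants an
*arrangement* class: both classes contain the same textures, but which
texture appears on the left vs. right half of the slide flips with the
label (blobs are painted in random order so overlap overwrites carry no
texture bias), making tile-marginal statistics uninformative by
construction. Reports follow the fixed template
"final diagnosis: &lt;class name&gt;." with optional appended
"&lt;GENE&gt; mutated."/"wild-type." sentences. Default fixture MPP is
1.0, so the ×2 resample to 0.5 MPP is always exercised.

Not emulated: H&E stain color distributions, scanner artefacts, pyramidal
containers, realistic tissue morphology, report language variability.
Passing tests therefore demonstrate that the machinery recovers planted
signal through the full pipeline under controlled conditions — not that it
reaches any particular accuracy on real pathology data.

## Experiment conditions (the verification suite's study design)

All experiments run on 640×640 px pseudo-slides at 1.0 MPP (≈10 retained
tiles each after normalization and occupancy filtering) with the tiny
encoder (embed dim 64, depth 2, 4 heads, branches (8,1),(32,4)) so the
full stack fits single-CPU runtimes.

- **Downstream recovery** uses well-separated periods (4, 10, 24 px) on 40
  patients: the question is whether the protocol recovers a clearly
  planted signal under 10-fold patient-level CV, not how much pretraining
  helps.
- **MAE pretraining** uses the hard condition — periods 10 vs 14 px,
  per-blob jitter sd 4, noise sd 14 — and evaluates the linear probe under
  placement nuisance (each evaluation sequence randomly shifted on the
  overlay and flipped with probability 0.5). With widely separated
  periods even an untrained random encoder's probe saturates, leaving no
  headroom to measure a pretraining effect; the nuisance evaluation
  reflects that placement invariance is precisely what the shift/flip
  augmentations teach. A known limitation remains: at this scale an
  untrained random slide encoder is a strong feature extractor, and the
  pretraining margin on a linear probe is small (typically 0.00–0.04
  AUROC across seeds) — consistent with masked autoencoders being
  fine-tuning-oriented rather than linear-probe-oriented learners. The
  reconstruction-side effects (loss progress, beating mean-of-visible
  imputation on held-out slides) are robust.
- **Vision–language** uses a 60-patient 2-class cohort with a planted
  "GENE7" token in class-1 reports, aligns from the MAE-pretrained
  encoder, and evaluates zero-shot on the held-out 20% of patients over
  50 prompt draws.

## Known limitations

- The autodiff engine is deliberately minimal (no kernel fusion, no
  mixed precision); it is fast enough for desk-scale sequences (N ≲ 10³)
  but is not a route to real-WSI-scale training.
- The baseline tile embedder is texture-statistic-specific; swapping in a
  learned encoder changes every downstream number.
- `make_folds` hashes multilabel rows to a composite class for
  stratification; exact per-label balance is not guaranteed.
- Real WSI container formats (SVS/NDPI pyramids) are out of scope; the
  interface accepts raster arrays plus an explicit microns-per-pixel value.
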