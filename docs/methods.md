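# Methods

`brainfuse` estimates chronological age from multimodal brain-imaging
derivatives — structural MRI gray-matter maps, scalar diffusion maps, and
region-wise MEG power spectral densities — and quantifies the benefit of
fusing the modalities through a low-rank factorization of the full
outer-product (tensor) fusion operator.

## Model

### Per-modality branches

Every branch maps one subject's data for one modality to a 64-dimensional
feature vector.

**Structural branches (sMRI, DTI).** A simple fully convolutional network
(SFCN-style): five blocks of `3×3×3 conv (stride 1, same padding) → batch
norm → 2×2×2 max pool → ReLU`, with channel widths `(32, 64, 128, 256,
256)` at full scale, followed by a head of `1×1×1 conv → 64 channels →
batch norm → ReLU → average pool` over the remaining spatial grid. Five
halvings of a canonical `96×128×96` volume leave a `3×4×3` grid; with
`final_pool="fixed(3,4,3)"` that grid is asserted, while the default
`"global"` average-pools whatever grid remains so smaller volumes run
through the identical architecture. The two structural modalities use
separate branch weights by default (`share_structural_weights` exists for
the tied variant).

**MEG branch.** Each brain region's power spectrum is one token. The
pipeline is: log-transform and per-region z-scoring of the PSD, a linear
projection of the frequency bins to `d_model`, optional sinusoidal
positional encoding over regions, a post-norm Transformer encoder
(self-attention across regions), two kernel-size-1 1D convolutions over
the region axis (channels 128 then 32), average pooling over regions, and
a fully connected layer to 64 features. With positional encoding disabled
the branch is provably invariant to region ordering, which the test suite
exploits.

### Fusion

Given per-modality features `z_1..z_M`, each is extended with a constant
slot, `z' = [z; 1]`, and the full tensor-fusion operator forms the outer
product `Z = z_1' ⊗ … ⊗ z_M'` and maps it linearly to the fused vector:
`h_k = ⟨W_k, Z⟩ + b_k`. The constant slots preserve all unimodal and
lower-order interaction terms inside the multilinear map. Materializing
`W` costs `Π_m (d_m+1)` weights per output; the model instead uses the
standard rank-r factorization

    W_k = Σ_{i=1}^{r} F_1^{(i)}[:,k] ⊗ … ⊗ F_M^{(i)}[:,k],

under which the fused vector is computed without ever building `Z`:

    h = Σ_i (F_1^{(i)T} z_1') ∘ … ∘ (F_M^{(i)T} z_M') + b,

with `∘` elementwise over the 64 outputs. The dense route is kept in the
package as an exact oracle; the factorized route is verified against it
to float64 round-off over randomized configurations. The trainable
parameter count is `r·d_out·Σ_m(d_m+1) + d_out`; for rank 4, `d_out=64`,
and three 64-d inputs that is 49,984. Factor entries are initialized
`N(0, 1/(d_m+1))` so each rank term's projection is O(1), and the row
multiplying the appended constant slot is initialized to unity: each
projection then starts at `1 + z·W`, so the M-way product is near-linear
in the features at initialization and gradients flow as in an additive
layer instead of being gated by products of zero-mean terms (products of
small zero-mean projections otherwise leave the multiplicative pathway
severely undertrained at short epoch budgets). `add` (elementwise sum) and
`concat` baselines are included for comparison. A single linear head maps
the fused (or unimodal) representation to one scalar age.

### Training protocol

MAE loss, Adam (`lr 1e-4`, `weight decay 1e-8`), mini-batch 12, 300
epochs at full scale; subjects are split 80/10/10 into train/validation/
test (sizes `floor(0.8n)`, `floor(0.1n)`, remainder — 416/52/53 for
n=521); after every epoch the model is scored on the validation split and
the best-on-validation weights are kept. The head bias is initialized to
the mean training age, which removes the long initial transient of the
MAE loss without affecting the optimum. All randomness (split, weight
init, shuffling, dropout) fans out deterministically from one seed via
`numpy` `SeedSequence` spawning, so seeded runs are bit-reproducible in
single-threaded execution.

### Bias correction and evaluation

Predicted brain age regresses toward the training mean, so the brain-age
gap (predicted − chronological) correlates negatively with age. On the
*training split only*, ordinary least squares fits `gap = α·age + β`, and
`corrected = predicted − (α·age + β)` is applied uniformly to all splits.
Metrics are MAE, RMSE, and R² against chronological age, reported per
split for corrected and raw predictions.

**A caution discovered during development:** for a degenerate
near-constant predictor, `gap ≈ −age + c`, so the correction alone
reconstructs age and corrected metrics look perfect (R² ≈ 1) even though
the model learned nothing. Corrected metrics are therefore reported but
never used as evidence of learning; the package's own recovery checks
assert on raw (uncorrected) predictions.

## Synthetic cohort generator

The generator emulates *preprocessed* pipeline outputs, not raw scanner
data, and its parameters are study conditions, not tuning knobs:

- **sMRI**: voxel intensity `0.5 − 0.002·(age − 53)` plus a fixed set of
  spherical "atrophy" foci decaying at twice the global slope, iid voxel
  noise (sd 0.05), and a per-subject intensity offset (sd 0.01).
- **DTI**: an independent linear trend (`0.45 − 0.0015·(age − 53)`), with
  its own subject offset and voxel noise.
- **MEG PSD**: `1/f` background plus a Gaussian alpha peak (center 10 Hz
  at the reference age, width 1.5 Hz) whose center drifts −0.03 Hz/year,
  with per-region gain, multiplicative spectral noise, and a per-subject
  peak jitter of 0.15 Hz.

The subject-level offsets are the load-bearing design choice. With iid
voxel noise alone, the spatial mean over even a 32³ grid recovers the age
trend almost noiselessly from a single modality, making fusion pointless.
The offsets set each modality's *age-equivalent* noise floor, and they
are deliberately matched across modalities (0.01/0.002 = 5 years for
sMRI; 0.15/0.03 Hz-per-year = 5 years for MEG; 0.01/0.0015 ≈ 6.7 years
for DTI) so that no single modality saturates the fused ceiling and the
multimodal comparison is informative: the ideal fused estimator's error
(≈ 2.9 years, combining three roughly-5-year modalities) is clearly below
the best unimodal one. Focal geometry is derived from the grid shape and
focus count only, so it is constant across a cohort. Ages are uniform
over the requested range; everything is deterministic given the seed.

## Problem sizes

Full scale matches the protocol the model family was designed for:
`96×128×96` volumes, 68 regions × 64 frequency bins, default channel
widths, 300 epochs. That configuration is CPU-hostile, so the package's
own study condition for recovery experiments — chosen as a problem-size
decision, not a time limit — is the **desk profile**: n=200 subjects,
32³ volumes, 68×64 PSD, SFCN widths `(2, 4, 8, 16, 16)`, MEG encoder
`d_model 32`, 1 layer, feed-forward 64, learning rate 1e-3, 15 epochs,
batch 12, fusion dropout 0. One trimodal run takes about a minute on one
CPU and reaches uncorrected test R² ≈ 0.9. Dropout is disabled at desk
scale because the baselines (`concat`, `add`, unimodal) have no dropout
anywhere, while the default low-rank layer applies dropout 0.1 to its
inputs; with 160 training subjects and 15 epochs that asymmetry
systematically penalizes the low-rank path without any regularization
benefit.

## Numerical choices

- **No deep-learning framework.** The package ships a small NumPy
  reverse-mode autograd (`brainfuse.nn`): tape-based `Tensor`, fused
  custom ops for the expensive layers, Adam. Gradients of every layer are
  verified against float64 central finite differences in the test suite.
- **Convolution** uses an im2col + batched GEMM path while the column
  buffer stays under 192 MB, and an offset/`tensordot` shift-accumulate
  path above that (full-resolution volumes). Both paths share the test
  oracle and agree to float32 round-off.
- **float32 end-to-end.** Python scalars are kept as scalars inside the
  autograd ops; wrapping them in 0-d arrays would silently promote the
  whole graph (and, after one optimizer step, the parameters) to float64,
  which doubles memory traffic. A regression test asserts the dtype.
- **BatchNorm/MaxPool** use fused closed-form backward passes rather than
  compositions of elementwise ops; batch norm freezes its running
  statistics at inference so constant inputs stay finite.
- **Softmax** subtracts the detached per-row maximum (shift invariance
  holds for both value and gradient).
- Checkpoints are single `.npz` archives with the configuration embedded
  as JSON; predictions and reports are TSV.

## Limitations

- The generator's linear trends and single spectral peak are far simpler
  than real aging physiology; results on it validate the machinery, not
  the science of brain aging.
- Gap-based bias correction can manufacture apparent accuracy for
  degenerate predictors (see above); corrected metrics must always be
  read next to raw ones.
- Desk-profile accuracy figures are not comparable to full-scale training
  on real cohorts; no claim is made about real-data performance.
- Training is single-threaded NumPy; there is no GPU path, and wall-clock
  scaling to full-size volumes is poor (the architecture supports them,
  the compute budget usually does not).
- At desk scale (n≈160 training subjects, short epoch budgets) simple
  concatenation followed by a linear head is a very strong baseline: it
  has orders of magnitude fewer fusion parameters than the rank-4
  factorization and nothing to undertrain. In repeated 5-seed desk
  experiments, low-rank fusion matched concatenation on the
  fused-beats-unimodal ordering and was more stable across seeds, but
  lost to it outright on test MAE on a majority of seeds by roughly
  0.5–0.9 years. The expressiveness advantage of multiplicative fusion
  should not be expected to show up at these sample sizes.
- The rank-r factorization is one of several possible low-rank forms of
  the fusion tensor; alternatives (e.g. shared factors across outputs)
  are out of scope.
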