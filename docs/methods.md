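# Methods

## Problem and model

`vitseq` classifies skull-stripped, MNI-registered T1-weighted 3D brain MRI
volumes into diagnostic classes (cognitively normal NC, mild cognitive
impairment MCI, Alzheimer's disease AD) by recasting volumetric
classification as *sequence* classification:

1. **Slicing.** A volume on the canonical (x, y, z) = (LR, PA, IS) grid is
   cut along one anatomical plane into an ordered stack of 2D slices
   (axial: one slice per z, shape x×y; coronal: per y, x×z; sagittal: per
   x, y×z). On the 113×137×113 MNI grid this gives 113 axial slices of
   113×137, 137 coronal of 113×113 and 113 sagittal of 137×113.
2. **Per-slice encoding.** Each slice is stretched to 224×224, replicated
   to three channels, cut into non-overlapping 16×16 patches (a 14×14
   grid, 196 tokens), linearly projected to the model dimension D,
   augmented with a learnable class token and position embeddings, and
   passed through pre-norm transformer blocks
   (x ← x + MHSA(LN(x)); x ← x + FF(LN(x)), scaled dot-product attention
   softmax(QKᵀ/√d_head)·V per head). The slice feature is the final-layer
   class-token state (token mean when the class token is disabled).
3. **Sequence classification.** The ordered n_slices×D feature matrix is
   classified by a *time-series transformer* (TST): fixed sinusoidal
   positional encodings are added (no input embedding — the model
   dimension equals the feature dimension by construction), transformer
   blocks mix along the slice axis, tokens are mean-pooled and a linear
   head produces softmax class probabilities.

Two baseline arms complete the 2×2 comparison: a compact CNN slice encoder
(stacked 3×3 conv → ReLU → 2×2 average pool, first conv stride 2, channel
width doubling per block, global average pool, linear readout) and a
bidirectional-LSTM sequence head (final forward and backward hidden states
concatenated, then a linear head). All four combinations — CNN-Bi-LSTM,
CNN-TST, ViT-Bi-LSTM, ViT-TST — are formed purely by composing encoders and
heads behind one FeatureSequence contract.

All networks run on a small in-package reverse-mode autodiff engine over
numpy (`vitseq.autograd` / `vitseq.nn`), gradient-checked against central
finite differences in the test suite. Adam minimizes cross-entropy, with
early stopping on validation loss and best-state restoration.

## Key parameters

| parameter | default | meaning / rationale |
|---|---|---|
| encoder D, depth, heads | 768 / 12 / 12 (full-scale ViT-B/16) | standard ViT-B/16 layout; pretrained .npz weights loadable, never required |
| test-scale encoder | D=32, depth 2, heads 2 | same geometry, sized for single-CPU runs; used by tests and the bundled protocol |
| patch side | 16 px | with 224×224 inputs gives the 14×14 grid of 196 tokens |
| TST head | depth 2, heads 2, mlp_ratio 2, mean pooling, sinusoidal positions | positional mode and pooling switchable (learned / class token) |
| Bi-LSTM head | hidden 128 (config default); the bundled desk-scale protocol uses hidden 32, 1 layer | forget-gate bias initialized to +1 so the cell starts with long memory — with ~113-step sequences this materially speeds convergence |
| split fractions | 60/20/20, test and validation floored, train = remainder | the only rounding rule consistent with published tuples (211, 70, 70) from 351 scans and (1378, 458, 458) from 2294 |
| training | Adam, lr 1e-4, batch 8, patience 10 (config default); `compare_architectures` uses lr 1e-3, 120 epochs, patience 25 | the higher rate and longer schedule are sized for the small frozen-feature heads of the desk-scale protocol |
| repetitions k | configurable, default 5; protocol runs use k=3 | "±" is the sample standard deviation of the metric over k independent split/train/evaluate cycles (seeds base_seed … base_seed+k−1) |

Encoders are used as *frozen* feature extractors in the bundled protocol
(mirroring transfer learning with a pretrained backbone): features are
computed once per (plane, encoder) and the k cycles re-split, re-train and
re-evaluate only the sequence head. `train()` optimizes whatever parameters
require gradients, so end-to-end fine-tuning works by leaving the encoder
unfrozen.

## Synthetic phantoms

The phantom generator emulates the *statistical shape* of the classification
problem, not anatomy. Each volume is an ellipsoidal "brain" (semi-axes 45 %
of each grid extent, ±3 % per-volume jitter shared across classes at a given
index) of mid-gray tissue (0.45), with a bright peripheral "cortical" band
(normalized radius ≥ 0.82) and a central near-zero "ventricular" cavity.
Disease severity is encoded as ventricle enlargement (radius fractions
NC 0.12 / MCI 0.20 / AD 0.30 of the brain radius) plus cortical dimming
(0.90 / 0.82 / 0.74) — a crude atrophy proxy producing a monotone signal
visible in every plane. Gaussian noise (sd 0.05) is added inside the brain
and intensities clipped to [0, 1]; background is exactly 0. A single
`separability` knob linearly scales all class offsets from the NC anchor:
at 0 every class has NC morphology and only the noise stream differs, so
chance-level accuracy is the correct outcome. Per-volume randomness derives
from `SeedSequence([seed, stream_tag, (class,) index])`, making any subset
reproducible; the morphology stream deliberately excludes the class so the
null case is exact.

What the phantoms do **not** model: anatomical texture, partial-volume
effects, scanner bias fields, registration error, inter-subject variability
beyond global jitter, or any MCI heterogeneity. Passing the end-to-end
tests therefore demonstrates that the pipeline is wired correctly and can
recover a planted monotone morphological signal — not clinical performance.

## Evaluation protocol

Within each repeated cycle, feature dimensions are z-scored using training
split statistics only, then fed to the head: frozen random encoders emit
features of arbitrary (seed-dependent) scale, while the sinusoidal
positional encoding and the LSTM gates assume roughly unit-scale inputs —
without this step a small-scale feature set is swamped by the positional
terms.

Scans are split 60/20/20 at the scan level (subject-level splitting is the
leakage-safe alternative for repeat-scan collections; the bundled protocol
splits scans, matching per-scan collection counts). Stratified splits use
largest-remainder apportionment per split, and are rejected as infeasible
when a class would be missing from any nonempty split. Metrics come from the
fixed-class-order (NC, MCI, AD) confusion matrix only: accuracy (percent),
per-class and macro precision/recall/F1. A class never predicted (or never
present) gets precision (recall) 0 with an explicit undefined flag rather
than NaN. The binary task filters MCI scans *before* splitting.

## Numerical choices and degenerate inputs

* float64 throughout; determinism via injected `numpy.random.Generator`s.
* Softmax/log-softmax are max-shifted; LayerNorm uses eps 1e-6.
* Bilinear slice resize (anisotropic stretch, no aspect-ratio padding),
  clipped to [0, 1]; intensity normalization is affine min-max.
* Constant volumes and non-finite intensities are rejected at
  normalization; non-NIfTI files raise a corrupt-input error; off-grid
  volumes warn by default, raise in strict mode.
* Early stopping compares validation loss with strict improvement;
  on ties the earlier state is kept. Non-finite training loss aborts with
  a divergence error.

## Problem sizes

The bundled end-to-end protocol uses 60 phantoms (30 NC / 30 AD), the
axial plane, test-scale encoders (D=32), k=3 repeated runs, and the same
for the zero-separability control — sizes chosen so the complete protocol
runs on a single CPU core in minutes while leaving a wide margin between
the planted-signal (≥ 90–95 % accuracy) and null (≈ 50 %) regimes.

## Known limitations

* Reported clinical-scale accuracies require the access-restricted ADNI
  collections and are out of scope; nothing here estimates them.
* The Bi-LSTM uses final-state readout; mean-over-states pooling sometimes
  trains faster but changes the baseline's definition.
* Stacked (n_layers > 1) Bi-LSTMs feed only the broadcast final states to
  deeper layers, since only the final states reach the classifier head.
* The numpy engine is single-threaded; full-scale (ViT-B/16, depth 12)
  forward passes work but are slow — it is intended for test-scale science,
  not GPU-scale training.
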