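# Methods

## The classification problem

Each example is one short MD trajectory of an enzyme–ligand complex, reduced
to a T × D matrix: T = 1,000 frames (20 ps, 0.02 ps per frame) and D = 15
geometric descriptors per frame. Descriptors are distances (Å), angles
([0°, 180°]) and signed dihedrals ([−180°, 180°), IUPAC convention; 0° = cis).
The label is binary: *reactive* if the ligand in the complex is the enzyme's
preferred enantiomer, *non-reactive* otherwise; the preference is per ligand
(typically S, for a minority of ligands R). The split between training and
validation is **by ligand**, never random: a model is always scored on
compounds it has not seen, so validation accuracy measures chemical
generalization, not memorization.

## Architectures and training regimes

All four networks run on a small in-package numpy engine (`trajsel.nn`) with
valid (unpadded) convolutions, non-overlapping max pooling, a standard LSTM
cell (gate order i,f,g,o; forget-gate bias 1), inverted dropout, RMSprop
(ρ = 0.9, ε = 1e-7) and Adam (β = 0.9/0.999, ε = 1e-7). Hidden activations
are ReLU unless noted. Weight initialization is Glorot-uniform from a
recorded seed; every fit shuffles with its own seeded generator, so training
histories are bit-reproducible single-threaded. Backward passes are verified
against float64 central differences (≤ 1e-7 relative error) in the test
suite.

| id | stack | regime |
|---|---|---|
| `cnn1d` | Conv1D(16,k7) → MaxPool(5) → Conv1D(16,k7) → GlobalMaxPool → Dense(1)+sigmoid | RMSprop 1e-4, 10 epochs, batch 8, BCE |
| `cnn2d` | Conv2D(8,1×5) → MaxPool(1×3) → Dropout(0.3) → Conv2D(4,1×5) → MaxPool(1×3) → Flatten → Dense(1)+sigmoid | RMSprop 1e-4, 20 epochs, batch 16, BCE |
| `cnn2d_cam` | [Conv2D(3×3)+MaxPool(2×2)] × 4 (128/64/32/16) → Flatten → Dense(256) → Dense(1)+sigmoid | RMSprop 1e-4, 20 epochs, batch 1, BCE |
| `lstm_forecaster` | LSTM(16) → LSTM(8) → Dense(1, linear) | Adam 0.01, 5 epochs, batch 128, MSE |

With the default input sizes the valid-convolution arithmetic gives
1000→994→198→192→16 (1-D stack), time widths 996→332→328→109 and flatten
length 6,540 (2-D stack), and spatial sizes 318→159→157→78→76→38→36→18 with
a final 18×18×16 feature map (image stack). These equalities are asserted in
tests. The output sigmoid is implemented as its own layer after a linear
Dense(1) so that saliency code can address the pre-sigmoid score; the
classification threshold is 0.5.

Forecasting uses sliding windows of 50 frames with the next value of the
query descriptor (d4 by default) as target; windows never cross trajectory
boundaries, and the default stride of 19 yields 50 windows per 1,000-frame
trajectory (490,000 at full study size). Reference forecasters: persistence
(predict the last observed query value), an affine map on the flattened
window, a one-hidden-layer (64-unit) dense net, and a small temporal-conv
regressor (Conv1D(16,k7) → GlobalMaxPool → Dense(1)). The 8-d final state of
the second LSTM is the window embedding; a trajectory embedding is the mean
of its window embeddings, and the semi-supervised classifier is a single
dense sigmoid head on those (RMSprop 1e-3, 20 epochs, batch 32 — a design
choice, as is the mean aggregation).

## Synthetic trajectory generator

No trajectory data ship with the package; the generator emulates the study's
statistical structure so every stage is testable without an MD engine.

**The hard constraint** is marginal matching: per channel, the pooled value
distributions of the two classes must be indistinguishable, so that class
information is carried only by dynamics. Channels are built in a
dimensionless signal space z and mapped affinely to physical units
(0.5 Å, 8°, or 15° per z-unit for distance/angle/dihedral channels), with
per-ligand baselines; angles are clipped to [0°, 180°], dihedrals wrapped,
distances floored at 0.05 Å.

* **Background**: every channel is a unit-amplitude sinusoid with a random
  per-trajectory frequency from the slow band (0.8–1.6 cycles per 100
  frames) and phase, plus i.i.d. Gaussian frame noise (σ = 0.2 z).
* **Temporal mode (default)**: the informative channels (defaults 3, 4, 10 —
  the d4/d5/d11 analogues, weighted 1.0/0.6/0.6) mix in a sinusoid whose
  frequency is drawn from the fast band (5–8 cycles per 100 frames) for
  reactive trajectories and from the slow band for non-reactive ones. The
  pooled marginal of a random-phase sinusoid is the arcsine law regardless of
  frequency, so marginals match by construction; shuffling frame order
  destroys the signal exactly (shuffled fast and slow sinusoids are i.i.d.
  draws from the same marginal).
* **Coupling mode**: the informative channels share one slow frequency
  (amplitude 2.5 z) and, in the reactive class only, a common phase; the
  non-reactive class randomizes the phase ordering. The instantaneous joint
  configuration carries the class, so this signal *survives* frame
  shuffling — the complementary control to the temporal mode.
* **Slow χ1-like channel** (index 2): a reflected random walk (step σ = 1°)
  inside ±12° around −90°, the catalytic orientation both classes are docked
  in; the walk is keyed by (ligand, replicate) only, so paired replicates of
  the two classes share the identical path and the channel carries no class
  signal at all.
* **Ligand identity**: channel baselines are drawn per ligand (distances
  3.5–4.5 Å, angles 85–105°, dihedrals ±40°), making the ligand-held-out
  split a real generalization test; 15 % of ligands are "hard" (signal
  weight × 0.6), reproducing the per-ligand error structure seen in real
  compound panels. Roughly 10 % of ligands prefer the R enantiomer.
* **Null control**: `generate_null_dataset` permutes labels within each
  ligand, preserving counts while destroying all class signal.

Determinism: every trajectory's stream is keyed by (master seed, ligand,
class, replicate) via `SeedSequence` spawn keys, so full datasets regenerate
bit-identically and single trajectories can be regenerated in isolation.

Baseline spread, noise level, frequency bands and the hard-ligand attenuation
were fixed once while designing the generator, with two goals: inter-ligand
variability comparable to the within-trajectory dynamic range (so ligands
differ meaningfully but a minmax-normalized channel is not dominated by
baseline offsets), and a class signal that the fixed, published training
regime — whose gradient-step budget is set by dataset size, not by us — can
learn robustly. What passing tests show is therefore that the implementation
of the models, regimes and analyses is correct and that the pipeline detects
purely-temporal class structure of realistic strength; they do not show that
real MD descriptor series are this clean, stationary, or Gaussian-noised,
nor that real accuracy would match.

## Normalization

Per-channel min–max to [0, 1], fitted on the training split only. Values
outside the fitted range (possible for unseen ligands) are clipped and
counted in the log. A constant channel gets scale 1 with a warning. Apply
followed by invert is the identity for unclipped values. Angles and
dihedrals enter the network as raw normalized values, not sin/cos pairs;
wrap-around discontinuities in dihedral channels are accepted (an optional
unwrap is deliberately not applied by default).

## Rendered trajectory images

For the image classifier each normalized trajectory is drawn as D dark
polyline traces (value 0) on a light background (value 1) in a size×size
grayscale image: each channel owns a horizontal band of ⌊size/D⌋ rows whose
top 4 rows stay blank (so bands never touch; remainder rows pad the bottom),
the T frames are linearly resampled to the image width, and adjacent columns
are joined by vertical pixel runs without anti-aliasing — the image is a
deterministic function of the tensor, which the tests exploit via an
independent per-column rasterization oracle.

## Interpretation

* **Ablation**: for each channel, a fresh 1-D CNN is trained on that single
  channel (input T × 1) with the standard regime, five replicas with
  different seeds; reported as mean ± sd next to an all-channel reference
  trained with the same seeds. Deterministic given the study seed.
* **1-D CAM**: the 1-D stack ends in GlobalMaxPool → Dense(1), exactly the
  structure classic class-activation mapping requires, so filter f's
  saliency is its final-conv feature map × its output weight, negatives
  clipped; a raw (unweighted post-ReLU) mode is also provided. Maps are
  upsampled by nearest-neighbour repeat with the pooling factor 5 (keeping
  them honestly piecewise-constant), centred on the frame axis with edge
  frames carrying the nearest value. Receptive-field bookkeeping (final-conv
  position j sees frames [5j, 5j+40]) is asserted against impulse responses.
  Reports default to the filter with the largest |output weight|, since an
  arbitrary fixed filter index can be dead under a given seed.
* **2-D Grad-CAM**: the image stack has hidden dense layers after Flatten,
  which makes classic CAM structurally impossible, so gradient-weighted CAM
  is used: channel weights are the spatial means of the pre-sigmoid score
  gradient at the final pooled 16-channel feature map; the rectified
  weighted sum is bilinearly upsampled to the input. The substitution is
  recorded in the map's metadata.
* **Latent space**: t-SNE (scikit-learn, perplexity 30, PCA initialization,
  fixed seed) of the 16-d GlobalMaxPool embeddings of a chosen split.

## Numerical and degenerate-input choices

* Angle/dihedral computations raise on coincident or collinear atoms
  (tolerance 1e-10) with the offending frame index; +180° maps to −180°.
* ROC-AUC comes from scikit-learn and is cross-checked in tests against a
  brute-force pairwise-concordance count; accuracy ties at the 0.5
  threshold resolve to the positive class (p ≥ 0.5).
* Saliency argmax ties break to the earliest frame.
* BCE is computed with probabilities clipped at 1e-7; the gradient uses the
  fused sigmoid+BCE form (p − y), so training is stable at saturation.
* Non-finite training loss aborts immediately with epoch/batch diagnostics.

## Problem sizes used in the shipped checks

The full-size dataset (9,800 × 1,000 × 15) is generated once to verify the
study's exact counts. Model-training checks run on reduced generations
(typically 8–16 ligands, 60–100 trajectories per class and per ligand,
250–1,000 frames), chosen as the smallest sizes at which the fixed training
regimes have enough gradient steps to converge; the acceptance script states
its sizes in its output. The image-saliency check uses 64×64 renders of
4-channel trajectories, which scale the CAM stack's arithmetic without
changing its structure.

## Known limitations

* The generator is a statistical emulator: no force-field realism, solvent,
  kinetics, or inter-descriptor geometric consistency (a real d4 and d5 share
  atoms; the synthetic analogues are independent channels).
* The numpy engine is single-threaded-deterministic but not fast; full-size
  (9,800-trajectory) training is feasible yet slow, and the shipped checks
  use the reduced sizes above.
* Descriptors d2, d7–d10, d13 and d14 have no fixed chemical identity in the
  default set; they are configurable placeholders with the documented
  kind/unit layout.
* The LSTM embedding classifier is expected to sit at chance on
  class-uninformative data and is not a competitive classifier on informative
  data either — consistent with the negative semi-supervised result it
  reproduces.
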