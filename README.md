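# trajsel

Deep-learning classification of short molecular-dynamics trajectories of
enzyme–ligand complexes, for predicting enzyme enantioselectivity.

## The problem

ω-Transaminases convert ketones into chiral amines, and for a given substrate
the enzyme prefers one mirror-image form (enantiomer) over the other.
Whether a docked enzyme–ligand complex can actually react shows up in how the
complex moves during even a very short (20 ps) MD simulation — but not in any
single hand-crafted geometric criterion. `trajsel` treats each trajectory as a
multichannel time series of **D = 15 geometric descriptors** (distances in Å,
angles and dihedrals in degrees, e.g. the proton–nucleophile distance Hα–Nz
or the slow ligand-orientation dihedral χ1) sampled at **T = 1,000 frames**,
and trains small neural networks to label each trajectory as containing the
**reactive** (preferred) or **non-reactive** enantiomer.

The package implements the complete workflow:

* **`trajsel.synthetic`** — a statistical trajectory generator emulating the
  full study (49 ligands × 2 classes × 100 trajectories × 1,000 frames × 15
  channels). Its defining property mirrors the real data: the per-channel
  value distributions of the two classes are *identical by construction*;
  class information lives only in temporal patterns (default) or
  cross-channel phase coupling, so nothing short of a sequence model can
  separate the classes.
* **`trajsel.featurize`** — distances / angles / dihedrals from raw
  coordinates (multi-model PDB reader built in), plus train-split-only
  min–max normalization.
* **`trajsel.data`** — ligand-held-out train/validation splits (validation
  ligands are never seen in training, so accuracy measures generalization to
  new compounds), and the four network encodings: (N, 1000, 15) signals,
  (N, 15, 1000, 1) matrix images, rendered 320×320 trace images, and
  (N, 50, 15) forecasting windows.
* **`trajsel.models`** — the four architectures with their fixed training
  regimes, on a small in-package numpy NN engine (`trajsel.nn`):
  * 1D-CNN: Conv1D(16,k7) → MaxPool(5) → Conv1D(16,k7) → GlobalMaxPool →
    Dense(1, sigmoid); RMSprop 1e-4, 10 epochs, batch 8, binary cross-entropy.
  * 2D-CNN: Conv2D(8,1×5) → MaxPool(1×3) → Dropout(0.3) → Conv2D(4,1×5) →
    MaxPool(1×3) → Flatten → Dense(1, sigmoid); 20 epochs, batch 16.
  * CAM 2D-CNN: four Conv(3×3)/MaxPool(2×2) blocks (128/64/32/16 filters) →
    Flatten → Dense(256) → Dense(1, sigmoid); 20 epochs, batch 1.
  * LSTM forecaster: LSTM(16) → LSTM(8) → Dense(1); Adam 0.01, 5 epochs,
    batch 128, MSE — predicts the query descriptor (d4) at the next step;
    the second LSTM state is an 8-d window embedding for semi-supervised
    classification. Reference forecasters: persistence, linear, dense,
    temporal-conv.
* **`trajsel.interpret`** — channel ablation (15 single-channel models × 5
  replicas + an "All" reference), class-activation maps for the 1D-CNN,
  Grad-CAM for the image model, per-trajectory maximum-activation records,
  and t-SNE (perplexity 30) of the 16-d penultimate embeddings.

## Worked example

```python
from trajsel.synthetic import GeneratorConfig, generate_dataset
from trajsel.data import default_split
from trajsel.models import ArchitectureSpec, build_cnn1d, train_classifier, evaluate

cfg = GeneratorConfig(n_ligands=12, n_per_class=100, n_frames=1000, master_seed=7)
bundle = generate_dataset(cfg)          # 2,400 trajectories, 1000 x 15 each
default_split(bundle, 0.75)             # ligands 1-9 train, 10-12 validation
bundle.fit_normalizer()                 # min-max fitted on the train split only

model = build_cnn1d(bundle.n_frames, bundle.n_channels, seed=7)
trained = train_classifier(model, bundle, ArchitectureSpec.default("cnn1d", seed=7))
report = evaluate(trained, bundle, "validation")
print(f"validation accuracy {report.accuracy:.3f}  ROC-AUC {report.roc_auc:.3f}")
print(report.per_ligand)
```

Output:

```
validation accuracy 0.938  ROC-AUC 0.996
   ligand_id  misclassified_reactive  misclassified_nonreactive    n
0         10                       0                          1  200
1         11                       5                          0  200
2         12                      30                          1  200
```

The classifier generalizes to the three held-out ligands (each evaluated on
200 trajectories it has never seen); ligand 12 is one of the generator's
intrinsically harder ligands (attenuated signal), which is why its reactive
trajectories are misclassified more often — the same per-ligand error
structure seen when ranking real compounds.

The same end-to-end flow is available from the shell:

```bash
trajsel demo --out demo_run --seed 0          # reduced one-command pipeline
trajsel synth --n-ligands 12 --n-per-class 100 --frames 1000 --seed 7 --out data.h5
trajsel dataset --in data.h5 --train-ligands 1-9 --val-ligands 10-12 --out dataset.h5
trajsel train --arch cnn1d --data dataset.h5 --seed 7 --out model.npz
trajsel eval --model model.npz --data dataset.h5
trajsel explain --model model.npz --data dataset.h5 --what ablation
```

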