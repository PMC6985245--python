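# dropsort

Image-based single-cell **viability sorting** for drop-on-demand dispensers,
in silico.

Single-cell printers isolate one cell per microwell by imaging the dispenser
nozzle and only depositing droplets in which a feature-based algorithm (object
count, size, roundness) sees exactly one cell. That gate cannot tell whether
the cell will actually *grow*: damaged or senescent cells look like intact
single cells, so in hard samples most populated wells never produce a colony
and the *clone recovery* — colonies per populated well — stays low. dropsort
implements the obvious extension: a shallow convolutional neural network that
scores each 55×55 nozzle crop with a growth probability *P*, so the shutter
can discard cells with *P* ≤ *T* and deposit only likely-viable ones.

The package is aimed at people studying image-gated cell sorting and cell-line
development workflows who need a fully synthetic, end-to-end testbed: no
instrument data is required anywhere.

## What is inside

| module | contents |
|---|---|
| `dropsort.imaging` | synthetic nozzle-camera frame pairs (empty + cell) and labeled crop datasets with a configurable viable fraction c_v |
| `dropsort.detection` | background subtraction, Otsu/fixed segmentation, area/perimeter/roundness features, the single-cell verdict, 55×55 cropping |
| `dropsort.classifier` | `ViabilityCNN` model / `ViabilityCNNResults`: the shallow CNNs (CNN-4/32, CNN-32/128), class-weighted training, augmentation, 10-fold CV, save/load |
| `dropsort.metrics` | confusion rates, ROC/AUC under the strict *P* > *T* rule, predicted clone recovery, growth increase (GI), campaign pooling |
| `dropsort.throughput` | `ThroughputModel`: Poisson droplet occupancy + renewal timing → cloning frequency and recovery as functions of *T* |
| `dropsort.simulator` | event-driven dispensing runs (droplet → detection gate → CNN gate → well → colony) and the three-arm sorting benchmark |
| `dropsort.cli` | `dropsort generate / train / evaluate / sweep / simulate / fig6 / pipeline / config` |

## The model in brief

For a sample whose dispensed single cells grow without any classifier at rate
c_v, a classifier operating at true-positive rate TPR and dead-pass rate
d = FP/(TN+FP) yields

    recovery(T) = c_v·TPR / (c_v·TPR + (1 − c_v)·d),      GI = recovery / c_v,

with GI = 1 for an accept-all gate and GI ≤ 1/c_v. Droplet occupancy is
Poisson with λ = C·V (concentration × droplet volume; λ = 0.16 at the default
10⁶ cells/ml and 160 pl, so P(single cell) = λe^(−λ) ≈ 0.136). Each accepted
droplet costs a deposition dead time t_deposit on top of the dispensing clock
f_disp, giving the cloning frequency — viable cells dispensed per second —

    f(T) = [c_v·TPR / p_pass] / [1/(f_disp·p_single·p_pass) + t_deposit],
    p_pass = c_v·TPR + (1 − c_v)·d.

Raising *T* always raises recovery for a well-ordered classifier but
eventually starves the dispenser; the sweep exposes the trade-off and the
frequency-optimal threshold.

## Worked example

```python
import numpy as np
from dropsort import (ViabilityCNN, TrainConfig, build_cnn, SorterConfig,
                      ThroughputModel, roc_auc, fig6_experiment)
from dropsort.imaging import generate_dataset

manifest, crops = generate_dataset(400, c_v=0.5, seed=7)
model = ViabilityCNN(crops, manifest["label"].to_numpy(),
                     spec=build_cnn(4, 32), split=manifest["split"].to_numpy())
res = model.fit(TrainConfig(epochs=30, seed=1))
print(res.summary())

va = res.val_indices
labels_va = manifest["label"].to_numpy()[va]
print(res.evaluate(crops[va], labels_va))

curve, auc = roc_auc(labels_va, res.predict(crops[va]))
sweep = ThroughputModel(SorterConfig(c_v=0.27)).sweep(curve)
print(f"best cloning frequency {sweep.attrs['best_frequency_hz']:.3f} Hz "
      f"at T={sweep.attrs['best_frequency_threshold']:.2f} "
      f"(GI {sweep.attrs['gi_at_best_frequency']:.2f})")

report = fig6_experiment(SorterConfig(), model=res, seed=99)
print(f"empirical GI {report['empirical_GI']:.2f} "
      f"(analytic {report['analytic_GI_at_operating_point']:.2f})")
```

prints

```
CNN-4/32: shallow CNN viability classifier
====================================================
architecture: conv 3x3 x4 (same, ReLU) -> maxpool 2x2 -> conv 3x3 x4 (same, ReLU) -> maxpool 2x2 -> flatten -> dense 32 (ReLU) -> dense 1 (sigmoid)
normalization: clip(diff, -255, 255) -> [0, 1], background at 0.5
train/val:     320/80 crops (fingerprint 5a534983b95399ae)
epochs:        30  batch 32  lr 0.001
final loss:    train 0.0811  val 0.0615  (min val 0.0615 @ epoch 30)
{'ACC': 1.0, 'AUC': 1.0, 'TPR': 1.0, 'dead_pass_rate': 0.0, 'threshold': 0.5}
best cloning frequency 0.350 Hz at T=0.30 (GI 3.70)
empirical GI 3.35 (analytic 3.51)
```

On this synthetic benchmark the two morphological classes are separable by
construction, so the validation metrics saturate; the interesting outputs are
the threshold economics (here a 3.7-fold GI is available near the
frequency-optimal threshold for a 27 %-recovery sample) and the agreement
between the event-driven simulation (GI 3.35 over 288 wells) and the
closed-form prediction at the classifier's measured operating point (3.51) —
the gap is well within the binomial noise of three 96-well plates.

The same steps are available from the shell:

```bash
dropsort generate --n 400 --cv 0.5 --seed 7 --out data/
dropsort train --manifest data/manifest.csv --arch 4/32 --epochs 30 --out model.npz
dropsort evaluate --model model.npz --manifest data/manifest.csv
dropsort fig6 --model model.npz --seed 99
```

## Documentation

`docs/methods.md` describes the synthetic-imaging model, the network and
training protocol, the metric conventions (including why the dead-recognition
rate is *not* called a false-positive rate here), the throughput model's
assumptions, and known limitations.
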