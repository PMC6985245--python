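# Methods

This note documents the models, conventions and design choices behind
dropsort, in the order data flows through the package.

## Synthetic nozzle imagery

The generator emulates the image stream of a drop-on-demand single-cell
printer: for every dispense event, a frame of the nozzle region plus an
"empty" frame captured just before the cell arrived, sharing one background
realization so a posteriori background subtraction is effective but not
perfect (the two frames carry independent per-pixel camera noise).

* **Background** — mean gray level (default 120 on an 8-bit scale), a
  randomly oriented linear illumination ramp (default ±5 % across the frame),
  and i.i.d. Gaussian pixel noise (default SD 3). Intensities are clipped to
  the representable range, never wrapped.
* **Viable cell** — a single disk of radius ~N(8, 1) px with a smooth
  sigmoid radial roll-off and a +60 gray-value body contrast. Its binarized
  isoperimetric roundness 4πA/P² is ≥ 0.9.
* **Dead cell** — by default a single blob whose boundary radius is modulated
  by random low-order angular harmonics (amplitude 0.5·r) at 0.6× the viable
  contrast. Crucially, such cells still pass a size/roundness single-cell
  gate — which is precisely why a learned classifier adds value. Setting
  `dead_fragmentation > 1` instead renders that many scattered sub-blobs;
  fragmented debris is then (realistically) rejected by the detection gate,
  so fragmentation is an opt-in robustness knob rather than the default.
* **Growth label** — growth is class-conditional Bernoulli, defaults 0.95
  (viable morphology) and 0.02 (dead morphology), chosen to mirror
  trypan-blue viabilities of fresh (~97 %) versus deliberately damaged
  (<1 %) cell suspensions. Because growth is stochastic, simulated clone
  recoveries carry sampling noise like a real incubation readout.

What the generator does **not** model: realistic optics (diffraction,
defocus, halo), cell motion blur, debris and satellite droplets,
multi-cell-in-frame scenes (beyond what detection tests construct), and any
µm/px calibration — sizes are in pixels throughout, since nozzle-camera
calibration varies by instrument. Passing tests therefore demonstrate the
correctness of the pipeline's logic and arithmetic, not classifier
performance on real instrument imagery: the synthetic classes are separable
by construction, so accuracy/AUC saturate in a way real data would not.

Every generator output is a pure function of (parameters, seed).

## Detection gate

Standard feature-based single-cell detection on the signed difference image
(cell frame − empty frame, no clipping):

1. Gaussian presmoothing of |diff| (σ = 1.5 px) to suppress per-pixel camera
   noise; the cell body (radius ≫ σ) is essentially unaffected. Disable with
   `smoothing_sigma=0` for geometric oracle tests.
2. Otsu threshold on the smoothed magnitude (a fixed gray-value threshold is
   available for reproducibility), 8-connected components, area = pixel
   count, perimeter = contour length (scikit-image convention), roundness =
   4πA/P² clipped to 1. Degenerate point-like contours (P → 0) are counted
   as perfectly round; they are far below any sensible `area_min` anyway.
3. **Single-cell verdict**: exactly one object inside
   [`area_min`, `area_max`] with roundness ≥ `roundness_min`, and no second
   object of at least `area_min` anywhere in the frame — two cell-sized
   objects mean ambiguous droplet occupancy and are never dispensed as a
   single cell. The default gates (20–2000 px², roundness ≥ 0.5) are exposed
   placeholders, not instrument values.
4. **Cropping**: the centroid rounds to the nearest pixel and maps to the
   central pixel of a 55×55 window spanning [c−27, c+27]; out-of-frame parts
   are padded with the frame's median so border crops carry no artificial
   dark edge into the CNN.

## The shallow CNN

Two canonical architectures, CNN-4/32 and CNN-32/128 (filters per conv
layer / hidden nodes): conv 3×3 (stride 1, same padding, ReLU) → max-pool
2×2 → conv 3×3 → max-pool 2×2 → flatten → dense (ReLU) → dense 1 (sigmoid),
on 55×55×1 inputs. Kernel size, stride, padding and activations are our
choices — the minimal standard configuration consistent with an "extremely
shallow" design; no dropout is used, regularization comes from augmentation
and the tiny parameter count.

The implementation is self-contained NumPy (im2col convolutions, explicit
backward pass verified against numerical differentiation, Adam with step
size 10⁻³). At hundreds of training crops this trains in seconds on one CPU
core; there is deliberately no GPU path.

* **Normalization** — crops are signed differences; they are clipped to
  ±255 and mapped linearly to [0, 1], putting pure background at 0.5. The
  scheme is recorded in model provenance so deployment matches training.
  Internally the network re-centers the input at zero so early activations
  are signal-driven rather than bias-dominated.
* **Loss** — class-weighted binary cross-entropy on logits, weights
  N/(2·N_class) (sample-mean 1; for a balanced set this reduces to the
  unweighted loss — a closed-form identity the tests assert).
* **Augmentation** — horizontal/vertical flips, 90° rotations, integer
  shifts ≤ 3 px (median fill), ±10 % brightness jitter about the background
  level. Cells have no canonical orientation in the nozzle, so all of these
  are label-preserving.
* **Mini-batching** — one epoch is ⌈N/batch⌉ iterations over a reshuffled
  training set; per-epoch training and validation losses are recorded.
* **Determinism** — a single master seed fans out to weight initialization,
  shuffling and augmentation draws; identical seeds give bit-identical
  histories and predictions.
* **Cross-validation** — stratified k-fold (default k = 10), every record
  validated exactly once, metrics reported per fold and as fold means.
* **Serialization** — one self-describing NPZ container holding weights,
  architecture, training configuration, normalization scheme and a dataset
  fingerprint; load/save round-trips predictions bit-identically.

The classifier is exposed statsmodels-style: `ViabilityCNN` (model built
from data) → `fit()` → `ViabilityCNNResults` (estimates, history, summary,
persistence). The rest of the package is generators and closed-form
arithmetic, for which fitted-model objects would be artificial.

## Metric conventions

The positive class is *viable* and the decision rule is strict: viable iff
P > T (P = T counts as dead; T = 1 therefore rejects everything).

In this field's sorting literature the accuracy on dead cells,
TN/(TN+FP) — a specificity — is sometimes labeled "FPR". dropsort exposes
it under the honest name `dead_recognition_rate` (with `fpr_paper` kept as a
documented alias) and uses its complement, the **dead-pass rate**
FP/(TN+FP), as the ROC x-axis. This is the unique reading under which the
ROC/AUC axes are standard *and* the recovery formula's (1 − FPR) term is
consistent.

The ROC sweep covers every distinct score plus the T = 0 and T = 1
endpoints; the T = 0 row is reported as the gate-off (accept-all) limit so
the curve always spans (1,1) → (0,0). The trapezoidal AUC then equals the
tie-corrected pairwise statistic exactly (ties ½), which the tests verify
against a brute-force oracle and against scikit-learn.

Rates with vanishing denominators raise rather than returning 0, so
degenerate samples surface loudly. Campaign pooling uses integer colony
counts per component: Σ round(cᵢnᵢ) / Σ nᵢ.

## Throughput model

Droplet occupancy is Poisson with λ = C·V; only exactly-one-cell droplets
reach the classifier (the detection gate rejects empty and multi-cell
droplets). The cycle per accepted droplet is a renewal:
1/(f_disp·p_single·p_pass) waiting time plus t_deposit of deposition dead
time, with p_pass = c_v·TPR + (1−c_v)·dead_pass. Defaults: f_disp = 20 Hz,
V = 160 pl, C = 10⁶ /ml (λ = 0.16, p_single = 0.1363), t_deposit = 1.5 s.

t_deposit is a **calibration knob** summarising stage motion and plate
handling, chosen so the no-classifier cloning frequencies land in the few-
tenths-of-a-Hz range typical of plate-filling single-cell printers; it is
config-exposed and should be recalibrated per instrument. Classifier compute
time is ignored: a shallow net evaluates well inside one 50 ms droplet
period.

## Dispense simulator

An event-driven replay of a sorting run: droplets on the f_disp clock,
Poisson occupancy, detection gate, classifier gate, shutter, wells filling
column-major (A1→H1→A2…, 96 per plate), then Bernoulli colony growth.
Conservation (droplets = empty + multi-cell + detection-failed +
classifier-rejected + accepted) and the timing identity
elapsed = n_droplets/f_disp + accepted·t_deposit hold exactly.

The classifier gate accepts either a trained network (full imaging path:
render → subtract → detect → crop → predict) or an abstract operating point
(accept viable with probability TPR, dead with dead-pass) — the latter
matches the analytic model's assumptions exactly and is used for the
formula-versus-simulation agreement checks. Multi-cell droplets are always
rejected by the detection gate, and every accepted droplet is assumed to
deliver its cell to the well.

The three-arm benchmark dispenses (1) a fresh sample without the classifier
onto two 96-well plates, (2) a mixed fresh+damaged sample without the
classifier and (3) the same mixed sample with the classifier at T = 0.5,
three plates each, reporting per-arm recovery with across-plate SD and the
empirical GI. The mixture fractions are derived from the growth
probabilities so the no-classifier arms sit at 27 % (mixed,
c_v = 0.25/0.93 ≈ 0.269) and 76.8 % (fresh, c_v ≈ 0.804) expected recovery.
The classifier's operating point is estimated from the run itself (accepted
class counts over the expected class mix at the gate) and converted to an
analytic GI through the growth-probability-aware recovery formula, so the
empirical/analytic comparison needs no side information.

## Problem sizes and tolerances

The standard synthetic benchmark used throughout the tests is 400 crops at
c_v = 0.5 with CNN-4/32 trained 30 epochs (≈15 s on one CPU core); the
simulator agreement checks use 10⁴-droplet runs; stochastic assertions use
3-standard-error bands with binomial or delta-method SEs (covariances
ignored where that is conservative). The separability knob, cross-validation
and pipeline tests run on reduced frames (100×100) and smaller sets to keep
the full suite desk-scale. Exact reproducibility assertions (bit-identical
reruns, save/load round trips) use fixed seeds.

## Known limitations

* Synthetic separability: headline classification metrics on this benchmark
  say nothing about accuracy on real nozzle imagery.
* The detection thresholds are placeholders; on real data they must be tuned
  to the instrument's magnification and illumination.
* Single-label, binary output; multi-class sorting would need an output-layer
  change and different metrics.
* The throughput model ignores plate-exchange robotics, queueing and
  evaporation; t_deposit lumps all per-accept dead time into one constant.
* Wells are assumed to receive their cell with certainty; failed depositions
  are not modeled.
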