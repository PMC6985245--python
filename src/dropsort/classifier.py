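"""Shallow-CNN viability classifier: model, training, cross-validation, I/O.

The estimator follows the model/results idiom: :class:`ViabilityCNN` is built
from a labeled crop dataset, ``fit()`` trains the network and returns a
:class:`ViabilityCNNResults` carrying the trained weights, the per-epoch
loss history, provenance, and prediction/serialization methods.

Two canonical architectures are provided — CNN-4/32 (4 filters per conv
layer, 32 hidden nodes) and CNN-32/128 — both: two 3x3 convolutions each
followed by 2x2 max-pooling, one fully connected ReLU layer, one sigmoid
output on 55x55x1 background-subtracted crops.  Training uses class-weighted
binary cross-entropy (weights N/(2*N_class), mean 1 over the sample), Adam,
mini-batches, and random augmentation drawn from flips, 90-degree rotations,
small shifts and brightness jitter — cells have no canonical orientation in
the nozzle, so these are label-preserving.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cnn import ShallowCNN, sigmoid, weighted_bce
from .metrics import classify, confusion, dead_pass_rate, accuracy, roc_auc, tpr

__all__ = [
    "CnnSpec",
    "AugmentParams",
    "TrainConfig",
    "build_cnn",
    "normalize_crops",
    "augment",
    "ViabilityCNN",
    "ViabilityCNNResults",
    "cross_validate",
    "load_model",
    "ModelLoadError",
]

CROP = 55
#: normalization applied to signed background-subtracted crops before the net:
#: clip to +-full_scale, then map linearly to [0, 1] (background sits at 0.5)
NORMALIZATION = "clip(diff, -255, 255) -> [0, 1], background at 0.5"


@dataclass(frozen=True)
class CnnSpec:
    """Architecture description: conv(F)x2 with pooling, FC(D), sigmoid out."""

    conv_filters: int
    fc_nodes: int
    input_shape: tuple = (CROP, CROP, 1)
    n_conv_layers: int = 2

    def __post_init__(self):
        if self.conv_filters < 1 or self.fc_nodes < 1:
            raise ValueError("conv_filters and fc_nodes must be >= 1")

    @property
    def name(self) -> str:
        return f"CNN-{self.conv_filters}/{self.fc_nodes}"

    def layers(self) -> list[str]:
        f, d = self.conv_filters, self.fc_nodes
        return [
            f"conv 3x3 x{f} (same, ReLU)",
            "maxpool 2x2",
            f"conv 3x3 x{f} (same, ReLU)",
            "maxpool 2x2",
            "flatten",
            f"dense {d} (ReLU)",
            "dense 1 (sigmoid)",
        ]


def build_cnn(conv_filters: int, fc_nodes: int) -> CnnSpec:
    """Construct an architecture spec; (4, 32) and (32, 128) are canonical."""
    return CnnSpec(conv_filters=conv_filters, fc_nodes=fc_nodes)


@dataclass(frozen=True)
class AugmentParams:
    hflip: bool = True
    vflip: bool = True
    rotate90: bool = True
    max_shift_px: int = 3
    brightness_jitter: float = 0.1

    def __post_init__(self):
        if self.max_shift_px < 0 or self.max_shift_px > 5:
            raise ValueError("max_shift_px must be in [0, 5] to keep cells in-crop")

    @property
    def enabled(self) -> bool:
        return (
            self.hflip
            or self.vflip
            or self.rotate90
            or self.max_shift_px > 0
            or self.brightness_jitter > 0
        )


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    augmentation: AugmentParams = field(default_factory=AugmentParams)
    class_weights: dict | None = None  # {"viable": w, "dead": w}; None = inverse freq
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.class_weights is not None and min(self.class_weights.values()) <= 0:
            raise ValueError("class weights must be positive")


def normalize_crops(crops: np.ndarray, full_scale: float = 255.0) -> np.ndarray:
    """Map signed difference crops to [0, 1] with symmetric clipping.

    Zero difference (pure background) maps to 0.5; this exact scheme is
    recorded in model provenance so deployment matches training.
    """
    crops = np.asarray(crops, dtype=float)
    return (np.clip(crops, -full_scale, full_scale) + full_scale) / (2.0 * full_scale)


def augment(crop: np.ndarray, params: AugmentParams, rng: np.random.Generator) -> np.ndarray:
    """One random label-preserving transform draw applied to a 55x55 crop."""
    if crop.shape != (CROP, CROP):
        raise ValueError(f"augment expects a {CROP}x{CROP} crop, got {crop.shape}")
    out = crop
    if params.hflip and rng.random() < 0.5:
        out = out[:, ::-1]
    if params.vflip and rng.random() < 0.5:
        out = out[::-1, :]
    if params.rotate90:
        out = np.rot90(out, k=int(rng.integers(0, 4)))
    if params.max_shift_px > 0:
        dy, dx = rng.integers(-params.max_shift_px, params.max_shift_px + 1, size=2)
        if dy or dx:
            fill = float(np.median(out))
            shifted = np.full_like(out, fill)
            ys = slice(max(0, dy), CROP + min(0, dy))
            xs = slice(max(0, dx), CROP + min(0, dx))
            yt = slice(max(0, -dy), CROP + min(0, -dy))
            xt = slice(max(0, -dx), CROP + min(0, -dx))
            shifted[ys, xs] = out[yt, xt]
            out = shifted
    if params.brightness_jitter > 0:
        # jitter intensity deviations about the neutral background level
        j = 1.0 + rng.uniform(-params.brightness_jitter, params.brightness_jitter)
        ref = 0.5 if 0.0 <= out.min() and out.max() <= 1.0 else 0.0
        out = ref + (out - ref) * j
    return np.ascontiguousarray(out)


def _labels_to_y(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "bif":
        return arr.astype(float)
    return (arr == "viable").astype(float)


def _fingerprint(crops: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.round(crops, 4).tobytes())
    h.update(y.tobytes())
    return h.hexdigest()[:16]


class ViabilityCNN:
    """Shallow-CNN viability model over a labeled crop dataset.

    Parameters
    ----------
    crops : (n, 55, 55) array of signed background-subtracted difference crops
        (raw gray-value scale; normalization to [0, 1] is applied internally).
    labels : length-n sequence of "viable"/"dead" (or boolean, truthy=viable).
    spec : architecture, default CNN-4/32.
    split : optional length-n sequence of "train"/"val"; when omitted, fit()
        holds out a random stratified ``val_fraction``.
    """

    def __init__(self, crops, labels, spec: CnnSpec | None = None, split=None):
        crops = np.asarray(crops, dtype=float)
        if crops.ndim != 3 or crops.shape[1:] != (CROP, CROP):
            raise ValueError(f"crops must be (n, {CROP}, {CROP}), got {crops.shape}")
        y = _labels_to_y(labels)
        if len(y) != len(crops):
            raise ValueError("crops and labels must have equal length")
        if y.min() == y.max():
            raise ValueError(
                "training requires both classes present (class weights undefined)"
            )
        self.crops = crops
        self.y = y
        self.spec = spec or build_cnn(4, 32)
        self.split = None if split is None else np.asarray(split)

    @classmethod
    def from_manifest(cls, manifest: pd.DataFrame, image_dir, spec=None):
        """Build from a dataset manifest whose image_path column names PNG crops
        written by the synthetic-imaging generator (difference mapped to [0, 255])."""
        import os

        from PIL import Image

        crops = []
        for p in manifest["image_path"]:
            u8 = np.asarray(Image.open(os.path.join(image_dir, p)), dtype=float)
            crops.append(u8 * 2.0 - 255.0)  # back to the signed-difference scale
        split = manifest["split"].to_numpy() if "split" in manifest else None
        return cls(np.stack(crops), manifest["label"].to_numpy(), spec=spec, split=split)

    # ------------------------------------------------------------------

    def _train_val_indices(self, rng, val_fraction=0.2):
        if self.split is not None:
            tr = np.flatnonzero(self.split == "train")
            va = np.flatnonzero(self.split == "val")
            if len(tr) and len(va):
                return tr, va
        idx = np.arange(len(self.y))
        va = []
        for cls_val in (0.0, 1.0):
            members = idx[self.y == cls_val]
            members = rng.permutation(members)
            k = max(1, int(round(len(members) * val_fraction)))
            va.extend(members[:k])
        va = np.sort(np.array(va))
        tr = np.setdiff1d(idx, va)
        return tr, va

    def class_weights(self, cfg: TrainConfig) -> np.ndarray:
        """Per-sample weights: N/(2*N_class) by default (mean 1 per sample)."""
        if cfg.class_weights is not None:
            wv, wd = cfg.class_weights["viable"], cfg.class_weights["dead"]
        else:
            n = len(self.y)
            nv = float(self.y.sum())
            wv, wd = n / (2.0 * nv), n / (2.0 * (n - nv))
        return np.where(self.y == 1.0, wv, wd)

    def fit(self, cfg: TrainConfig | None = None) -> "ViabilityCNNResults":
        """Train with mini-batch Adam; one epoch is ceil(N_train/batch) iterations."""
        cfg = cfg or TrainConfig()
        rng = np.random.default_rng(cfg.seed)
        net = ShallowCNN(self.spec.conv_filters, self.spec.fc_nodes,
                         seed=int(rng.integers(2**31)))
        tr, va = self._train_val_indices(rng)
        w_all = self.class_weights(cfg)
        x_norm = normalize_crops(self.crops)
        xva = x_norm[va][..., None]
        yva, wva = self.y[va], w_all[va]

        history = {"epoch": [], "train_loss": [], "val_loss": []}
        aug = cfg.augmentation
        for epoch in range(cfg.epochs):
            order = rng.permutation(tr)
            losses = []
            for start in range(0, len(order), cfg.batch_size):
                batch = order[start : start + cfg.batch_size]
                xb = x_norm[batch]
                if aug.enabled:
                    xb = np.stack([augment(c, aug, rng) for c in xb])
                xb = xb[..., None]
                yb, wb = self.y[batch], w_all[batch]
                logits, cache = net.forward(xb, want_cache=True)
                losses.append(weighted_bce(logits, yb, wb))
                grads = net.backward(cache, logits, yb, wb)
                net.adam_step(grads, lr=cfg.learning_rate)
            val_logits = net.forward(xva)
            history["epoch"].append(epoch + 1)
            history["train_loss"].append(float(np.mean(losses)))
            history["val_loss"].append(weighted_bce(val_logits, yva, wva))

        provenance = {
            "spec": dataclasses.asdict(self.spec),
            "train_config": {
                "epochs": cfg.epochs,
                "batch_size": cfg.batch_size,
                "learning_rate": cfg.learning_rate,
                "augmentation": dataclasses.asdict(cfg.augmentation),
                "class_weights": cfg.class_weights,
                "seed": cfg.seed,
            },
            "normalization": NORMALIZATION,
            "dataset_fingerprint": _fingerprint(self.crops, self.y),
            "n_train": int(len(tr)),
            "n_val": int(len(va)),
        }
        return ViabilityCNNResults(
            spec=self.spec,
            net=net,
            history=pd.DataFrame(history),
            provenance=provenance,
            val_indices=va,
        )


class ViabilityCNNResults:
    """A trained viability classifier plus its training record.

    ``predict`` maps raw signed-difference crops (n, 55, 55) to growth
    probabilities in [0, 1]; ``classify_crops`` applies the strict P > T rule.
    """

    def __init__(self, spec, net, history, provenance, val_indices=None):
        self.spec = spec
        self.net = net
        self.history = history
        self.provenance = provenance
        self.val_indices = val_indices

    def predict(self, crops: np.ndarray) -> np.ndarray:
        crops = np.asarray(crops, dtype=float)
        single = crops.ndim == 2
        if single:
            crops = crops[None]
        if crops.shape[1:] != (CROP, CROP):
            raise ValueError(
                f"crops must be {CROP}x{CROP} (no implicit resize), got {crops.shape[1:]}"
            )
        p = sigmoid(self.net.forward(normalize_crops(crops)[..., None])).ravel()
        return p[0] if single else p

    def classify_crops(self, crops: np.ndarray, T: float = 0.5):
        return classify(self.predict(crops), T)

    def evaluate(self, crops, labels, T: float = 0.5) -> dict:
        """ACC/AUC/TPR/dead-pass of this model on a labeled crop set."""
        scores = self.predict(crops)
        cc = confusion(labels, classify(scores, T))
        _, auc = roc_auc(labels, scores)
        return {
            "ACC": accuracy(cc),
            "AUC": auc,
            "TPR": tpr(cc),
            "dead_pass_rate": dead_pass_rate(cc),
            "threshold": T,
        }

    def summary(self) -> str:
        h = self.history
        lines = [
            f"{self.spec.name}: shallow CNN viability classifier",
            "=" * 52,
            "architecture: " + " -> ".join(self.spec.layers()),
            f"normalization: {self.provenance['normalization']}",
            f"train/val:     {self.provenance['n_train']}/{self.provenance['n_val']} crops"
            f" (fingerprint {self.provenance['dataset_fingerprint']})",
            f"epochs:        {len(h)}  batch {self.provenance['train_config']['batch_size']}"
            f"  lr {self.provenance['train_config']['learning_rate']}",
            f"final loss:    train {h['train_loss'].iloc[-1]:.4f}"
            f"  val {h['val_loss'].iloc[-1]:.4f}"
            f"  (min val {h['val_loss'].min():.4f} @ epoch {int(h.loc[h['val_loss'].idxmin(), 'epoch'])})",
        ]
        return "\n".join(lines)

    def plot_history(self, ax=None):
        """Training and validation loss per epoch (the overfitting diagnostic)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.history["epoch"], self.history["train_loss"], label="train")
        ax.plot(self.history["epoch"], self.history["val_loss"], "--", label="validation")
        ax.set_xlabel("epoch")
        ax.set_ylabel("class-weighted BCE")
        ax.set_title(self.spec.name)
        ax.legend()
        return ax

    def save(self, path) -> None:
        """Self-describing single-file container: weights + spec + provenance."""
        meta = {
            "format": "dropsort-viability-cnn-v1",
            "provenance": self.provenance,
            "history": self.history.to_dict(orient="list"),
        }
        with open(path, "wb") as fh:
            np.savez(
                fh,
                meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                **self.net.state_dict(),
            )


class ModelLoadError(RuntimeError):
    pass


def load_model(path) -> ViabilityCNNResults:
    """Load a saved classifier; predictions round-trip bit-identically."""
    try:
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"].tobytes()).decode())
            if meta.get("format") != "dropsort-viability-cnn-v1":
                raise ModelLoadError(f"unrecognized model format in {path}")
            spec_d = meta["provenance"]["spec"]
            spec = CnnSpec(
                conv_filters=spec_d["conv_filters"], fc_nodes=spec_d["fc_nodes"]
            )
            net = ShallowCNN(spec.conv_filters, spec.fc_nodes, seed=0)
            net.load_state_dict({k: data[k] for k in net.params})
            history = pd.DataFrame(meta["history"])
    except ModelLoadError:
        raise
    except Exception as exc:  # truncated/corrupt container
        raise ModelLoadError(f"cannot load model from {path}: {exc}") from exc
    return ViabilityCNNResults(
        spec=spec, net=net, history=history, provenance=meta["provenance"]
    )


def cross_validate(
    spec: CnnSpec, crops, labels, k: int = 10, cfg: TrainConfig | None = None
) -> pd.DataFrame:
    """Stratified k-fold cross-validation; each record validated exactly once.

    Returns one row per fold plus a ``mean`` row with the arithmetic fold
    means of ACC/AUC/TPR/dead-pass (at T = 0.5).
    """
    cfg = cfg or TrainConfig()
    crops = np.asarray(crops, dtype=float)
    y = _labels_to_y(labels)
    n = len(y)
    if k > n:
        raise ValueError(f"k={k} exceeds dataset size {n}")
    rng = np.random.default_rng(cfg.seed)

    fold_of = np.empty(n, dtype=int)
    for cls_val in (0.0, 1.0):  # stratified: spread each class over folds
        members = rng.permutation(np.flatnonzero(y == cls_val))
        fold_of[members] = np.arange(len(members)) % k

    rows = []
    for fold in range(k):
        va = np.flatnonzero(fold_of == fold)
        tr = np.flatnonzero(fold_of != fold)
        split = np.where(fold_of == fold, "val", "train")
        model = ViabilityCNN(crops, y, spec=spec, split=split)
        fold_cfg = dataclasses.replace(cfg, seed=int(rng.integers(2**31)))
        res = model.fit(fold_cfg)
        m = res.evaluate(crops[va], y[va])
        rows.append({"fold": fold, "n_val": len(va), **{k2: m[k2] for k2 in
                     ("ACC", "AUC", "TPR", "dead_pass_rate")}})
    df = pd.DataFrame(rows)
    mean = df[["ACC", "AUC", "TPR", "dead_pass_rate"]].mean()
    df.loc[len(df)] = {"fold": "mean", "n_val": df["n_val"].sum(), **mean.to_dict()}
    return df
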