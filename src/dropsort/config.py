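"""Structured configuration and the end-to-end pipeline with run manifests.

One YAML file carries a section per stage (imaging, detection, classifier,
sorter); every field mirrors the corresponding dataclass and omitted keys take
the dataclass default.  ``run_pipeline`` chains generate -> train -> evaluate
-> sweep -> simulate, writing each stage's artifacts plus a run manifest with
checksums so deterministic stages can be verified on re-run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import time

import numpy as np
import yaml

from .classifier import AugmentParams, TrainConfig, ViabilityCNN, build_cnn
from .detection import DetectionParams
from .imaging import ImagingParams, generate_dataset
from .metrics import roc_auc
from .simulator import fig6_experiment, grow_colonies, simulate_run
from .throughput import SorterConfig, ThroughputModel

__all__ = ["default_config", "default_config_yaml", "load_config", "run_pipeline"]

_SECTIONS = {
    "imaging": ImagingParams,
    "detection": DetectionParams,
    "sorter": SorterConfig,
}


def default_config() -> dict:
    cfg = {name: dataclasses.asdict(cls()) for name, cls in _SECTIONS.items()}
    cfg["classifier"] = {
        "arch": "4/32",
        **{
            k: v
            for k, v in dataclasses.asdict(TrainConfig()).items()
            if k != "augmentation"
        },
        "augmentation": dataclasses.asdict(AugmentParams()),
    }
    cfg["dataset"] = {"n": 1000, "c_v": 0.5, "seed": 0}
    return cfg


def default_config_yaml() -> str:
    return yaml.safe_dump(default_config(), sort_keys=False)


def _build(cls, section: dict):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - fields
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = dict(section)
    if cls is ImagingParams and "frame_size" in kwargs:
        kwargs["frame_size"] = tuple(kwargs["frame_size"])
    return cls(**kwargs)


def load_config(path) -> dict:
    """Parse and validate a config file into typed parameter objects."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    merged = default_config()
    for section, value in raw.items():
        if section not in merged:
            raise ValueError(f"unknown config section {section!r}")
        merged[section].update(value or {})

    ds = merged["dataset"]
    if not 0.0 <= float(ds["c_v"]) <= 1.0:
        raise ValueError(f"dataset.c_v must be in [0, 1], got {ds['c_v']}")
    cls_cfg = merged["classifier"]
    arch = str(cls_cfg["arch"])
    conv, fc = (int(x) for x in arch.split("/"))
    out = {name: _build(cls, merged[name]) for name, cls in _SECTIONS.items()}
    out["spec"] = build_cnn(conv, fc)
    out["train"] = TrainConfig(
        epochs=int(cls_cfg["epochs"]),
        batch_size=int(cls_cfg["batch_size"]),
        learning_rate=float(cls_cfg["learning_rate"]),
        augmentation=_build(AugmentParams, cls_cfg["augmentation"]),
        class_weights=cls_cfg.get("class_weights"),
        seed=int(cls_cfg["seed"]),
    )
    out["dataset"] = {"n": int(ds["n"]), "c_v": float(ds["c_v"]), "seed": int(ds["seed"])}
    out["raw"] = merged
    return out


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config_path, out_dir, seed: int | None = None) -> dict:
    """Execute generate -> train -> evaluate -> sweep -> simulate.

    Returns the run manifest (also written to ``out_dir/manifest.json``)
    listing every produced artifact with its checksum.
    """
    cfg = load_config(config_path)
    os.makedirs(out_dir, exist_ok=True)
    ds = cfg["dataset"]
    seed = ds["seed"] if seed is None else seed
    artifacts = {}

    def record(name, path):
        artifacts[name] = {"path": os.path.relpath(path, out_dir), "sha256": _sha256(path)}

    # 1. generate
    data_dir = os.path.join(out_dir, "dataset")
    manifest, crops = generate_dataset(
        ds["n"], ds["c_v"], params=cfg["imaging"], seed=seed, out_dir=data_dir
    )
    record("dataset_manifest", os.path.join(data_dir, "manifest.csv"))

    # 2. train
    model = ViabilityCNN(
        crops, manifest["label"].to_numpy(), spec=cfg["spec"],
        split=manifest["split"].to_numpy(),
    )
    res = model.fit(cfg["train"])
    model_path = os.path.join(out_dir, "model.npz")
    res.save(model_path)
    record("model", model_path)
    hist_path = os.path.join(out_dir, "training_history.csv")
    res.history.to_csv(hist_path, index=False)
    record("training_history", hist_path)

    # 3. evaluate on the validation split
    va = res.val_indices
    labels_va = manifest["label"].to_numpy()[va]
    scores_va = res.predict(crops[va])
    metrics = res.evaluate(crops[va], labels_va, T=cfg["sorter"].T)
    curve, auc = roc_auc(labels_va, scores_va)
    eval_path = os.path.join(out_dir, "evaluation.json")
    with open(eval_path, "w") as fh:
        json.dump(metrics, fh, indent=2)
    record("evaluation", eval_path)

    # 4. threshold sweep
    sorter = cfg["sorter"].replace(c_v=ds["c_v"])
    sweep = ThroughputModel(sorter).sweep(curve)
    sweep_path = os.path.join(out_dir, "threshold_sweep.csv")
    sweep.to_csv(sweep_path, index=False)
    record("threshold_sweep", sweep_path)

    # 5. simulate a sorting run with the trained classifier, dispensing at the
    # frequency-optimal threshold found by the sweep (the operator's choice)
    sim_cfg = sorter.replace(T=sweep.attrs["best_frequency_threshold"])
    run = simulate_run(
        sim_cfg, model=res, imaging=cfg["imaging"], n_wells=48, seed=seed + 1
    )
    grow_colonies(run, np.random.default_rng(seed + 2))
    run_path = os.path.join(out_dir, "simulation_wells.csv")
    run.to_frame().to_csv(run_path, index=False)
    record("simulation_wells", run_path)
    summary_path = os.path.join(out_dir, "simulation_summary.json")
    with open(summary_path, "w") as fh:
        json.dump(run.summary(), fh, indent=2)
    record("simulation_summary", summary_path)

    run_manifest = {
        "command": "pipeline",
        "config": cfg["raw"],
        "master_seed": seed,
        "artifacts": artifacts,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(run_manifest, fh, indent=2)
    return run_manifest
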