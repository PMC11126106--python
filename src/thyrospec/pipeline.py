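"""End-to-end orchestration: simulate -> preprocess -> blocks -> train -> report.

The canonical stage order is correct -> smooth -> normalize -> trim; it is
exposed as a configurable list because the literature rarely pins it.  The
spectral PCA is always fitted on training-case pixels only and then frozen
for validation and test data (patient-level leakage control).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from thyrospec.blockset import Block, BlockDataset, SplitPlan, crop_blocks, split_by_case
from thyrospec.errors import ConfigError
from thyrospec.hsi_io import CaseRecord
from thyrospec.preprocess import (
    PCAProjection,
    minmax_normalize,
    pca_apply,
    pca_fit,
    savgol_smooth,
    trim_bands,
    whiteboard_correct,
)
from thyrospec.synthgen import SynthParams, synth_cohort, write_cohort
from thyrospec.train_eval import TrainConfig, evaluate, evaluate_accuracy, train
from thyrospec.v3dnet import V3DnetConfig, build_v3dnet


@dataclass
class PreprocessConfig:
    """Radiometric/spectral stage parameters and their order."""

    board_reflectance: float = 0.5
    smooth_window: int = 21
    smooth_polyorder: int = 5
    normalize_scope: str = "per_block"
    n_edge: int = 49
    stage_order: tuple[str, ...] = ("correct", "smooth", "normalize", "trim")

    def validate(self) -> None:
        if set(self.stage_order) - {"correct", "smooth", "normalize", "trim"}:
            raise ConfigError(f"unknown stages in {self.stage_order}")


def preprocess_case(case: CaseRecord, cfg: PreprocessConfig | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Run the radiometric/spectral stages on one case.

    Returns the processed ``(rows, cols, bands)`` array and the label mask.
    """
    cfg = PreprocessConfig() if cfg is None else cfg
    cfg.validate()
    cube = case.cube
    for stage in cfg.stage_order:
        if stage == "correct":
            cube = whiteboard_correct(cube, case.white_ref, case.dark_ref,
                                      rw=cfg.board_reflectance)
        elif stage == "smooth":
            data = savgol_smooth(cube.data, cfg.smooth_window,
                                 cfg.smooth_polyorder, axis=-1)
            cube = type(cube)(data, cube.wavelengths, cube.bit_depth,
                              "reflectance")
        elif stage == "normalize":
            data = minmax_normalize(cube.data, cfg.normalize_scope)
            cube = type(cube)(data, cube.wavelengths, cube.bit_depth,
                              "reflectance")
        elif stage == "trim":
            cube = trim_bands(cube, cfg.n_edge)
    return cube.data, case.mask.labels


@dataclass
class DatasetBundle:
    """Per-partition block datasets plus the frozen spectral projection."""

    train: BlockDataset
    val: BlockDataset
    test: BlockDataset
    projection: PCAProjection | None
    plan: SplitPlan


def _blocks_for(cases: list[CaseRecord], ids, pre_cfg: PreprocessConfig,
                size: int, stride: int, purity: float) -> list[Block]:
    out: list[Block] = []
    by_id = {c.case_id: c for c in cases}
    for cid in ids:
        case = by_id[cid]
        data, mask = preprocess_case(case, pre_cfg)
        for b in crop_blocks(data, mask, size, stride, purity):
            out.append(Block(b.data, b.label, cid, b.origin))
    return out


def _project_blocks(blocks: list[Block], proj: PCAProjection) -> list[Block]:
    return [Block(pca_apply(proj, b.data).astype(np.float32), b.label,
                  b.case_id, b.origin) for b in blocks]


def build_datasets(cases: list[CaseRecord], plan: SplitPlan,
                   pre_cfg: PreprocessConfig | None = None,
                   size: int = 50, stride: int | None = None,
                   purity: float = 1.0, pca_k: int = 3,
                   max_pca_pixels: int = 50_000, seed: int = 0,
                   train_stride: int | None = None) -> DatasetBundle:
    """Cut case cubes into blocks per split and PCA-reduce their spectra.

    The k-component spectral PCA is fitted on (a pixel subsample of) the
    training blocks only, then applied to every partition.  ``train_stride``
    may be smaller than ``stride`` to cut overlapping training crops
    (augmentation-rich regime); validation and test tiles always use
    ``stride``.
    """
    pre_cfg = PreprocessConfig() if pre_cfg is None else pre_cfg
    stride = size if stride is None else stride
    train_stride = stride if train_stride is None else train_stride
    parts = {name: _blocks_for(cases, ids, pre_cfg, size, st, purity)
             for name, ids, st in (("train", plan.train_ids, train_stride),
                                   ("val", plan.val_ids, stride),
                                   ("test", plan.test_ids, stride))}
    proj = None
    if pca_k is not None and parts["train"]:
        pixels = np.concatenate(
            [b.data.reshape(-1, b.data.shape[-1]) for b in parts["train"]])
        if len(pixels) > max_pca_pixels:
            rng = np.random.default_rng(seed)
            pixels = pixels[rng.choice(len(pixels), max_pca_pixels,
                                       replace=False)]
        proj = pca_fit(pixels, pca_k)
        parts = {name: _project_blocks(blocks, proj)
                 for name, blocks in parts.items()}
    return DatasetBundle(
        train=BlockDataset.from_blocks(parts["train"], partition="train"),
        val=BlockDataset.from_blocks(parts["val"], partition="val"),
        test=BlockDataset.from_blocks(parts["test"], partition="test"),
        projection=proj, plan=plan)


# ---------------------------------------------------------------------------
# Synthetic end-to-end experiment
# ---------------------------------------------------------------------------

def run_synthetic_experiment(separation: float = 0.3, noise_sd: float = 0.02,
                             n_benign: int = 8, n_malignant: int = 8,
                             block_size: int = 20, epochs: int = 30,
                             seed: int = 0,
                             synth_overrides: dict | None = None,
                             train_cfg: TrainConfig | None = None,
                             model_cfg: V3DnetConfig | None = None) -> dict:
    """Generate a desk-scale cohort, train a scaled V3Dnet, report accuracy.

    This is the recovery experiment: with spectrally separated classes the
    held-out-case block accuracy should be high; at separation 0 the labels
    are unlearnable and accuracy should sit at chance.
    """
    overrides = dict(separation=separation, noise_sd=noise_sd)
    overrides.update(synth_overrides or {})
    params = SynthParams.desk(**overrides)
    cases = synth_cohort(n_benign, n_malignant, params, seed=seed)
    plan = split_by_case(cases, seed=seed)
    pre_cfg = PreprocessConfig(board_reflectance=params.board_reflectance,
                               n_edge=10)
    bundle = build_datasets(cases, plan, pre_cfg, size=block_size,
                            stride=block_size, purity=1.0, pca_k=3, seed=seed,
                            train_stride=block_size // 2)
    if model_cfg is None:
        model_cfg = V3DnetConfig.desk()
        model_cfg.input_size = (block_size, block_size, 3)
    model = build_v3dnet(model_cfg, seed=seed)
    if train_cfg is None:
        train_cfg = TrainConfig(learning_rate=0.05, momentum=0.9,
                                lr_decay=0.90, clip_norm=25.0,
                                batch_size=32, epochs=epochs, seed=seed)
    history = train(model, bundle.train, bundle.val, train_cfg)
    # model selection: evaluate the best-validation-accuracy checkpoint
    model.net.load_state_dict(model.best_state)
    counts, report = evaluate(model, bundle.test)
    return {
        "test_accuracy": evaluate_accuracy(model, bundle.test),
        "confusion": {"tp": counts.tp, "fn": counts.fn,
                      "fp": counts.fp, "tn": counts.tn},
        "metrics": report.as_dict(),
        "history": history,
        "n_blocks": {"train": len(bundle.train), "val": len(bundle.val),
                     "test": len(bundle.test)},
        "plan": {"train": bundle.plan.train_ids, "val": bundle.plan.val_ids,
                 "test": bundle.plan.test_ids},
        "model": model,
        "bundle": bundle,
    }


# ---------------------------------------------------------------------------
# Config-driven pipeline
# ---------------------------------------------------------------------------

_DEFAULT_CONFIG = {
    "version": "1",
    "seed": 0,
    "synth": {"preset": "desk", "n_benign": 8, "n_malignant": 8,
              "separation": 0.3, "noise_sd": 0.02},
    "preprocess": {"board_reflectance": 0.5, "smooth_window": 21,
                   "smooth_polyorder": 5, "normalize_scope": "per_block",
                   "n_edge": 10},
    "blocks": {"size": 20, "stride": 20, "purity": 1.0, "pca_k": 3},
    "model": {"scale": "desk"},
    "train": {"learning_rate": 0.05, "momentum": 0.9, "lr_decay": 0.90,
              "clip_norm": 25.0, "batch_size": 32, "epochs": 30,
              "class_weighting": True},
}


def _merge_config(user: dict) -> dict:
    cfg = json.loads(json.dumps(_DEFAULT_CONFIG))
    for section, value in user.items():
        if section not in cfg:
            raise ConfigError(f"unknown config section {section!r}")
        if isinstance(value, dict):
            for key, v in value.items():
                if key not in cfg[section]:
                    raise ConfigError(f"unknown key {section}.{key}")
                cfg[section][key] = v
        else:
            cfg[section] = value
    return cfg


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Execute simulate -> preprocess -> blocks -> train -> evaluate.

    ``config`` is a dict or a YAML path; unknown keys are rejected.  Writes a
    manifest (config hash + seeds), metrics JSON and the model checkpoint to
    ``out_dir`` and returns the metrics dict.  Deterministic given identical
    config.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    cfg = _merge_config(config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    synth = cfg["synth"]
    preset = SynthParams.desk if synth["preset"] == "desk" else SynthParams
    params = preset(separation=synth["separation"], noise_sd=synth["noise_sd"])
    cases = synth_cohort(synth["n_benign"], synth["n_malignant"], params,
                         seed=seed)
    write_cohort(cases, out / "cases", params)

    plan = split_by_case(cases, seed=seed)
    pre_cfg = PreprocessConfig(**cfg["preprocess"])
    blocks_cfg = cfg["blocks"]
    bundle = build_datasets(cases, plan, pre_cfg, size=blocks_cfg["size"],
                            stride=blocks_cfg["stride"],
                            purity=blocks_cfg["purity"],
                            pca_k=blocks_cfg["pca_k"], seed=seed)
    bundle.train.save(out / "train_blocks.h5")
    bundle.test.save(out / "test_blocks.h5")

    model_cfg = V3DnetConfig.desk() if cfg["model"]["scale"] == "desk" \
        else V3DnetConfig()
    model_cfg.input_size = (blocks_cfg["size"], blocks_cfg["size"],
                            blocks_cfg["pca_k"])
    model = build_v3dnet(model_cfg, seed=seed)
    tr = cfg["train"]
    train_cfg = TrainConfig(learning_rate=tr["learning_rate"],
                            momentum=tr["momentum"],
                            lr_decay=tr.get("lr_decay", 1.0),
                            clip_norm=tr.get("clip_norm"),
                            batch_size=tr["batch_size"], epochs=tr["epochs"],
                            class_weighting=tr["class_weighting"], seed=seed)
    history = train(model, bundle.train, bundle.val, train_cfg)
    counts, report = evaluate(model, bundle.test)
    model.save(out / "model.npz")

    result = {"metrics": report.as_dict(),
              "confusion": {"tp": counts.tp, "fn": counts.fn,
                            "fp": counts.fp, "tn": counts.tn},
              "test_accuracy": evaluate_accuracy(model, bundle.test),
              "n_blocks": {"train": len(bundle.train),
                           "val": len(bundle.val),
                           "test": len(bundle.test)}}
    (out / "metrics.json").write_text(json.dumps(result, indent=2))
    manifest = {
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
        "seed": seed,
        "split": {"train": plan.train_ids, "val": plan.val_ids,
                  "test": plan.test_ids},
        "history_final": {k: (v[-1] if isinstance(v, list) else v)
                          for k, v in history.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    # training history as CSV
    hist_rows = ["epoch,train_loss,train_acc,val_acc"] + [
        f"{i},{l},{a},{v}" for i, (l, a, v) in enumerate(
            zip(history["train_loss"], history["train_acc"],
                history["val_acc"]))]
    (out / "history.csv").write_text("\n".join(hist_rows) + "\n")
    return result
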