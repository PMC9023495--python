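"""Run configuration schema, named presets, and the stage dispatcher.

A run config is a plain mapping (usually loaded from YAML) with a ``stage``
plus nested per-stage sections. Validation errors name the offending field
path. Every numeric choice of the default recipe (batch 32, momentum 0.9,
weight decay 0.0005, lambda 1.0, alpha 0.5 and the learning-rate ladders)
lives in the ``paper-herb`` preset and can be overridden; ``desk`` shrinks
the iteration counts for laptop-scale runs with the same rate ladders.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Optional

import numpy as np
import yaml

from . import evaluation, prune, synthetic
from .distill import TransferConfig, transfer_train
from .imaging import AugmentationConfig
from .network import (build_network, desk_student, desk_teacher, load_checkpoint,
                      save_checkpoint)
from .synthetic import SynthConfig, generate_dataset, load_dataset, write_dataset
from .training import TrainConfig, pretrain_then_finetune, train_crossentropy

__all__ = ["ConfigError", "RunConfig", "load_run_config", "run", "PRESETS"]

STAGES = ("synth", "train", "transfer", "cut", "compress", "evaluate", "sweep")

PRESETS: Dict[str, Dict[str, Any]] = {
    # Full-scale recipe: iteration counts as printed for the herb task
    # (small-DNN fine-tune ladder; the large DNN uses 5000 per rate).
    "paper-herb": {
        "train": {"lr_schedule": [[0.01, 10000], [0.001, 10000], [0.0001, 10000]],
                  "batch_size": 32, "momentum": 0.9, "weight_decay": 0.0005},
        "train_large": {"lr_schedule": [[0.01, 5000], [0.001, 5000], [0.0001, 5000]],
                        "batch_size": 32, "momentum": 0.9, "weight_decay": 0.0005},
        "transfer": {"lambda_": 1.0,
                     "train": {"lr_schedule": [[0.001, 10000], [0.0001, 5000]]}},
        "cut": {"alpha": 0.5, "subset_size": 256,
                "retrain": {"lambda_": 1.0,
                            "train": {"lr_schedule": [[0.001, 5000], [0.0001, 2000]]}}},
    },
    # Source-task pre-training ladder: 0.1 -> 0.0001, /10 every 30 epochs.
    "paper-imagenet": {
        "train": {"lr_schedule": [[0.1, 1125000], [0.01, 1125000],
                                  [0.001, 1125000], [0.0001, 1125000]],
                  "batch_size": 32, "momentum": 0.9, "weight_decay": 0.0005},
    },
    # Same ladders at one tenth (or less) of the iteration budget.
    "desk": {
        "train": {"lr_schedule": [[0.01, 600], [0.001, 300], [0.0001, 100]],
                  "batch_size": 32, "momentum": 0.9, "weight_decay": 0.0005},
        "transfer": {"lambda_": 1.0,
                     "train": {"lr_schedule": [[0.001, 600], [0.0001, 200]]}},
        "cut": {"alpha": 0.5, "subset_size": 64,
                "retrain": {"lambda_": 1.0,
                            "train": {"lr_schedule": [[0.001, 250], [0.0001, 100]]}}},
    },
}


class ConfigError(ValueError):
    """Schema violation; the message names the field path."""


def _check_keys(d: dict, allowed, path: str):
    for k in d:
        if k not in allowed:
            raise ConfigError(f"{path}.{k}: unknown field")


def _build(cls, d: Optional[dict], path: str):
    d = dict(d or {})
    names = {f.name for f in dataclasses.fields(cls)}
    _check_keys(d, names, path)
    try:
        return cls(**d)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"{path}: {e}") from e


def synth_config_from(d, path="synth") -> SynthConfig:
    return _build(SynthConfig, d, path)


def aug_config_from(d, path="aug") -> AugmentationConfig:
    d = dict(d or {})
    for k in ("scale_range", "ratio_range", "crop_frac_range", "mean", "sd"):
        if k in d:
            d[k] = tuple(d[k])
    return _build(AugmentationConfig, d, path)


def train_config_from(d, path="train") -> TrainConfig:
    d = dict(d or {})
    if "lr_schedule" in d:
        d["lr_schedule"] = tuple(tuple(x) for x in d["lr_schedule"])
    return _build(TrainConfig, d, path)


def transfer_config_from(d, path="transfer") -> TransferConfig:
    d = dict(d or {})
    if "train" in d:
        d["train"] = train_config_from(d["train"], f"{path}.train")
    return _build(TransferConfig, d, path)


def cut_config_from(d, path="cut") -> prune.CutConfig:
    d = dict(d or {})
    if "retrain" in d:
        d["retrain"] = transfer_config_from(d["retrain"], f"{path}.retrain")
    return _build(prune.CutConfig, d, path)


_ARCHES = {"desk_student": desk_student, "desk_teacher": desk_teacher}


def arch_from(d, n_classes: int, path="arch"):
    d = dict(d or {})
    name = d.pop("model", "desk_student")
    if name not in _ARCHES:
        raise ConfigError(f"{path}.model: unknown architecture {name!r}")
    d.setdefault("n_classes", n_classes)
    try:
        return _ARCHES[name](**d)
    except TypeError as e:
        raise ConfigError(f"{path}: {e}") from e


@dataclass
class RunConfig:
    stage: str
    paths: Dict[str, str] = field(default_factory=dict)
    global_seed: int = 0
    preset: Optional[str] = None
    options: Dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ConfigError(f"stage: unknown stage {self.stage!r} (expected one of {STAGES})")
        if self.preset is not None and self.preset not in PRESETS:
            raise ConfigError(f"preset: unknown preset {self.preset!r}")


def load_run_config(source) -> RunConfig:
    """Build a RunConfig from a YAML path or a mapping."""
    if isinstance(source, (str, Path)):
        source = yaml.safe_load(Path(source).read_text())
    if not isinstance(source, dict):
        raise ConfigError(": run config must be a mapping")
    d = dict(source)
    _check_keys(d, {"stage", "paths", "global_seed", "preset", "options"}, "")
    if "stage" not in d:
        raise ConfigError("stage: required field missing")
    return RunConfig(stage=d["stage"], paths=dict(d.get("paths") or {}),
                     global_seed=int(d.get("global_seed", 0)),
                     preset=d.get("preset"), options=dict(d.get("options") or {}))


def _merged_options(cfg: RunConfig) -> Dict[str, Any]:
    base: Dict[str, Any] = {}
    if cfg.preset:
        base = json.loads(json.dumps(PRESETS[cfg.preset]))

    def merge(a, b):
        for k, v in b.items():
            if isinstance(v, dict) and isinstance(a.get(k), dict):
                merge(a[k], v)
            else:
                a[k] = v
    merge(base, cfg.options)
    return base


def _require_path(cfg: RunConfig, key: str) -> Path:
    if key not in cfg.paths:
        raise ConfigError(f"paths.{key}: required field missing")
    p = Path(cfg.paths[key])
    if key != "out" and not p.exists():
        raise FileNotFoundError(f"paths.{key}: {p} does not exist")
    return p


def _echo_config(cfg: RunConfig, opts: dict, out: Path):
    out.mkdir(parents=True, exist_ok=True)
    effective = {"stage": cfg.stage, "paths": cfg.paths, "global_seed": cfg.global_seed,
                 "preset": cfg.preset, "options": opts}
    (out / "effective_config.yaml").write_text(yaml.safe_dump(effective))


def _tsv_logger(path: Path):
    f = open(path, "a")
    f.write("iteration\tlr\tloss\tcross_entropy\tpenalty\tbatch_top1\n")

    def log(row):
        f.write(f"{row.iteration}\t{row.lr}\t{row.loss:.6f}\t"
                f"{row.cross_entropy:.6f}\t{row.penalty:.6f}\t{row.batch_top1:.2f}\n")
        f.flush()
    return log, f


def run(config: RunConfig) -> dict:
    """Dispatch a stage; returns a small dict describing the artifacts."""
    opts = _merged_options(config)
    out = _require_path(config, "out")
    _echo_config(config, opts, out)
    seed = config.global_seed

    if config.stage == "synth":
        scfg = synth_config_from({**opts.get("synth", {}), }, "options.synth")
        if scfg.seed == 0 and seed:
            scfg = dataclasses.replace(scfg, seed=seed)
        ds = generate_dataset(scfg)
        write_dataset(ds, out / "dataset", scfg)
        return {"dataset": str(out / "dataset"), "n_images": len(ds)}

    aug = aug_config_from(opts.get("aug"), "options.aug")

    if config.stage == "train":
        data = load_dataset(_require_path(config, "data"))
        tcfg = train_config_from({"seed": seed, **opts.get("train", {})}, "options.train")
        spec = arch_from(opts.get("arch"), data.n_classes, "options.arch")
        model = build_network(spec, seed=seed)
        log, fh = _tsv_logger(out / "log.tsv")
        try:
            if "source" in config.paths:
                source = load_dataset(_require_path(config, "source"))
                pre_cfg = train_config_from(
                    {"seed": seed, **opts.get("pretrain", opts.get("train", {}))},
                    "options.pretrain")
                src_spec = arch_from(opts.get("arch"), source.n_classes, "options.arch")
                model = build_network(src_spec, seed=seed)
                model, _ = pretrain_then_finetune(model, source, data, pre_cfg, tcfg, aug, log=log)
            else:
                model, _ = train_crossentropy(model, data, aug, tcfg, log=log)
        finally:
            fh.close()
        save_checkpoint(model, out / "model.ckpt")
        return {"checkpoint": str(out / "model.ckpt")}

    if config.stage == "transfer":
        data = load_dataset(_require_path(config, "data"))
        student = load_checkpoint(_require_path(config, "student"))
        teacher = load_checkpoint(_require_path(config, "teacher"))
        xcfg = transfer_config_from(opts.get("transfer"), "options.transfer")
        xcfg = dataclasses.replace(
            xcfg, train=dataclasses.replace(xcfg.train, seed=seed))
        log, fh = _tsv_logger(out / "log.tsv")
        try:
            student, _ = transfer_train(student, teacher, data, aug, xcfg, log=log)
        finally:
            fh.close()
        save_checkpoint(student, out / "model.ckpt")
        return {"checkpoint": str(out / "model.ckpt")}

    if config.stage in ("cut", "compress"):
        data = load_dataset(_require_path(config, "data"))
        student = load_checkpoint(_require_path(config, "student"))
        teacher = load_checkpoint(_require_path(config, "teacher"))
        ccfg = cut_config_from(opts.get("cut"), "options.cut")
        holdout = None
        if "holdout" in config.paths:
            holdout = load_dataset(_require_path(config, "holdout"))
        log, fh = _tsv_logger(out / "log.tsv")
        try:
            model, report = _compress_with_artifacts(student, teacher, data, aug,
                                                     ccfg, holdout, out, log)
        finally:
            fh.close()
        return {"checkpoint": str(out / "ws_final.ckpt"),
                "report": str(out / "report.json")}

    if config.stage == "evaluate":
        data = load_dataset(_require_path(config, "data"))
        model = load_checkpoint(_require_path(config, "model"))
        topk = opts.get("topk", [1, 5])
        logits = evaluation.predict_logits(model, data.images, aug)
        report = {
            "topk": {int(k): evaluation.topk_macro_accuracy(logits, data.labels, k)
                     for k in topk if k <= data.n_classes},
            "confusion": evaluation.confusion_matrix(
                np.argmax(logits, axis=1), data.labels, data.n_classes).tolist(),
        }
        (out / "report.json").write_text(json.dumps(report, indent=2))
        return {"report": str(out / "report.json")}

    if config.stage == "sweep":
        data = load_dataset(_require_path(config, "data"))
        student = load_checkpoint(_require_path(config, "student"))
        teacher = load_checkpoint(_require_path(config, "teacher"))
        holdout = load_dataset(_require_path(config, "holdout"))
        base = cut_config_from(opts.get("cut"), "options.cut")
        alphas = opts.get("alphas", [round(0.1 * i, 1) for i in range(1, 10)])
        rows = []
        for a in alphas:
            ccfg = dataclasses.replace(base, alpha=float(a))
            from .network import copy_model
            model, rep = prune.compress(copy_model(student), teacher, data, aug,
                                        ccfg, holdout=holdout)
            rows.append({"alpha": float(a),
                         "top1": rep.holdout_accuracy[-1]["top1"],
                         "params_after": rep.params_after})
        (out / "sweep.json").write_text(json.dumps(rows, indent=2))
        return {"sweep": str(out / "sweep.json")}

    raise ConfigError(f"stage: unknown stage {config.stage!r}")


def _compress_with_artifacts(student, teacher, data, aug, ccfg, holdout, out: Path, log):
    def on_layer(t, mod):
        save_checkpoint(mod, out / f"ws_{t}.ckpt")

    model, report = prune.compress(student, teacher, data, aug, ccfg,
                                   holdout=holdout, log=log, on_layer=on_layer)
    for entry in report.layers:
        (out / f"scores_{entry['layer']}.json").write_text(json.dumps(entry["scores"]))
    save_checkpoint(model, out / "ws_final.ckpt")
    (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
    return model, report
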