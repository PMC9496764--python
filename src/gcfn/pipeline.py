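"""End-to-end pipeline runner: simulate -> augment -> preprocess -> tfr ->
train / baseline, driven by a single YAML configuration.

Every constant of the decoding recipe (slide step 80, 8-30 Hz band, filter
order 5, dropout 0.3, chance rate 0.25, layer sizes) lives in
:data:`DEFAULT_CONFIG` rather than in stage logic, so a run is fully
described by its configuration; the emitted ``manifest.json`` records the
configuration hash, seed and package version, from which the run is
reproducible.
"""

from __future__ import annotations

import copy
import hashlib
import json
import os
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .augment import AugmentConfig, augment_dataset, source_groups
from .baseline import csp_lda_crossval
from .dataio import TrialSet, save_trialset
from .model import GCFNConfig, FusionNet
from .preprocess import FilterSpec, bandpass, to_gru_layout, zscore
from .synth import SynthConfig, generate
from .tfr import CWTParams, batch_images, image_stack
from .trainer_eval import TrainConfig, make_folds, train_and_evaluate

__all__ = ["DEFAULT_CONFIG", "RunConfig", "PipelineError", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "gcfn_run",
    "verbosity": 1,
    "synth": {
        "n_per_class": 50,
        "fs": 250.0,
        "duration": 3.5,
        "erd_depth": 0.5,
        "noise_sigma": 10.0,
        "rhythm_amp": 5.0,
    },
    "augment": {"step": 80, "include_original": True},
    "filter": {"low_hz": 8.0, "high_hz": 30.0, "order": 5, "zero_phase": True},
    "tfr": {"freq_bins": 32, "image_height": 224, "image_width": 93},
    "model": {
        "variant": "gcfn",        # gcfn | eeg-gru | cwt-cnn
        "cnn_filters": 64,
        "gru1_units": 25,
        "gru2_units": 50,
        "fc1_units": 128,
        "dropout_p": 0.3,
    },
    "train": {
        "folds": 10,
        "mode": "paper",          # paper | group_safe
        "learning_rate": 1e-3,
        "batch_size": 64,
        "max_epochs": 100,
        "early_stop_patience": 10,
    },
    "baseline": {"enabled": False, "pairs": 2},
    "eval": {"chance_rate": 0.25},
}


class PipelineError(RuntimeError):
    """A stage failure, prefixed with the stage name."""


@dataclass
class RunConfig:
    """Validated pipeline configuration (merged over the defaults)."""

    raw: dict

    @classmethod
    def from_dict(cls, overrides: dict | None = None) -> "RunConfig":
        cfg = copy.deepcopy(DEFAULT_CONFIG)
        for key, val in (overrides or {}).items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
        return cls(raw=cfg)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def __getitem__(self, key: str):
        return self.raw[key]

    def sha256(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True).encode()
        ).hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name}: {exc}") from exc
        return wrapper
    return deco


def _build_model_cfg(cfg: RunConfig, n_samples: int, n_channels: int) -> GCFNConfig:
    m = cfg["model"]
    t = cfg["tfr"]
    return GCFNConfig(
        cnn_filters=m["cnn_filters"],
        cnn_kernel=(t["image_height"], 1),
        gru1_units=m["gru1_units"],
        gru2_units=m["gru2_units"],
        fc1_units=m["fc1_units"],
        dropout_p=m["dropout_p"],
        eeg_input=(n_samples, n_channels),
        image_input=(t["image_height"], t["image_width"], 1),
    )


def run_pipeline(cfg: RunConfig | dict, *, log_fn=None) -> dict:
    """Execute the configured stage sequence and write all artifacts.

    Returns a report dict with the metrics of every trained model.  All
    intermediate trial containers, the per-fold metrics table, confusion
    matrices, a JSON-lines run log, and a manifest are written to
    ``out_dir``.
    """
    if isinstance(cfg, dict):
        cfg = RunConfig.from_dict(cfg)
    out_dir = cfg["out_dir"]
    os.makedirs(out_dir, exist_ok=True)
    log_path = os.path.join(out_dir, "run_log.jsonl")
    log_file = open(log_path, "a")

    def log(event: str, **info) -> None:
        entry = {"t": time.strftime("%Y-%m-%dT%H:%M:%S"), "event": event, **info}
        log_file.write(json.dumps(entry) + "\n")
        log_file.flush()
        if log_fn is not None:
            log_fn(entry)

    seed = int(cfg["seed"])
    report: dict = {"models": {}}
    try:
        ts = _stage("simulate")(_simulate)(cfg, seed)
        log("simulate", trials=ts.n_trials)
        save_trialset(ts, os.path.join(out_dir, "raw.npz"))

        aug_cfg = AugmentConfig(**cfg["augment"])
        aug = _stage("augment")(augment_dataset)(ts, aug_cfg)
        groups = source_groups(ts.n_trials, aug_cfg, ts.n_samples)
        log("augment", trials=aug.n_trials, step=aug_cfg.step)
        save_trialset(aug, os.path.join(out_dir, "augmented.npz"))

        filt = _stage("preprocess")(bandpass)(aug, FilterSpec(**cfg["filter"]))
        zs = _stage("preprocess")(zscore)(filt)
        eeg = to_gru_layout(zs)
        log("preprocess", band=[cfg["filter"]["low_hz"], cfg["filter"]["high_hz"]])

        params = CWTParams(
            freqs=np.linspace(8.0, 30.0, cfg["tfr"]["freq_bins"]),
            image_shape=(cfg["tfr"]["image_height"], cfg["tfr"]["image_width"]),
            n_channels=filt.n_channels,
        )
        images = image_stack(_stage("tfr")(batch_images)(filt, params))
        log("tfr", images=len(images))

        folds = _stage("folds")(make_folds)(
            aug.n_trials, groups=groups, mode=cfg["train"]["mode"],
            seed=seed, n_folds=cfg["train"]["folds"],
        )
        train_cfg = TrainConfig(
            learning_rate=cfg["train"]["learning_rate"],
            batch_size=cfg["train"]["batch_size"],
            max_epochs=cfg["train"]["max_epochs"],
            early_stop_patience=cfg["train"]["early_stop_patience"],
            seed=seed,
        )
        model_cfg = _build_model_cfg(cfg, zs.n_samples, zs.n_channels)
        variant = cfg["model"]["variant"]
        flags = {
            "gcfn": (True, True),
            "eeg-gru": (True, False),
            "cwt-cnn": (False, True),
        }
        if variant not in flags:
            raise PipelineError(f"stage train: unknown model variant {variant!r}")
        use_gru, use_cnn = flags[variant]

        def builder(s: int) -> FusionNet:
            return FusionNet(model_cfg, use_gru=use_gru, use_cnn=use_cnn, seed=s)

        result = _stage("train")(train_and_evaluate)(
            builder, eeg if use_gru else None, images if use_cnn else None,
            aug.labels, folds, train_cfg,
        )
        report["models"][variant] = result
        log("train", model=variant, mean_accuracy=result["mean_accuracy"],
            kappa=result["kappa"])

        if cfg["baseline"]["enabled"]:
            bl = _stage("baseline")(csp_lda_crossval)(filt, folds, m=cfg["baseline"]["pairs"])
            report["models"]["csp_lda"] = bl
            log("baseline", mean_accuracy=bl["mean_accuracy"], kappa=bl["kappa"])

        _write_outputs(out_dir, cfg, seed, report)
        log("done")
    finally:
        log_file.close()
    return report


def _simulate(cfg: RunConfig, seed: int) -> TrialSet:
    return generate(SynthConfig(seed=seed, **cfg["synth"]))


def _write_outputs(out_dir: str, cfg: RunConfig, seed: int, report: dict) -> None:
    rows = []
    for name, res in report["models"].items():
        for i, m in enumerate(res["fold_metrics"], start=1):
            rows.append({
                "model": name, "fold": i,
                "accuracy": m.accuracy, "kappa": m.kappa,
            })
        rows.append({
            "model": name, "fold": "mean",
            "accuracy": res["mean_accuracy"], "kappa": res["kappa"],
        })
        np.savetxt(
            os.path.join(out_dir, f"confusion_{name}.csv"),
            res["confusion"], fmt="%d", delimiter=",",
        )
    pd.DataFrame(rows).to_csv(os.path.join(out_dir, "metrics.csv"), index=False)
    manifest = {
        "package_version": __version__,
        "config_sha256": cfg.sha256(),
        "seed": seed,
        "config": cfg.raw,
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
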