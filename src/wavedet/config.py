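"""YAML run configuration with dotted-key overrides.

Sections: model / wtp / hhm / loss / optim / data / eval, plus top-level
``seed``, ``out_dir`` and ``device``.  Every artifact written by the CLI
embeds the config hash and seed so runs are reproducible from their outputs.
"""

from __future__ import annotations

import hashlib
import json
import yaml

from .detector import ModelConfig
from .matching import CostWeights
from .train import TrainConfig
from .wavelet import WTPConfig

__all__ = ["default_config", "load_config", "apply_overrides",
           "build_model_config", "build_train_config", "config_hash"]


def default_config() -> dict:
    return {
        "seed": 0,
        "out_dir": "runs/default",
        "device": "cpu",
        "model": {
            "num_classes": 9,
            "hidden_dim": 256,
            "heads": 8,
            "encoder_layers": 6,
            "decoder_layers": 6,
            "num_queries": 300,
            "deformable_points": 4,
            "ffn_hidden_dim": 1024,
            "backbone_channels": [256, 512, 1024, 2048],
            "use_wtp": True,
        },
        "wtp": {"levels": 2, "kernel_size": 5, "learnable_mode": "IWT",
                "share_across_scales": False},
        "hhm": {"schedule": [12, 10, 8, 6, 4, 2]},
        "loss": {"lambda_class": 2.0, "lambda_l1": 5.0, "lambda_giou": 2.0,
                 "focal_alpha": 0.25, "focal_gamma": 2.0},
        "optim": {"epochs": 50, "batch_size": 2, "lr": 1e-4,
                  "backbone_lr": 1e-5, "weight_decay": 1e-4,
                  "lr_drop_epochs": [10, 30], "lr_drop_factor": 0.1,
                  "eval_every": 5},
        "data": {"data_root": ".", "manifest": None, "split_seed": 0,
                 "test_fraction": 0.15, "group_aware_split": False},
        "eval": {"score_threshold": 0.3},
    }


def load_config(path=None) -> dict:
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for section, value in user.items():
            if isinstance(value, dict) and isinstance(cfg.get(section), dict):
                cfg[section].update(value)
            else:
                cfg[section] = value
    return cfg


def apply_overrides(cfg: dict, overrides: list) -> dict:
    """Apply "a.b=value" style overrides (YAML-parsed values)."""
    for item in overrides:
        if "=" not in item:
            raise ValueError(f"override {item!r} is not of the form key=value")
        key, raw = item.split("=", 1)
        value = yaml.safe_load(raw)
        node = cfg
        parts = key.split(".")
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = value
    return cfg


def build_model_config(cfg: dict) -> ModelConfig:
    m = dict(cfg["model"])
    m["backbone_channels"] = tuple(m.get("backbone_channels",
                                         [256, 512, 1024, 2048]))
    m["wtp"] = WTPConfig(**cfg.get("wtp", {}))
    m["score_threshold"] = cfg.get("eval", {}).get("score_threshold", 0.3)
    return ModelConfig(**m)


def build_train_config(cfg: dict) -> TrainConfig:
    o = dict(cfg.get("optim", {}))
    o["lr_drop_epochs"] = tuple(o.get("lr_drop_epochs", (10, 30)))
    o["schedule"] = list(cfg.get("hhm", {}).get("schedule",
                                                [12, 10, 8, 6, 4, 2]))
    o["loss"] = CostWeights(**cfg.get("loss", {}))
    o["seed"] = cfg.get("seed", 0)
    return TrainConfig(**o)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]
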