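"""Training loop: seeded, CPU-first, resumable, with per-layer loss logging.

The reference optimization recipe (AdamW, lr 1e-4 with 1e-5 for the
backbone, decay x0.1 at epochs 10 and 30, weight decay 1e-4, batch 2,
50 epochs) is stored as :func:`reference_recipe`; desk-scale runs override
freely.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .autograd import Tensor
from .data import IMAGENET_MEAN, IMAGENET_STD, box_xywh_to_normalized
from .detector import ModelConfig, WaveletDetector
from .evaluation import EvalResult, evaluate_detections
from .matching import (CostWeights, DuplicationSchedule, GroundTruthSet,
                       hhm_loss_batched)
from .nn import AdamW

__all__ = ["TrainConfig", "Trainer", "reference_recipe",
           "save_checkpoint", "load_checkpoint"]


@dataclass
class TrainConfig:
    epochs: int = 50
    batch_size: int = 2
    lr: float = 1e-4
    backbone_lr: float = 1e-5
    weight_decay: float = 1e-4
    lr_drop_epochs: tuple = (10, 30)
    lr_drop_factor: float = 0.1
    seed: int = 0
    schedule: list = field(default_factory=lambda: [12, 10, 8, 6, 4, 2])
    loss: CostWeights = field(default_factory=CostWeights)
    eval_every: int = 5
    stop_at_map50: float | None = None


def reference_recipe() -> TrainConfig:
    return TrainConfig()


def prepare_samples(manifest, images: dict, mean=IMAGENET_MEAN,
                    std=IMAGENET_STD):
    """Manifest + raw [0,1] arrays -> (stacked images, GroundTruthSets).

    Images are channel-replicated and standardized; boxes converted to
    normalized center format."""
    m = np.asarray(mean, dtype=np.float32).reshape(3, 1, 1)
    s = np.asarray(std, dtype=np.float32).reshape(3, 1, 1)
    xs, gts, ids = [], [], []
    for im in manifest.images:
        arr = np.asarray(images[im["id"]], dtype=np.float32)
        xs.append((np.repeat(arr[None], 3, axis=0) - m) / s)
        anns = manifest.annotations_for(im["id"])
        if anns:
            boxes = np.stack([box_xywh_to_normalized(
                a.bbox, im["width"], im["height"]) for a in anns])
            labels = np.array([a.category_id for a in anns])
        else:
            boxes = np.zeros((0, 4))
            labels = np.zeros(0, dtype=np.int64)
        gts.append(GroundTruthSet(boxes.astype(np.float32), labels))
        ids.append(im["id"])
    return np.stack(xs), gts, ids


class Trainer:
    def __init__(self, model: WaveletDetector, config: TrainConfig):
        self.model = model
        self.config = config
        backbone = set(id(p) for p in model.backbone.parameters())
        head_params = [p for p in model.parameters() if id(p) not in backbone]
        self.opt_head = AdamW(head_params, lr=config.lr,
                              weight_decay=config.weight_decay)
        self.opt_backbone = AdamW(model.backbone.parameters(),
                                  lr=config.backbone_lr,
                                  weight_decay=config.weight_decay)
        self.schedule = DuplicationSchedule(config.schedule)
        self.history: list[dict] = []
        self.epoch = 0
        self.last_layer_losses: list = []

    def _set_lr(self):
        factor = self.config.lr_drop_factor ** sum(
            self.epoch >= e for e in self.config.lr_drop_epochs)
        self.opt_head.lr = self.config.lr * factor
        self.opt_backbone.lr = self.config.backbone_lr * factor

    def train_epoch(self, images: np.ndarray, gts: list,
                    rng: np.random.Generator) -> float:
        n = len(images)
        order = rng.permutation(n)
        bs = self.config.batch_size
        total = 0.0
        layer_totals = None
        self._set_lr()
        for lo in range(0, n, bs):
            idx = order[lo:lo + bs]
            layers = self.model.forward(Tensor(images[idx]))
            loss, breakdown = hhm_loss_batched(
                layers, [gts[i] for i in idx], self.schedule,
                self.config.loss, return_breakdown=True)
            self.opt_head.zero_grad()
            self.opt_backbone.zero_grad()
            loss.backward()
            self.opt_head.step()
            self.opt_backbone.step()
            total += loss.item()
            if layer_totals is None:
                layer_totals = np.array(breakdown)
            else:
                layer_totals += breakdown
        self.epoch += 1
        self.last_layer_losses = [round(float(v / n), 4)
                                  for v in layer_totals]
        return total / n

    def evaluate(self, images: np.ndarray, gts: list, ids: list,
                 score_threshold: float = 0.3,
                 image_sizes: list | None = None) -> EvalResult:
        preds, gt_dicts = [], []
        h, w = images.shape[-2:]
        for i, img_id in enumerate(ids):
            # AP/AUC need the full candidate list; score_threshold only sets
            # the F1 / precision / recall operating point inside the evaluator
            for r in self.model.predict(images[i], threshold=0.0,
                                        image_id=img_id):
                preds.append(r.to_json())
            g = gts[i]
            for b, lab in zip(g.boxes, g.labels):
                cx, cy, bw, bh = b
                gt_dicts.append({
                    "image_id": img_id, "category_id": int(lab),
                    "bbox": [float((cx - bw / 2) * w), float((cy - bh / 2) * h),
                             float(bw * w), float(bh * h)]})
        return evaluate_detections(preds, gt_dicts,
                                   score_threshold=score_threshold)

    def fit(self, train_images, train_gts, test_images=None, test_gts=None,
            test_ids=None, log_path=None, verbose: bool = False):
        """Run the configured number of epochs; returns the history list.

        Evaluates every ``eval_every`` epochs when a test split is given and
        stops early once ``stop_at_map50`` is reached.
        """
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        log_fh = open(log_path, "a") if log_path else None
        try:
            for _ in range(cfg.epochs):
                t0 = time.time()
                mean_loss = self.train_epoch(train_images, train_gts, rng)
                entry = {"epoch": self.epoch, "loss": mean_loss,
                         "layer_losses": self.last_layer_losses,
                         "time_s": round(time.time() - t0, 2)}
                do_eval = (test_images is not None
                           and (self.epoch % cfg.eval_every == 0
                                or self.epoch == cfg.epochs))
                if do_eval:
                    res = self.evaluate(test_images, test_gts,
                                        test_ids or list(range(len(test_gts))))
                    entry["map50"] = res.macro.get("map50")
                    entry["map50_95"] = res.macro.get("map50_95")
                    entry["f1"] = res.macro.get("f1")
                self.history.append(entry)
                if log_fh:
                    log_fh.write(json.dumps(entry) + "\n")
                    log_fh.flush()
                if verbose:
                    print(entry)
                if (cfg.stop_at_map50 is not None
                        and entry.get("map50") is not None
                        and entry["map50"] >= cfg.stop_at_map50):
                    break
        finally:
            if log_fh:
                log_fh.close()
        return self.history


def save_checkpoint(path, model: WaveletDetector, train_config=None,
                    epoch: int = 0, seed: int = 0):
    """Versioned checkpoint: weights + model config + epoch + seed."""
    state = model.state_dict()
    meta = {
        "format_version": 1,
        "epoch": epoch,
        "seed": seed,
        "model_config": _config_dict(model.config),
        "train_config": asdict(train_config) if train_config else None,
    }
    np.savez(Path(path), __meta__=json.dumps(meta), **state)


def _config_dict(cfg: ModelConfig) -> dict:
    d = asdict(cfg)
    return d


def load_checkpoint(path):
    """Returns (model, meta)."""
    from .wavelet import WTPConfig
    with np.load(Path(path), allow_pickle=False) as archive:
        meta = json.loads(str(archive["__meta__"]))
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    mc = dict(meta["model_config"])
    mc["wtp"] = WTPConfig(**mc["wtp"])
    mc["backbone_channels"] = tuple(mc["backbone_channels"])
    model = WaveletDetector(ModelConfig(**mc), seed=meta.get("seed", 0))
    model.load_state_dict(state)
    return model, meta
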