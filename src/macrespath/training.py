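"""Training loops: teacher (attention-crop backbone), distilled student,
plain student, and the per-class lesion segmentation U-Nets.

All randomness is derived from one config seed via ``numpy.random
.SeedSequence`` keyed by (seed, stream, epoch), so each stream — batch
shuffling, augmentation, attention-map selection — is independently
reproducible and a run resumed at epoch ``e`` consumes exactly the random
numbers the uninterrupted run would have.  The learning rate follows a
cosine-annealing schedule with warm restarts: it decays from ``base_lr`` to
``eta_min`` over ``t_max`` steps and resets to ``base_lr``.

Model selection keeps the weights with the best validation accuracy; on
ties, the earlier epoch wins.  Validation is always computed in eval mode
with augmentation disabled.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np

from . import losses
from .attention import BACM, bacm_forward_loss
from .augment import AugmentConfig, augment_batch
from .metrics import per_class_report
from .models import ModelConfig, build_backbone, build_unet
from .nn import Adam, Tensor, cosine_annealing_lr
from .patches import NormalizationStats, PatchRecord

_STREAMS = {"model": 0, "data": 1, "aug": 2, "crop": 3}


@dataclasses.dataclass
class TrainConfig:
    epochs: int = 50
    batch_size: int = 8
    base_lr: float = 1e-5
    schedule: str = "cosine_annealing"  # "constant" | "cosine_annealing"
    t_max: int | None = None            # default: steps_per_epoch * epochs
    eta_min: float = 0.0
    seed: int = 0
    device: str = "cpu"

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.base_lr <= 0:
            raise ValueError("epochs/batch_size must be >= 1 and base_lr > 0")
        if self.schedule not in ("constant", "cosine_annealing"):
            raise ValueError(f"unknown schedule {self.schedule!r}")


def stream_rng(seed: int, stream: str, epoch: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence((seed, _STREAMS[stream], epoch)))


# ---------------------------------------------------------------------------
# data plumbing


def patches_to_arrays(patches: list[PatchRecord]) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([p.pixels for p in patches])
    y = np.array([p.label for p in patches], dtype=np.int64)
    return X, y


def channel_stats(X: np.ndarray) -> NormalizationStats:
    """Per-channel normalisation stats from a NHWC uint8 training array."""
    flat = X.reshape(-1, 3).astype(np.float64)
    mean, std = flat.mean(axis=0), flat.std(axis=0)
    if (std <= 0).any():
        raise ValueError("zero-variance channel in training data")
    return NormalizationStats(mean=mean, std=std, computed_over=[])


def make_preprocess(stats: NormalizationStats):
    """NHWC uint8 -> normalized NCHW float32."""
    def preprocess(batch: np.ndarray) -> np.ndarray:
        return stats.apply(batch)  # NHWC float32, the network's native layout
    return preprocess


def evaluate(model, X: np.ndarray, y: np.ndarray, preprocess,
             n_classes: int, batch_size: int = 32) -> dict:
    """Classification report on a split, eval mode, no augmentation."""
    model.eval()
    preds = []
    for i in range(0, len(X), batch_size):
        logits = model(Tensor(preprocess(X[i:i + batch_size])))
        preds.append(logits.data.argmax(axis=1))
    model.train()
    return per_class_report(y, np.concatenate(preds), n_classes)


# ---------------------------------------------------------------------------
# generic loop


def _run_training(model, loss_for_batch, data, cfg: TrainConfig, preprocess,
                  n_classes: int, augment_cfg: AugmentConfig | None):
    Xtr, ytr = data["train"]
    Xval, yval = data["val"]
    if len(Xtr) == 0 or len(Xval) == 0:
        raise ValueError("train and val splits must be nonempty")
    opt = Adam(model.parameters(), cfg.base_lr)
    steps_per_epoch = math.ceil(len(Xtr) / cfg.batch_size)
    t_max = cfg.t_max or steps_per_epoch * cfg.epochs
    history: list[dict] = []
    lr_trace: list[float] = []
    best_acc, best_state, best_epoch = -1.0, None, -1
    step = 0
    for epoch in range(cfg.epochs):
        rng_data = stream_rng(cfg.seed, "data", epoch)
        rng_aug = stream_rng(cfg.seed, "aug", epoch)
        rng_crop = stream_rng(cfg.seed, "crop", epoch)
        perm = rng_data.permutation(len(Xtr))
        epoch_losses: list[float] = []
        for i in range(0, len(perm), cfg.batch_size):
            idx = perm[i:i + cfg.batch_size]
            raw, yb = Xtr[idx], ytr[idx]
            if augment_cfg is not None:
                raw = augment_batch(raw, augment_cfg, rng_aug)
            if cfg.schedule == "cosine_annealing":
                opt.lr = cosine_annealing_lr(step, cfg.base_lr, t_max, cfg.eta_min)
            else:
                opt.lr = cfg.base_lr
            lr_trace.append(opt.lr)
            loss = loss_for_batch(raw, yb, rng_crop)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
            step += 1
        report = evaluate(model, Xval, yval, preprocess, n_classes)
        acc = report["overall_accuracy"]
        history.append({
            "epoch": epoch,
            "train_loss": float(np.mean(epoch_losses)),
            "val_accuracy": acc,
            "lr_last": lr_trace[-1],
        })
        if acc > best_acc:  # strict: ties keep the earlier epoch
            best_acc, best_epoch = acc, epoch
            best_state = [a.copy() for a in model.state_arrays()]
    if best_state is not None:
        model.load_state_arrays(best_state)
    return {"history": history, "lr_trace": lr_trace,
            "best_epoch": best_epoch, "best_val_accuracy": best_acc}


# ---------------------------------------------------------------------------
# teacher


def train_teacher(model_cfg: ModelConfig, data: dict, cfg: TrainConfig,
                  focal: losses.FocalParams = losses.FocalParams(),
                  augment_cfg: AugmentConfig | None = None,
                  theta_c: float = 0.5) -> tuple[BACM, dict]:
    """Train the attention-crop teacher with the two-pass focal loss.

    ``data`` maps split -> (X uint8 NHWC, y int); normalisation stats come
    from the training split only.
    """
    stats = channel_stats(data["train"][0])
    preprocess = make_preprocess(stats)
    backbone = build_backbone(model_cfg, seed=cfg.seed)
    model = BACM(backbone, n_maps=model_cfg.n_attention_maps,
                 theta_c=theta_c, crop_size=model_cfg.input_size, seed=cfg.seed)

    def loss_fn(logits, labels):
        return losses.focal_loss(logits, labels, focal)

    def loss_for_batch(raw, yb, rng_crop):
        loss, _, _ = bacm_forward_loss(model, raw, yb, loss_fn, preprocess, rng_crop)
        return loss

    result = _run_training(model, loss_for_batch, data, cfg, preprocess,
                           model_cfg.n_classes, augment_cfg)
    result["normalization"] = stats
    return model, result


# ---------------------------------------------------------------------------
# student


def train_student(student_cfg: ModelConfig, data: dict, cfg: TrainConfig,
                  teacher: BACM | None = None,
                  distill: losses.DistillParams = losses.DistillParams(),
                  focal: losses.FocalParams = losses.FocalParams(),
                  weights: tuple[float, float] = (0.5, 0.5),
                  literal_eq5: bool = False,
                  augment_cfg: AugmentConfig | None = None):
    """Train the plain student, optionally guided by a frozen teacher.

    With a teacher, each batch combines the hard-label focal term with the
    temperature-scaled KL term against the teacher's soft labels, plus a
    focal term on the prediction for the teacher's attention-cropped
    picture.  By default that prediction is the student's (so the term
    carries gradient); ``literal_eq5`` uses the teacher's own prediction
    instead, making the term a constant of the student optimisation.
    Without a teacher the loss reduces to plain supervised focal loss.
    """
    stats = channel_stats(data["train"][0])
    preprocess = make_preprocess(stats)
    model = build_backbone(student_cfg, seed=cfg.seed)
    if teacher is not None:
        if teacher.backbone.cfg.n_classes != student_cfg.n_classes:
            raise ValueError("teacher/student class-count mismatch")
        teacher.eval()
        teacher_checksum = _params_checksum(teacher)
    t = distill.temperature

    mix = 0.0 if teacher is None else distill.mix
    w = (1.0, 0.0) if teacher is None else weights

    def loss_for_batch(raw, yb, rng_crop):
        z_s = model(Tensor(preprocess(raw)))
        shp = losses.softmax(z_s, 1.0)
        hard = losses.focal_loss_pt(losses.true_class_prob(shp, yb), focal)
        if teacher is not None:
            fmap_t, logits_t = teacher.backbone.forward_features(
                Tensor(preprocess(raw)))
        if mix > 0:
            tsl = losses.soft_targets(logits_t.data, t)
            ssp = losses.softmax(z_s, t)
            soft_term = (mix * t * t) * losses.kl_divergence(tsl, ssp)
        else:
            soft_term = 0.0
        l_kd = (1.0 - mix) * hard + soft_term
        if teacher is not None and w[1] > 0:
            crops = teacher.crop_batch(raw, fmap_t, rng_crop)
            if literal_eq5:
                z_att = Tensor(teacher.backbone(Tensor(preprocess(crops))).data)
            else:
                z_att = model(Tensor(preprocess(crops)))
            att = losses.focal_loss(z_att, yb, focal)
        else:
            att = 0.0
        return losses.total_loss(l_kd, att, w)

    result = _run_training(model, loss_for_batch, data, cfg, preprocess,
                           student_cfg.n_classes, augment_cfg)
    result["normalization"] = stats
    if teacher is not None:
        assert _params_checksum(teacher) == teacher_checksum, \
            "teacher parameters changed during distillation"
        teacher.train()
    return model, result


def _params_checksum(model) -> float:
    return float(sum(np.abs(a).sum() for a in model.state_arrays()))


# ---------------------------------------------------------------------------
# segmentation


def train_unet(tiles: np.ndarray, masks: np.ndarray, cfg: TrainConfig,
               base_width: int = 8, depth: int = 2,
               stats: NormalizationStats | None = None):
    """Train a binary-segmentation U-Net with pixelwise BCE.

    ``tiles`` NHWC uint8, ``masks`` NHW binary.  Returns (model, result).
    """
    stats = stats or channel_stats(tiles)
    preprocess = make_preprocess(stats)
    model = build_unet(base_width=base_width, depth=depth, seed=cfg.seed)
    opt = Adam(model.parameters(), cfg.base_lr)
    n = len(tiles)
    steps_per_epoch = math.ceil(n / cfg.batch_size)
    t_max = cfg.t_max or steps_per_epoch * cfg.epochs
    history, step = [], 0
    eps = 1e-7
    for epoch in range(cfg.epochs):
        rng = stream_rng(cfg.seed, "data", epoch)
        perm = rng.permutation(n)
        epoch_losses = []
        for i in range(0, n, cfg.batch_size):
            idx = perm[i:i + cfg.batch_size]
            x = Tensor(preprocess(tiles[idx]))
            y = masks[idx].astype(np.float32)[:, None]
            if cfg.schedule == "cosine_annealing":
                opt.lr = cosine_annealing_lr(step, cfg.base_lr, t_max, cfg.eta_min)
            p = model(x).sigmoid()
            yt = Tensor(y)
            loss = -(yt * (p + eps).log()
                     + (1.0 - yt) * (1.0 - p + eps).log()).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
            step += 1
        history.append({"epoch": epoch, "train_loss": float(np.mean(epoch_losses))})
    return model, {"history": history, "normalization": stats}


# ---------------------------------------------------------------------------
# run-state persistence (CSV history)


def write_history(result: dict, out_dir: str | Path) -> Path:
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "history.csv"
    pd.DataFrame(result["history"]).to_csv(path, index=False)
    np.savetxt(out / "lr_trace.txt", np.asarray(result.get("lr_trace", [])))
    return path
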