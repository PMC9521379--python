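"""Base-model training with the mask-gated cross-entropy loss.

The loss is the ordinary per-pixel cross-entropy with a binary supervision
mask multiplied into every pixel term:

    L = -(1/N)(1/M) sum_n sum_m sum_c Mask(x_{n,m}) * y_{n,m}^c * log p_{n,m}^c

with N images per batch, M pixels per image, and one-hot labels y.  The
denominator is the total pixel count M, not the masked count, so masking
only ever removes terms; the masked-count normalization is available
behind a flag.  An all-ones mask recovers plain cross-entropy exactly.

Optimization follows the Adam protocol (lr 1e-4, weight decay 1e-5, batch
16), with random patch cropping and lossless flip/rotate augmentation
applied jointly to image, label, and mask.  Because a training epoch over
a handful of small phantoms gives far fewer gradient steps than an epoch
over stacks of full MRI slices, the sampling density is explicit:
``crops_per_image`` random patches are drawn per image per epoch.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam, softmax
from .bayesian_unet import TrainedModel, UNetConfig, build_model
from .io_preprocess import AugmentConfig, VolumeRecord, augment, gaussian_normalize, random_crop

LOG_EPS = 1e-7  # probabilities are clipped to [LOG_EPS, 1] before log


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    weight_decay: float = 1e-5
    batch_size: int = 16
    epochs: int = 20
    patch_shape: tuple[int, int] = (32, 32)
    seed: int = 0
    augmentation: AugmentConfig = field(default_factory=AugmentConfig)
    crops_per_image: int = 8
    lesion_biased_crops: bool = True
    normalize_by_mask_count: bool = False

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("rates must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


def masked_cross_entropy(probs: np.ndarray, labels: np.ndarray, masks: np.ndarray,
                         normalize_by_mask_count: bool = False) -> float:
    """Mask-gated cross-entropy over a batch.

    probs: (N, C, H, W) softmax outputs; labels: (N, H, W) integer class
    ids; masks: (N, H, W) binary.  A fully zero mask returns 0.0 with a
    warning (no supervision at all).
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels)
    masks = np.asarray(masks)
    if probs.ndim != 4:
        raise ValueError(f"probs must be (N, C, H, W), got shape {probs.shape}")
    n, c, h, w = probs.shape
    if labels.shape != (n, h, w) or masks.shape != (n, h, w):
        raise ValueError(
            f"shape mismatch: probs {probs.shape}, labels {labels.shape}, masks {masks.shape}"
        )
    uniq = np.unique(masks)
    if not np.isin(uniq, [0, 1]).all():
        raise ValueError(f"mask must be binary, found values {uniq}")
    if labels.min() < 0 or labels.max() >= c:
        raise ValueError(f"labels must lie in [0, {c - 1}]")
    if masks.sum() == 0:
        warnings.warn("supervision mask is entirely zero; loss is 0", stacklevel=2)
        return 0.0
    p_true = np.take_along_axis(probs, labels[:, None].astype(np.intp), axis=1)[:, 0]
    terms = masks * np.log(np.clip(p_true, LOG_EPS, 1.0))
    denom = float(masks.sum()) if normalize_by_mask_count else float(n * h * w)
    return float(-terms.sum() / denom)


def _loss_and_grad(logits: np.ndarray, labels: np.ndarray, masks: np.ndarray,
                   normalize_by_mask_count: bool) -> tuple[float, np.ndarray]:
    """Loss value and dL/dlogits for one batch (softmax folded in)."""
    n, c, h, w = logits.shape
    p = softmax(logits.astype(np.float64), axis=1)
    onehot = np.zeros_like(p)
    np.put_along_axis(onehot, labels[:, None].astype(np.intp), 1.0, axis=1)
    denom = float(masks.sum()) if normalize_by_mask_count else float(n * h * w)
    if denom == 0:
        return 0.0, np.zeros_like(logits)
    p_true = np.take_along_axis(p, labels[:, None].astype(np.intp), axis=1)[:, 0]
    loss = float(-(masks * np.log(np.clip(p_true, LOG_EPS, 1.0))).sum() / denom)
    dlogits = (masks[:, None] * (p - onehot) / denom).astype(np.float32)
    return loss, dlogits


def _prepare_batch(records, masks, indices, patch_shape, cfg: TrainConfig,
                   rng: np.random.Generator):
    xs, ys, ms = [], [], []
    for i in indices:
        rec = records[i]
        m = masks[i] if masks is not None else None
        img, lab, msk = random_crop(rec, patch_shape, seed=int(rng.integers(2 ** 31)),
                                    mask=m, lesion_biased=cfg.lesion_biased_crops)
        img, lab, msk = augment(img, lab, msk, seed=int(rng.integers(2 ** 31)),
                                config=cfg.augmentation)
        xs.append(img)
        ys.append(lab)
        ms.append(msk)
    return (np.stack(xs).astype(np.float32), np.stack(ys).astype(np.intp),
            np.stack(ms).astype(np.float64))


def train_base_model(records: list[VolumeRecord],
                     masks: list[np.ndarray] | None,
                     unet_config: UNetConfig,
                     train_config: TrainConfig,
                     lambda_used: float | None = None) -> TrainedModel:
    """Train one segmentation network under a fixed supervision-mask set.

    ``masks[i]`` is the binary supervision mask for ``records[i]``; None
    means full supervision (all-ones masks).  Deterministic for a fixed
    (data, configs, seed) on a fixed BLAS build.
    """
    if masks is not None:
        if len(masks) != len(records):
            raise ValueError(f"{len(records)} records but {len(masks)} masks")
        for rec, m in zip(records, masks):
            if m is None:
                raise ValueError(f"missing supervision mask for {rec.subject_id!r}")
            if m.shape != rec.label.shape:
                raise ValueError(
                    f"mask shape {m.shape} != label shape {rec.label.shape} "
                    f"for {rec.subject_id!r}"
                )
    cfg = train_config
    model = build_model(unet_config, seed=cfg.seed)
    model.fingerprint = {"lambda": lambda_used, "seed": cfg.seed, "epochs": cfg.epochs}
    if cfg.epochs == 0:
        return model

    dropout_in_training = unet_config.has_dropout  # both train_* modes
    ss = np.random.SeedSequence(cfg.seed)
    data_rng = np.random.default_rng(ss.spawn(1)[0])
    net_rng = np.random.default_rng(ss.spawn(1)[0])
    opt = Adam(model.net.parameters(), lr=cfg.learning_rate,
               weight_decay=cfg.weight_decay)
    n = len(records)
    steps = max(1, math.ceil(n * cfg.crops_per_image / cfg.batch_size))
    curve = []
    for _ in range(cfg.epochs):
        epoch_loss = 0.0
        for _ in range(steps):
            idx = data_rng.integers(0, n, size=cfg.batch_size)
            x, y, m = _prepare_batch(records, masks, idx, cfg.patch_shape, cfg, data_rng)
            logits = model.net.forward(x, dropout_active=dropout_in_training, rng=net_rng)
            loss, dlogits = _loss_and_grad(logits, y, m, cfg.normalize_by_mask_count)
            opt.zero_grad()
            model.net.backward(dlogits)
            opt.step()
            epoch_loss += loss
        curve.append(epoch_loss / steps)
    model.fingerprint["loss_curve"] = curve
    return model


def train_uncertainty_oracle(records: list[VolumeRecord],
                             unet_config: UNetConfig,
                             train_config: TrainConfig) -> TrainedModel:
    """Train the Bayesian network that scores annotation uncertainty.

    Full supervision (all-ones masks, plain cross-entropy); requires θ > 0
    and inference-time dropout so MC sampling is possible afterwards.
    """
    if unet_config.dropout_rate <= 0:
        raise ValueError("uncertainty oracle needs dropout_rate > 0 for MC sampling")
    if unet_config.dropout_mode != "train_and_inference":
        raise ValueError("uncertainty oracle needs dropout_mode='train_and_inference'")
    model = train_base_model(records, None, unet_config, train_config, lambda_used=1.0)
    return model


def records_from_phantoms(samples, label: str = "observed",
                          normalize: bool = True) -> list[VolumeRecord]:
    """Adapt phantom samples to training records; labels from the noisy
    observed annotation by default (the clean label is held out as truth)."""
    records = []
    for smp in samples:
        img = gaussian_normalize(smp.image) if normalize else smp.image
        lab = smp.observed_label if label == "observed" else smp.clean_label
        records.append(VolumeRecord(image=img.astype(np.float32), label=lab,
                                    subject_id=smp.sample_id))
    return records
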