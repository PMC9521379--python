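"""Whole-image prediction by sliding-window tiling with 50% overlap.

Windows advance by half the patch size per axis; the final window is
clamped to the image edge so every pixel is covered without padding.
Overlapping probabilities are averaged uniformly per pixel.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class TilingPlan:
    patch_shape: tuple[int, int]
    stride: tuple[int, int]
    origins: list[tuple[int, int]]
    accumulation: str = "mean"


def _axis_origins(size: int, patch: int, stride: int) -> list[int]:
    origins = list(range(0, size - patch + 1, stride))
    if origins[-1] != size - patch:
        origins.append(size - patch)
    return origins


def plan_tiling(image_shape: tuple[int, int], patch_shape: tuple[int, int]) -> TilingPlan:
    h, w = image_shape
    ph, pw = patch_shape
    if ph > h or pw > w:
        raise ValueError(f"patch shape {patch_shape} exceeds image shape {image_shape}")
    stride = (max(1, ph // 2), max(1, pw // 2))
    origins = [(oy, ox)
               for oy in _axis_origins(h, ph, stride[0])
               for ox in _axis_origins(w, pw, stride[1])]
    return TilingPlan(patch_shape=(ph, pw), stride=stride, origins=origins)


def sliding_window_predict(predict_fn, image: np.ndarray, plan: TilingPlan) -> np.ndarray:
    """Average per-window softmax maps into one (classes, H, W) probability map.

    ``predict_fn`` maps a batch of patches (B, C, ph, pw) to a batch of
    probability maps (B, classes, ph, pw); all windows of the plan are
    predicted in one call.  Models and ensembles are adapted via
    ``as_predict_fn``.
    """
    _, h, w = image.shape
    ph, pw = plan.patch_shape
    if any(oy + ph > h or ox + pw > w for oy, ox in plan.origins):
        raise ValueError(f"tiling plan exceeds image shape {(h, w)}")
    windows = np.stack([image[:, oy:oy + ph, ox:ox + pw] for oy, ox in plan.origins])
    probs = np.asarray(predict_fn(windows))
    if probs.shape[0] != len(plan.origins) or probs.ndim != 4:
        raise ValueError(
            f"predict_fn returned shape {probs.shape} for {len(plan.origins)} windows"
        )
    acc = np.zeros((probs.shape[1], h, w), dtype=np.float64)
    count = np.zeros((h, w), dtype=np.float64)
    for b, (oy, ox) in enumerate(plan.origins):
        acc[:, oy:oy + ph, ox:ox + pw] += probs[b]
        count[oy:oy + ph, ox:ox + pw] += 1.0
    if (count == 0).any():
        raise AssertionError("tiling plan left uncovered pixels")
    return acc / count


def as_predict_fn(model_or_ensemble):
    """Adapt a TrainedModel or EnsembleModel to a batched patch predictor."""
    from .bayesian_unet import TrainedModel, predict_probabilities

    if isinstance(model_or_ensemble, TrainedModel):
        return lambda patches: predict_probabilities(model_or_ensemble, patches,
                                                     stochastic=False)
    if hasattr(model_or_ensemble, "members"):
        from .ensemble import fuse_probability

        def fn(patches):
            return fuse_probability([
                predict_probabilities(m, patches, stochastic=False)
                for m in model_or_ensemble.members
            ])

        return fn
    if callable(model_or_ensemble):
        return model_or_ensemble
    raise TypeError(f"cannot build a predictor from {type(model_or_ensemble)!r}")
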