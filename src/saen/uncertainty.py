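"""Monte-Carlo-dropout annotation-uncertainty estimation.

A Bayesian (dropout-bearing) network is run T times on the same image with
dropout active; the T softmax maps form a predictive sample.  The per-pixel
mean of the foreground probability approximates the Bayesian predictive
probability, and its per-pixel standard deviation (population convention,
divide by T) is the probability-variation uncertainty: exactly zero where
every sample agrees, large where the approximate posterior disagrees with
itself — empirically, at ambiguous lesion boundaries.  Min–max
normalization puts each image's map on [0, 1] so one threshold grid can
serve every image.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .bayesian_unet import TrainedModel, predict_probabilities


@dataclass
class ProbabilityStack:
    """T softmax samples for one image: (T, classes, H, W)."""

    samples: np.ndarray
    source_model_id: str = ""

    def __post_init__(self) -> None:
        s = self.samples
        if s.ndim != 4 or s.shape[0] < 1:
            raise ValueError(f"expected (T, classes, H, W) with T >= 1, got {s.shape}")
        sums = s.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("per-pixel class probabilities must sum to 1")

    @property
    def T(self) -> int:
        return self.samples.shape[0]


@dataclass
class UncertaintyMap:
    values: np.ndarray          # (H, W), >= 0
    normalized: bool = False
    normalization_stats: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if (self.values < 0).any():
            raise ValueError("uncertainty values must be non-negative")
        if self.normalized and (self.values > 1 + 1e-12).any():
            raise ValueError("normalized uncertainty must lie in [0, 1]")


def mc_sample(model: TrainedModel, image: np.ndarray, T: int, seed: int) -> ProbabilityStack:
    """Draw T stochastic forward passes with independent dropout masks."""
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    if not (model.config.dropout_rate > 0 and model.config.dropout_mode == "train_and_inference"):
        warnings.warn("model has no inference-time dropout; MC samples will be identical",
                      stacklevel=2)
    # one batched forward: the dropout mask spans the batch axis, so the
    # T replicas get independent Bernoulli draws from a single seeded rng
    batch = np.broadcast_to(image, (T,) + image.shape)
    samples = predict_probabilities(model, np.ascontiguousarray(batch),
                                    stochastic=True, seed=seed)
    return ProbabilityStack(samples=samples)


def mean_probability(stack: ProbabilityStack) -> np.ndarray:
    """Per-pixel, per-class arithmetic mean over the T samples: (classes, H, W)."""
    return stack.samples.mean(axis=0)


def probability_variation(stack: ProbabilityStack, class_of_interest: int = 1) -> UncertaintyMap:
    """Per-pixel SD of the chosen class probability across the T samples.

    Population convention (divide by T): identical samples give exactly 0.
    T = 1 yields an all-zero map with a warning.
    """
    c = class_of_interest
    if not 0 <= c < stack.samples.shape[1]:
        raise IndexError(f"class index {c} out of range for {stack.samples.shape[1]} classes")
    if stack.T == 1:
        warnings.warn("T=1: probability variation is identically zero", stacklevel=2)
        return UncertaintyMap(values=np.zeros(stack.samples.shape[2:]))
    p = stack.samples[:, c]
    var = (p * p).mean(axis=0) - p.mean(axis=0) ** 2
    # exact-zero convention: pixels where every sample agrees get SD 0,
    # untouched by floating-point cancellation in the shortcut formula
    var[p.max(axis=0) == p.min(axis=0)] = 0.0
    return UncertaintyMap(values=np.sqrt(np.maximum(var, 0.0)))


def normalize_uncertainty(raw: UncertaintyMap) -> UncertaintyMap:
    """Min–max rescale to [0, 1] per image; a constant map becomes all zeros.

    The all-zero convention for constant maps means "uniformly certain":
    every pixel then survives any threshold λ >= 0.
    """
    if raw.normalized:
        return raw
    v = raw.values
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        out = np.zeros_like(v)
    else:
        out = (v - lo) / (hi - lo)
    return UncertaintyMap(values=out, normalized=True, normalization_stats=(lo, hi))
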