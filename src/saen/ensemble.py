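"""Ensemble orchestration: K base learners under distinct λ masks, fused by
probability averaging, with member disagreement as epistemic uncertainty.

The pipeline is two-stage.  First a Bayesian oracle network scores every
training image's annotation uncertainty by MC dropout; the normalized maps
are thresholded at K sampled λ values to give K supervision-mask sets.
Then K networks are trained, one per mask set, with member seeds derived
as master_seed + member index.  At prediction time the member softmax maps
are averaged, the segmentation is the class argmax (foreground wins ties
at 0.5), and the per-pixel SD of the member foreground probabilities is
reported as epistemic uncertainty — on the same SD scale as the oracle's
aleatoric maps.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .bayesian_unet import TrainedModel, UNetConfig, load_model, predict_probabilities, save_model
from .masking import DEFAULT_LAMBDA_GRID, LambdaSchedule, make_mask, sample_lambda_schedule
from .training import TrainConfig, train_base_model
from .uncertainty import mc_sample, normalize_uncertainty, probability_variation


@dataclass
class EnsembleModel:
    members: list[TrainedModel]
    schedule: LambdaSchedule
    fusion: str = "mean_probability"

    def __post_init__(self) -> None:
        if len(self.members) != self.schedule.K:
            raise ValueError(
                f"{len(self.members)} members but schedule has K={self.schedule.K}"
            )

    @property
    def K(self) -> int:
        return len(self.members)


@dataclass
class EnsemblePrediction:
    fused_probability: np.ndarray    # (classes, H, W)
    segmentation: np.ndarray         # (H, W) uint8
    epistemic_uncertainty: np.ndarray  # (H, W) >= 0
    member_probabilities: list[np.ndarray] = field(default_factory=list)


def fuse_probability(member_probabilities: list[np.ndarray]) -> np.ndarray:
    """Arithmetic mean of the member softmax maps."""
    if len(member_probabilities) == 0:
        raise ValueError("need at least one member probability map")
    shapes = {p.shape for p in member_probabilities}
    if len(shapes) > 1:
        raise ValueError(f"member maps disagree in shape: {sorted(shapes)}")
    return np.mean(member_probabilities, axis=0)


def fuse(member_probabilities: list[np.ndarray],
         foreground_class: int = 1) -> EnsemblePrediction:
    """Average member maps, argmax to a segmentation, SD to uncertainty.

    Binary convention: a pixel is foreground iff its fused foreground
    probability is >= 0.5 (ties resolve to foreground).  Epistemic
    uncertainty is the population SD of the member foreground
    probabilities; a single member gives an all-zero map.
    """
    fused = fuse_probability(member_probabilities)
    if fused.shape[0] == 2:
        seg = (fused[foreground_class] >= 0.5).astype(np.uint8)
    else:
        seg = fused.argmax(axis=0).astype(np.uint8)
    fg = np.stack([p[foreground_class] for p in member_probabilities])
    var = (fg * fg).mean(axis=0) - fg.mean(axis=0) ** 2
    unc = np.sqrt(np.maximum(var, 0.0))
    return EnsemblePrediction(fused_probability=fused, segmentation=seg,
                              epistemic_uncertainty=unc,
                              member_probabilities=list(member_probabilities))


def predict_ensemble(ensemble: EnsembleModel, image: np.ndarray) -> EnsemblePrediction:
    """Deterministic member predictions on one image, fused."""
    maps = [predict_probabilities(m, image, stochastic=False) for m in ensemble.members]
    return fuse(maps)


def compute_uncertainty_maps(records, oracle: TrainedModel, T: int = 20,
                             seed: int = 0, foreground_class: int = 1):
    """Normalized MC-dropout uncertainty map for every training record.

    Computed once from the frozen oracle; the same maps are thresholded at
    every λ (two-stage design — masks are never refreshed during base-model
    training)."""
    maps = []
    sub_seeds = np.random.SeedSequence(seed).generate_state(len(records))
    for rec, s in zip(records, sub_seeds):
        stack = mc_sample(oracle, rec.image, T=T, seed=int(s))
        raw = probability_variation(stack, class_of_interest=foreground_class)
        maps.append(normalize_uncertainty(raw))
    return maps


def compute_training_masks(records, oracle: TrainedModel, lam: float,
                           T: int = 20, seed: int = 0,
                           foreground_class: int = 1) -> list[np.ndarray]:
    """One supervision mask per record from the frozen oracle at threshold λ."""
    maps = compute_uncertainty_maps(records, oracle, T=T, seed=seed,
                                    foreground_class=foreground_class)
    return [make_mask(u, lam, source_sample_id=rec.subject_id).mask
            for rec, u in zip(records, maps)]


def train_ensemble(records, oracle: TrainedModel, K: int,
                   unet_config: UNetConfig, train_config: TrainConfig,
                   master_seed: int = 0, grid=DEFAULT_LAMBDA_GRID,
                   T: int = 20) -> EnsembleModel:
    """Supervision-augmented ensemble: K learners under distinct λ masks."""
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    if oracle.config.dropout_rate <= 0:
        raise ValueError("oracle must have dropout_rate > 0")
    schedule = sample_lambda_schedule(K, grid=grid, seed=master_seed)
    maps = compute_uncertainty_maps(records, oracle, T=T, seed=master_seed)
    members = []
    for k, lam in enumerate(schedule.lambdas):
        try:
            masks = [make_mask(u, lam, source_sample_id=rec.subject_id).mask
                     for rec, u in zip(records, maps)]
            cfg_k = TrainConfig(**{**train_config.__dict__, "seed": master_seed + k})
            members.append(train_base_model(records, masks, unet_config, cfg_k,
                                            lambda_used=lam))
        except Exception as err:
            raise RuntimeError(f"training ensemble member {k} (lambda={lam}) failed") from err
    return EnsembleModel(members=members, schedule=schedule)


def train_rwi_baseline(records, K: int, unet_config: UNetConfig,
                       train_config: TrainConfig, master_seed: int = 0) -> EnsembleModel:
    """Random-weight-initialization ensemble control: K fully supervised
    learners differing only in their seeds, fused identically."""
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    members = []
    for k in range(K):
        cfg_k = TrainConfig(**{**train_config.__dict__, "seed": master_seed + k})
        members.append(train_base_model(records, None, unet_config, cfg_k,
                                        lambda_used=1.0))
    schedule = LambdaSchedule(lambdas=[1.0] * K, grid=(1.0,), seed=master_seed)
    return EnsembleModel(members=members, schedule=schedule)


# -- serialization -----------------------------------------------------

def save_ensemble(ensemble: EnsembleModel, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for k, m in enumerate(ensemble.members):
        save_model(m, out / f"member_{k:02d}.npz")
    meta = dict(K=ensemble.K, lambdas=ensemble.schedule.lambdas,
                grid=list(ensemble.schedule.grid), seed=ensemble.schedule.seed,
                fusion=ensemble.fusion,
                fingerprints=[{k: v for k, v in m.fingerprint.items() if k != "loss_curve"}
                              for m in ensemble.members])
    (out / "ensemble.json").write_text(json.dumps(meta, indent=2))
    return out / "ensemble.json"


def load_ensemble(ens_dir) -> EnsembleModel:
    ens_dir = Path(ens_dir)
    meta = json.loads((ens_dir / "ensemble.json").read_text())
    members = [load_model(ens_dir / f"member_{k:02d}.npz") for k in range(meta["K"])]
    schedule = LambdaSchedule(lambdas=meta["lambdas"], grid=tuple(meta["grid"]),
                              seed=meta["seed"])
    return EnsembleModel(members=members, schedule=schedule, fusion=meta["fusion"])
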