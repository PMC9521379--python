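"""Binary supervision masks from normalized uncertainty, and λ schedules.

A pixel participates in the loss iff its normalized uncertainty does not
exceed the threshold λ (boundary inclusive).  One λ per base learner,
drawn from a fixed grid — without replacement while possible, so the K
learners see maximally diverse supervision.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .uncertainty import UncertaintyMap

DEFAULT_LAMBDA_GRID: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(1, 11))


@dataclass
class SupervisionMask:
    mask: np.ndarray            # (H, W) uint8
    lambda_used: float
    source_sample_id: str = ""


@dataclass
class LambdaSchedule:
    lambdas: list[float]
    grid: tuple[float, ...]
    seed: int

    def __post_init__(self) -> None:
        if any(not 0.0 <= l <= 1.0 for l in self.lambdas):
            raise ValueError(f"every lambda must lie in [0, 1], got {self.lambdas}")

    @property
    def K(self) -> int:
        return len(self.lambdas)


def make_mask(uncertainty: UncertaintyMap, lam: float,
              source_sample_id: str = "") -> SupervisionMask:
    """Mask = 1 where U <= λ (pixel kept in the loss), 0 where U > λ."""
    if not uncertainty.normalized:
        raise ValueError("uncertainty map must be normalized to [0, 1] first "
                         "(see normalize_uncertainty)")
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    return SupervisionMask(mask=(uncertainty.values <= lam).astype(np.uint8),
                           lambda_used=lam, source_sample_id=source_sample_id)


def sample_lambda_schedule(K: int, grid=DEFAULT_LAMBDA_GRID, seed: int = 0) -> LambdaSchedule:
    """Draw K thresholds from the grid; without replacement while K <= |grid|.

    Distinct thresholds per base learner maximize supervision diversity;
    only when K exceeds the grid size are repeats allowed.
    """
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    grid = tuple(float(g) for g in grid)
    if len(grid) == 0:
        raise ValueError("lambda grid must be non-empty")
    if any(not 0.0 <= g <= 1.0 for g in grid):
        raise ValueError(f"grid values must lie in [0, 1], got {grid}")
    rng = np.random.default_rng(seed)
    if K <= len(grid):
        lambdas = list(rng.choice(grid, size=K, replace=False))
    else:
        lambdas = list(rng.choice(grid, size=K, replace=True))
    return LambdaSchedule(lambdas=[float(l) for l in lambdas], grid=grid, seed=seed)
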