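"""Reference uptake: liver and blood-pool SUVmean used to normalize lesions.

Lesion PSMA scores are normalized by the mean SUV of a healthy reference
tissue.  Both standard PET references are computed — the liver and the
blood pool (aorta) — and the caller records which one downstream scoring
should divide by.  The blood pool is the default; the choice is
configurable because either organ is a legitimate normalizer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .grid import OrganMaskSet, VoxelGrid

ReferenceChoice = Literal["blood_pool", "liver"]


@dataclass(frozen=True)
class ReferenceUptake:
    """Mean SUV of the two reference organs and the normalizer choice."""

    liver_suv_mean: float
    blood_pool_suv_mean: float
    reference_choice: ReferenceChoice = "blood_pool"

    def __post_init__(self) -> None:
        if self.liver_suv_mean <= 0 or self.blood_pool_suv_mean <= 0:
            raise ValueError("reference SUVmean values must be positive")
        if self.reference_choice not in ("blood_pool", "liver"):
            raise ValueError(f"unknown reference_choice {self.reference_choice!r}")

    @property
    def chosen_mean(self) -> float:
        """SUVmean of the organ selected for normalization."""
        if self.reference_choice == "liver":
            return self.liver_suv_mean
        return self.blood_pool_suv_mean


def _masked_mean(pet: VoxelGrid, mask: np.ndarray, organ: str) -> float:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != pet.shape:
        raise ValueError(f"{organ} mask shape {mask.shape} != grid shape {pet.shape}")
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"{organ} mask empty")
    vals = pet.values[mask]
    if np.any(vals < 0):
        raise ValueError(f"negative SUV under {organ} mask")
    return float(vals.mean())


def compute_reference_uptake(
    pet: VoxelGrid,
    masks: OrganMaskSet,
    reference_choice: ReferenceChoice = "blood_pool",
) -> ReferenceUptake:
    """Arithmetic-mean SUV over the liver and blood-pool masks.

    Plain (untrimmed) means are used.  Raises ``ValueError`` if either
    mask is empty, shape-mismatched, or covers negative SUV values.
    """
    masks.check_congruent(pet)
    return ReferenceUptake(
        liver_suv_mean=_masked_mean(pet, masks.liver, "liver"),
        blood_pool_suv_mean=_masked_mean(pet, masks.blood_pool, "blood_pool"),
        reference_choice=reference_choice,
    )
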