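"""PSMA scores: per-lesion, per-compartment, and composite tumor burden.

The lesion PSMA score is

    score = volume_ml * SUVmean / SUVmean_reference

i.e. reference-normalized total lesion uptake, in millilitres (the SUV
ratio is dimensionless).  Compartment scores are sums of the accepted
lesion scores in that compartment (regional and non-regional nodes pool
into a single nodal compartment); the composite score is the sum of the
compartment scores, so it equals the sum over all accepted, classified
lesions.  A compartment with no accepted lesion is *missing*, not zero
— a patient without nodal disease has no nodal score, matching the
"N/A" convention of clinical response tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .grid import Lesion
from .reference import ReferenceUptake


@dataclass
class CompartmentScores:
    """Per-compartment and composite PSMA scores for one patient-timepoint.

    ``None`` marks a compartment with no accepted lesion.  The composite
    is the sum of the non-missing compartment scores (0.0 when all are
    missing).
    """

    prostate_bed: float | None = None
    nodal: float | None = None
    osseous: float | None = None
    reference_used: str = "blood_pool"

    @property
    def composite(self) -> float:
        return sum(
            v for v in (self.prostate_bed, self.nodal, self.osseous) if v is not None
        )

    def as_dict(self) -> dict[str, float | None]:
        return {
            "prostate_bed": self.prostate_bed,
            "nodal": self.nodal,
            "osseous": self.osseous,
            "composite": self.composite,
        }


def lesion_psma_score(lesion: Lesion, ref: ReferenceUptake) -> float:
    """volume_ml x SUVmean / reference SUVmean for one accepted lesion."""
    if not lesion.accepted:
        raise ValueError(f"lesion {lesion.lesion_id} was rejected at review")
    if ref.chosen_mean <= 0:
        raise ValueError("reference SUVmean must be positive")
    score = lesion.volume_ml * lesion.suv_mean / ref.chosen_mean
    lesion.psma_score = score
    return score


def compartment_scores(
    lesions: list[Lesion], ref: ReferenceUptake
) -> CompartmentScores:
    """Sum accepted lesion scores into compartments and the composite.

    Rejected or unclassified lesions contribute nothing.  Compartments
    without any contributing lesion stay missing (``None``).
    """
    totals: dict[str, float] = {}
    for les in lesions:
        if not les.accepted or les.compartment is None:
            continue
        pooled = les.compartment.pooled()
        totals[pooled] = totals.get(pooled, 0.0) + lesion_psma_score(les, ref)
    return CompartmentScores(
        prostate_bed=totals.get("prostate_bed"),
        nodal=totals.get("nodal"),
        osseous=totals.get("osseous"),
        reference_used=ref.reference_choice,
    )


def display_score(score: float) -> float:
    """Round a score to 1 decimal for display (half away from zero)."""
    return math.floor(abs(score) * 10 + 0.5) / 10 * (1 if score >= 0 else -1)
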