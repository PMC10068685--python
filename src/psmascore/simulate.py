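"""Synthetic data: PET phantoms and paired baseline/follow-up cohorts.

Two generators make every pipeline stage testable without patient data.

**Phantoms** are whole-body-like SUV grids: a uniform background, a
liver plateau and a blood-pool (aorta) plateau as reference regions,
and spherical lesions of configurable radius and uptake placed in four
anatomic compartments (prostate/bed, regional node, non-regional node,
osseous).  Spheres with uniform uptake are used deliberately: the
analytic volume 4/3*pi*r^3 is an exact oracle for the segmentation
stage.  Additive Gaussian SUV noise (truncated at zero, since SUV is
non-negative) is optional.

**Cohorts** emulate the statistical structure of a treated
castration-sensitive prostate-cancer population: per-compartment
disease prevalence, log-normal baseline burden, a multiplicative
treatment effect (a point mass at 0 for complete responders mixed with
a log-normal residual), and a serum PSA tied to total tracer-avid
burden by a power law with multiplicative log-normal noise:

    PSA = s * (composite + c0)^beta * exp(sigma * eps),  eps ~ N(0,1)

In the noise-free limit (sigma=0, c0=0, beta=1) the PSA percent change
equals the composite-score percent change exactly, which pins down the
downstream correlation at r = 1 — the identifiability check for the
whole analysis chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import Compartment, Lesion, OrganMaskSet, VoxelGrid
from .scoring import CompartmentScores
from .response import PatientRecord


# --------------------------------------------------------------------------
# Phantom geometry
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LesionSpec:
    """A spherical lesion: centre (mm), radius (mm), uniform SUV, compartment."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    suv: float
    compartment: Compartment

    def __post_init__(self) -> None:
        if self.radius_mm <= 0 or self.suv <= 0:
            raise ValueError("lesion radius and SUV must be positive")

    @property
    def volume_ml(self) -> float:
        """Analytic sphere volume in mL."""
        return 4.0 / 3.0 * np.pi * self.radius_mm**3 / 1000.0


@dataclass(frozen=True)
class PhantomSpec:
    """Phantom recipe: grid geometry, organ plateaus, lesions, noise."""

    grid_shape: tuple[int, int, int] = (48, 48, 64)
    voxel_spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    background_suv: float = 1.0
    liver_suv: float = 5.0
    blood_pool_suv: float = 1.5
    lesions: tuple[LesionSpec, ...] = ()
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("background_suv", "liver_suv", "blood_pool_suv"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        object.__setattr__(self, "lesions", tuple(self.lesions))

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.grid_shape, self.voxel_spacing_mm))


def _coord_grids(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _ball(shape, spacing, center, radius) -> np.ndarray:
    xx, yy, zz = _coord_grids(shape, spacing)
    return (
        (xx - center[0]) ** 2 + (yy - center[1]) ** 2 + (zz - center[2]) ** 2
    ) <= radius**2


def _ellipsoid(shape, spacing, center, radii) -> np.ndarray:
    xx, yy, zz = _coord_grids(shape, spacing)
    return (
        ((xx - center[0]) / radii[0]) ** 2
        + ((yy - center[1]) / radii[1]) ** 2
        + ((zz - center[2]) / radii[2]) ** 2
    ) <= 1.0


def _cylinder_z(shape, spacing, axis_xy, radius, z_range) -> np.ndarray:
    xx, yy, zz = _coord_grids(shape, spacing)
    radial = (xx - axis_xy[0]) ** 2 + (yy - axis_xy[1]) ** 2 <= radius**2
    return radial & (zz >= z_range[0]) & (zz <= z_range[1])


def organ_layout(
    grid_shape: tuple[int, int, int], spacing_mm: tuple[float, float, float]
) -> OrganMaskSet:
    """Stylized whole-body anatomy on the phantom grid.

    The aorta runs along z in the upper 60% of the body with the
    common-iliac bifurcation at its caudal end; the liver sits
    right-lateral and cranial; the prostate/bed is a caudal midline
    sphere; the skeleton is a posterior spine column; the nodal region
    is a periaortic cylinder (minus the other organs) spanning pelvis
    to thorax.
    """
    X, Y, Z = (n * s for n, s in zip(grid_shape, spacing_mm))
    aorta_xy = (0.5 * X, 0.45 * Y)
    bifurcation_z = 0.35 * Z

    liver = _ellipsoid(
        grid_shape, spacing_mm,
        center=(0.28 * X, 0.45 * Y, 0.72 * Z),
        radii=(0.16 * X, 0.14 * Y, 0.12 * Z),
    )
    blood_pool = _cylinder_z(
        grid_shape, spacing_mm, aorta_xy, radius=8.0, z_range=(bifurcation_z, 0.95 * Z)
    )
    liver &= ~blood_pool  # keep organ masks disjoint where the aorta abuts the liver
    prostate_bed = _ball(
        grid_shape, spacing_mm, center=(0.5 * X, 0.5 * Y, 0.10 * Z), radius=8.0
    )
    skeleton = _cylinder_z(
        grid_shape, spacing_mm, (0.5 * X, 0.75 * Y), radius=8.0,
        z_range=(0.02 * Z, 0.98 * Z),
    )
    nodal = _cylinder_z(
        grid_shape, spacing_mm, aorta_xy, radius=30.0, z_range=(0.05 * Z, 0.95 * Z)
    )
    nodal &= ~(liver | blood_pool | prostate_bed | skeleton)
    return OrganMaskSet(
        liver=liver,
        blood_pool=blood_pool,
        prostate_bed=prostate_bed,
        skeleton=skeleton,
        nodal_region=nodal,
        bifurcation_z_mm=bifurcation_z,
    )


def default_lesion_center(
    compartment: Compartment,
    grid_shape: tuple[int, int, int],
    spacing_mm: tuple[float, float, float],
) -> tuple[float, float, float]:
    """A centre (mm) inside the given compartment's region of the layout."""
    X, Y, Z = (n * s for n, s in zip(grid_shape, spacing_mm))
    centers = {
        Compartment.PROSTATE_BED: (0.5 * X, 0.5 * Y, 0.10 * Z),
        Compartment.REGIONAL_NODE: (0.5 * X, 0.45 * Y + 18.0, 0.22 * Z),
        Compartment.NONREGIONAL_NODE: (0.5 * X + 19.0, 0.45 * Y, 0.60 * Z),
        Compartment.OSSEOUS: (0.5 * X, 0.75 * Y, 0.50 * Z),
    }
    return centers[compartment]


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[VoxelGrid, OrganMaskSet, list[Lesion]]:
    """Render a phantom: PET grid, organ masks, and ground-truth lesions.

    Ground-truth lesions carry the analytic sphere volume and nominal
    SUV.  Deterministic for a given spec (including seed).  Raises
    ``ValueError`` for a lesion centred outside the grid or overlapping
    a reference organ.
    """
    shape, spacing = spec.grid_shape, spec.voxel_spacing_mm
    masks = organ_layout(shape, spacing)
    extent = spec.extent_mm

    pet = np.full(shape, spec.background_suv, dtype=float)
    pet[masks.liver] = spec.liver_suv
    pet[masks.blood_pool] = spec.blood_pool_suv

    ground_truth: list[Lesion] = []
    for i, les in enumerate(spec.lesions):
        if not all(0.0 <= c <= e for c, e in zip(les.center_mm, extent)):
            raise ValueError(
                f"lesion {i} centre {les.center_mm} lies outside the grid "
                f"extent {tuple(round(e, 1) for e in extent)} mm"
            )
        mask = _ball(shape, spacing, les.center_mm, les.radius_mm)
        if (mask & (masks.liver | masks.blood_pool)).any():
            raise ValueError(f"lesion {i} overlaps a reference organ (liver/blood pool)")
        pet[mask] = np.maximum(pet[mask], les.suv)
        ground_truth.append(
            Lesion(
                lesion_id=f"GT{i + 1:03d}",
                mask=mask,
                volume_ml=les.volume_ml,
                suv_mean=les.suv,
                suv_max=les.suv,
                compartment=les.compartment,
            )
        )

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        pet = np.clip(pet + rng.normal(0.0, spec.noise_sd, size=shape), 0.0, None)
    return VoxelGrid(pet, spacing), masks, ground_truth


# --------------------------------------------------------------------------
# PSA link and cohort simulation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PsaLinkParams:
    """Power-law PSA/burden link with multiplicative log-normal noise."""

    scale: float = 0.5
    offset: float = 0.5
    exponent: float = 1.0
    noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.offset < 0 or self.noise_sd < 0:
            raise ValueError("offset and noise_sd must be >= 0")


def psa_from_burden(
    composite_score: float, params: PsaLinkParams, noise_draw: float = 0.0
) -> float:
    """PSA = s * (composite + c0)^beta * exp(sigma * noise_draw)."""
    if composite_score < 0:
        raise ValueError(f"composite score must be >= 0, got {composite_score}")
    return float(
        params.scale
        * (composite_score + params.offset) ** params.exponent
        * np.exp(params.noise_sd * noise_draw)
    )


@dataclass(frozen=True)
class TreatmentEffect:
    """Multiplicative residual burden: P(residual=0) = p_complete, else
    log-normal with the given median and log-sd."""

    p_complete: float = 0.55
    residual_median: float = 0.08
    residual_log_sd: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_complete <= 1.0:
            raise ValueError("p_complete must be a probability")
        if self.residual_median <= 0 or self.residual_log_sd < 0:
            raise ValueError("residual_median must be > 0, residual_log_sd >= 0")

    def draw(self, rng: np.random.Generator) -> float:
        if rng.random() < self.p_complete:
            return 0.0
        return float(
            np.exp(np.log(self.residual_median) + self.residual_log_sd * rng.standard_normal())
        )


# Default prevalence and burden follow a 30-patient metastatic CSPC cohort:
# prostate/bed disease in ~90% of patients, regional nodes ~83%,
# non-regional nodes ~30%, bone ~60%; baseline compartment scores are
# log-normal with medians near 21.6 (prostate), 5.3 (nodal, split
# regional/non-regional), 2.2 (osseous) and log-sd 1.2 spanning roughly
# 0.1-150.
_DEFAULT_PREVALENCE = {
    Compartment.PROSTATE_BED: 27 / 30,
    Compartment.REGIONAL_NODE: 25 / 30,
    Compartment.NONREGIONAL_NODE: 9 / 30,
    Compartment.OSSEOUS: 18 / 30,
}
_DEFAULT_BURDEN_MEDIAN = {
    Compartment.PROSTATE_BED: 21.6,
    Compartment.REGIONAL_NODE: 4.0,
    Compartment.NONREGIONAL_NODE: 2.0,
    Compartment.OSSEOUS: 2.2,
}


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a paired baseline/follow-up cohort."""

    n_patients: int = 30
    compartment_prevalence: dict = field(
        default_factory=lambda: dict(_DEFAULT_PREVALENCE)
    )
    burden_median: dict = field(default_factory=lambda: dict(_DEFAULT_BURDEN_MEDIAN))
    burden_log_sd: float = 1.2
    treatment_effect: TreatmentEffect = field(default_factory=TreatmentEffect)
    psa_link: PsaLinkParams = field(default_factory=PsaLinkParams)
    interval_median_months: float = 8.0
    interval_log_sd: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("need n_patients >= 2 (correlation undefined below that)")
        for comp, p in self.compartment_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence for {comp} must be in [0,1], got {p}")


def _pool(values: dict[Compartment, float]) -> CompartmentScores:
    """Pool per-compartment burdens into reporting compartments; zero -> missing."""
    def total(*comps: Compartment) -> float | None:
        present = [values[c] for c in comps if c in values and values[c] > 0]
        return sum(present) if present else None

    return CompartmentScores(
        prostate_bed=total(Compartment.PROSTATE_BED),
        nodal=total(Compartment.REGIONAL_NODE, Compartment.NONREGIONAL_NODE),
        osseous=total(Compartment.OSSEOUS),
    )


def generate_cohort(spec: CohortSpec) -> list[PatientRecord]:
    """Simulate paired scans plus PSA for ``n_patients`` patients.

    Per patient: compartments present per prevalence (patients are
    redrawn until at least one compartment is involved — every study
    patient had scoreable disease), baseline burden log-normal,
    follow-up = baseline x a treatment-effect draw per compartment, and
    PSA at both timepoints from the power-law link.  Deterministic for
    a given spec.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[PatientRecord] = []
    for pid in range(1, spec.n_patients + 1):
        for _ in range(1000):
            present = [
                comp
                for comp, p in spec.compartment_prevalence.items()
                if rng.random() < p
            ]
            if present:
                break
        else:
            raise RuntimeError("could not draw a patient with any disease present")

        baseline: dict[Compartment, float] = {}
        followup: dict[Compartment, float] = {}
        for comp in present:
            b = float(
                np.exp(
                    np.log(spec.burden_median[comp])
                    + spec.burden_log_sd * rng.standard_normal()
                )
            )
            baseline[comp] = b
            followup[comp] = b * spec.treatment_effect.draw(rng)

        scores0 = _pool(baseline)
        scores1 = _pool(followup)
        psa0 = psa_from_burden(scores0.composite, spec.psa_link, rng.standard_normal())
        psa1 = psa_from_burden(scores1.composite, spec.psa_link, rng.standard_normal())
        interval = int(
            np.clip(
                round(
                    float(
                        np.exp(
                            np.log(spec.interval_median_months)
                            + spec.interval_log_sd * rng.standard_normal()
                        )
                    )
                ),
                3,
                30,
            )
        )
        records.append(
            PatientRecord(
                patient_id=str(pid),
                baseline=scores0,
                followup=scores1,
                psa_baseline=psa0,
                psa_followup=psa1,
                interval_months=interval,
            )
        )
    return records
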