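"""Core spatial containers: the PET voxel grid and companion organ masks.

A whole-body PSMA PET scan is represented as a 3D scalar field of
standardized uptake values (SUV) on a regular grid with physical voxel
spacing in millimetres.  Anatomy is supplied as binary masks congruent
with that grid: the two reference organs (liver, blood pool / aorta),
the prostate / prostate bed, the skeleton, and a nodal region, plus the
axial coordinate of the common-iliac bifurcation used to split nodal
disease into regional (at/below the bifurcation) and non-regional
(above) stations.

Physical coordinates are in mm with the origin at the centre of the
first voxel, so voxel index ``i`` along an axis with spacing ``s`` sits
at ``i * s`` mm.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np


class Compartment(str, enum.Enum):
    """Anatomic disease compartments."""

    PROSTATE_BED = "prostate_bed"
    REGIONAL_NODE = "regional_node"
    NONREGIONAL_NODE = "nonregional_node"
    OSSEOUS = "osseous"

    def pooled(self) -> str:
        """Reporting compartment: regional and non-regional nodes pool to 'nodal'."""
        if self in (Compartment.REGIONAL_NODE, Compartment.NONREGIONAL_NODE):
            return "nodal"
        return self.value


#: Column order used for per-compartment score tables.
POOLED_COMPARTMENTS = ("prostate_bed", "nodal", "osseous")


@dataclass
class VoxelGrid:
    """A 3D field of SUV values with physical voxel spacing.

    Parameters
    ----------
    values
        3D array of non-negative SUV values (unitless).
    spacing_mm
        Voxel spacing along each axis, mm; all components positive.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"PET values must be 3D, got ndim={self.values.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be 3 positive reals, got {self.spacing_mm}")
        if np.any(self.values < 0):
            raise ValueError("SUV values must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (mm^3 / 1000)."""
        return float(np.prod(self.spacing_mm)) / 1000.0

    def coords_mm(self, index: tuple[int, int, int]) -> tuple[float, float, float]:
        """Physical coordinates (mm) of a voxel index, origin at first voxel centre."""
        return tuple(i * s for i, s in zip(index, self.spacing_mm))


@dataclass
class OrganMaskSet:
    """Binary organ/region masks on the PET grid.

    ``bifurcation_z_mm`` is the axial (last-axis) physical coordinate of
    the common-iliac bifurcation plane; nodal lesions with centroid
    strictly above it are classified non-regional.
    """

    liver: np.ndarray
    blood_pool: np.ndarray
    prostate_bed: np.ndarray
    skeleton: np.ndarray
    nodal_region: np.ndarray
    bifurcation_z_mm: float = 0.0

    _MASK_NAMES = ("liver", "blood_pool", "prostate_bed", "skeleton", "nodal_region")

    def __post_init__(self) -> None:
        shapes = set()
        for name in self._MASK_NAMES:
            mask = np.asarray(getattr(self, name), dtype=bool)
            setattr(self, name, mask)
            shapes.add(mask.shape)
        if len(shapes) != 1:
            raise ValueError(f"organ masks have inconsistent shapes: {shapes}")
        self.bifurcation_z_mm = float(self.bifurcation_z_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.liver.shape  # type: ignore[return-value]

    def check_congruent(self, grid: VoxelGrid) -> None:
        if self.shape != grid.shape:
            raise ValueError(
                f"mask shape {self.shape} does not match grid shape {grid.shape}"
            )

    def as_label_volume(self, labels: dict[str, int]) -> np.ndarray:
        """Collapse the masks into one integer label volume (later labels win)."""
        out = np.zeros(self.shape, dtype=np.int16)
        for name in self._MASK_NAMES:
            out[getattr(self, name)] = labels[name]
        return out

    @classmethod
    def from_label_volume(
        cls, volume: np.ndarray, labels: dict[str, int], bifurcation_z_mm: float
    ) -> "OrganMaskSet":
        return cls(
            **{name: volume == labels[name] for name in cls._MASK_NAMES},
            bifurcation_z_mm=bifurcation_z_mm,
        )


@dataclass
class Lesion:
    """A segmented tracer-avid hot spot.

    ``mask`` is a boolean voxel mask on the PET grid (one 26-connected
    component); ``volume_ml`` is voxel count x voxel volume for
    segmented lesions, or the analytic sphere volume for synthetic
    ground truth.  ``psma_score`` is filled in by the scoring stage.
    """

    lesion_id: str
    mask: np.ndarray
    volume_ml: float
    suv_mean: float
    suv_max: float
    compartment: Compartment | None = None
    accepted: bool = True
    psma_score: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.suv_mean > self.suv_max + 1e-9:
            raise ValueError(
                f"lesion {self.lesion_id}: suv_mean {self.suv_mean} > suv_max {self.suv_max}"
            )

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    def centroid_mm(self, grid: VoxelGrid) -> tuple[float, float, float]:
        idx = np.argwhere(self.mask)
        if idx.size == 0:
            raise ValueError(f"lesion {self.lesion_id} has an empty mask")
        centre = idx.mean(axis=0)
        return tuple(float(c * s) for c, s in zip(centre, grid.spacing_mm))
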