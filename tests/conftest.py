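import numpy as np
import pytest

import psmascore as ps
from psmascore import Compartment

SHAPE = (48, 48, 64)
SPACING = (2.0, 2.0, 2.0)


def make_lesion_spec(compartment, radius_mm=8.0, suv=8.0, center=None):
    center = center or ps.default_lesion_center(compartment, SHAPE, SPACING)
    return ps.LesionSpec(center_mm=center, radius_mm=radius_mm, suv=suv,
                         compartment=compartment)


@pytest.fixture(scope="session")
def four_lesion_phantom():
    """Noise-free phantom with one 8 mm SUV-8 sphere per compartment."""
    spec = ps.PhantomSpec(
        grid_shape=SHAPE,
        voxel_spacing_mm=SPACING,
        lesions=tuple(make_lesion_spec(c) for c in Compartment),
    )
    pet, masks, truth = ps.generate_phantom(spec)
    ref = ps.compute_reference_uptake(pet, masks)
    return spec, pet, masks, truth, ref


@pytest.fixture(scope="session")
def response_fixture():
    """The packaged per-patient response table."""
    return ps.load_response_table()


@pytest.fixture(scope="session")
def patient_fixture():
    return ps.load_patient_table()


@pytest.fixture()
def simple_lesion():
    """A hand-built lesion detached from any grid: 2 mL at SUVmean 4."""
    mask = np.zeros((4, 4, 4), dtype=bool)
    mask[1:3, 1:3, 1] = True
    return ps.Lesion(lesion_id="X", mask=mask, volume_ml=2.0, suv_mean=4.0, suv_max=5.0)
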