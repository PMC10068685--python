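"""Synthetic phantoms and cohorts: geometry oracles, the PSA link, and
determinism."""

import io as stdio

import numpy as np
import pytest

import psmascore as ps
from psmascore import Compartment
from psmascore.io import write_cohort_csv

from conftest import SHAPE, SPACING, make_lesion_spec


class TestPhantom:
    def test_empty_phantom_is_pure_background(self):
        pet, masks, truth = ps.generate_phantom(
            ps.PhantomSpec(grid_shape=SHAPE, voxel_spacing_mm=SPACING)
        )
        assert truth == []
        outside = ~(masks.liver | masks.blood_pool)
        assert pet.values[outside].max() == pytest.approx(1.0)
        assert pet.values[masks.liver].min() == pytest.approx(5.0)
        assert pet.values[masks.blood_pool].min() == pytest.approx(1.5)

    def test_sphere_volume_matches_analytic(self):
        spec = make_lesion_spec(Compartment.OSSEOUS, radius_mm=10.0)
        assert spec.volume_ml == pytest.approx(4.0 / 3.0 * np.pi, rel=1e-12)  # 4.18879 mL
        pet, _, truth = ps.generate_phantom(
            ps.PhantomSpec(grid_shape=SHAPE, voxel_spacing_mm=SPACING, lesions=(spec,))
        )
        voxelized_ml = truth[0].voxel_count * pet.voxel_volume_ml
        assert truth[0].volume_ml == pytest.approx(4.18879, abs=1e-4)
        assert voxelized_ml == pytest.approx(truth[0].volume_ml, rel=0.15)

    def test_deterministic_without_noise_regardless_of_seed(self):
        a = ps.generate_phantom(ps.PhantomSpec(seed=1))[0]
        b = ps.generate_phantom(ps.PhantomSpec(seed=99))[0]
        np.testing.assert_array_equal(a.values, b.values)

    def test_noise_deterministic_given_seed(self):
        spec = lambda s: ps.PhantomSpec(noise_sd=0.2, seed=s)  # noqa: E731
        a, b, c = (ps.generate_phantom(spec(s))[0] for s in (7, 7, 8))
        np.testing.assert_array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)
        assert a.values.min() >= 0  # truncation: SUV stays non-negative

    def test_lesion_outside_grid_rejected_with_index(self):
        bad = ps.LesionSpec((1e4, 10, 10), 5.0, 8.0, Compartment.OSSEOUS)
        with pytest.raises(ValueError, match="lesion 0"):
            ps.generate_phantom(ps.PhantomSpec(lesions=(bad,)))

    def test_lesion_overlapping_reference_organ_rejected(self):
        # dead centre of the liver
        X, Y, Z = (n * s for n, s in zip(SHAPE, SPACING))
        bad = ps.LesionSpec((0.28 * X, 0.45 * Y, 0.72 * Z), 6.0, 8.0, Compartment.OSSEOUS)
        with pytest.raises(ValueError, match="reference organ"):
            ps.generate_phantom(
                ps.PhantomSpec(grid_shape=SHAPE, voxel_spacing_mm=SPACING, lesions=(bad,))
            )

    def test_ground_truth_suv_recovered_under_noise(self):
        spec = ps.PhantomSpec(
            grid_shape=SHAPE, voxel_spacing_mm=SPACING,
            lesions=(make_lesion_spec(Compartment.OSSEOUS),), noise_sd=0.3, seed=5,
        )
        pet, _, truth = ps.generate_phantom(spec)
        measured = pet.values[truth[0].mask].mean()
        assert measured == pytest.approx(8.0, abs=0.3)


class TestPsaLink:
    def test_closed_forms(self):
        p = ps.PsaLinkParams(scale=2.0, offset=1.0, exponent=1.0, noise_sd=0.0)
        assert ps.psa_from_burden(0.0, p) == pytest.approx(2.0)
        p2 = ps.PsaLinkParams(scale=3.0, offset=0.0, exponent=2.0, noise_sd=0.0)
        # halving the burden under beta=2 quarters the PSA
        assert ps.psa_from_burden(2.0, p2) / ps.psa_from_burden(4.0, p2) == pytest.approx(0.25)

    def test_percent_change_identity_when_linear(self):
        p = ps.PsaLinkParams(scale=0.7, offset=0.0, exponent=1.0, noise_sd=0.0)
        b0, b1 = 12.0, 3.0
        psa_change = ps.percent_change(ps.psa_from_burden(b0, p), ps.psa_from_burden(b1, p))
        assert psa_change == pytest.approx(ps.percent_change(b0, b1))

    def test_negative_burden_rejected(self):
        with pytest.raises(ValueError):
            ps.psa_from_burden(-1.0, ps.PsaLinkParams())

    def test_monotone_in_burden(self):
        p = ps.PsaLinkParams(scale=1.0, offset=0.5, exponent=1.3, noise_sd=0.0)
        vals = [ps.psa_from_burden(b, p) for b in np.linspace(0, 50, 20)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestCohort:
    def test_zero_prevalence_compartment_always_missing(self):
        prev = {
            Compartment.PROSTATE_BED: 1.0,
            Compartment.REGIONAL_NODE: 0.0,
            Compartment.NONREGIONAL_NODE: 0.0,
            Compartment.OSSEOUS: 0.5,
        }
        recs = ps.generate_cohort(ps.CohortSpec(n_patients=25, compartment_prevalence=prev, seed=4))
        table = ps.build_cohort_table(recs)
        assert table.df["nodal_pct"].isna().all()
        assert not table.df["prostate_pct"].isna().any()

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError, match="n_patients"):
            ps.CohortSpec(n_patients=1)

    def test_serialized_cohort_is_byte_deterministic(self):
        def dump(seed):
            buf = stdio.StringIO()
            write_cohort_csv(ps.generate_cohort(ps.CohortSpec(n_patients=15, seed=seed)), buf)
            return buf.getvalue()

        assert dump(11) == dump(11)
        assert dump(11) != dump(12)

    def test_beta_recovered_by_log_log_regression(self):
        link = ps.PsaLinkParams(scale=0.5, offset=0.5, exponent=1.0, noise_sd=0.1)
        recs = ps.generate_cohort(ps.CohortSpec(n_patients=200, psa_link=link, seed=2))
        x = np.log([r.baseline.composite + link.offset for r in recs])
        y = np.log([r.psa_baseline for r in recs])
        beta = np.polyfit(x, y, 1)[0]
        assert beta == pytest.approx(1.0, abs=0.1)
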