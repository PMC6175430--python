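"""Particle conversion and one-point stoichiometric calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nfstoich.calibration import (
    DEFAULT_ISOFORM_SPECS,
    CalibrationFactors,
    ParticleProfile,
    StoichCalibrator,
    apply_calibration,
    calibration_factors,
    cohort_stoichiometry,
    combine_nfh,
    density_summary,
    profiles_from_records,
    to_molarity,
    to_particles,
)
from nfstoich.cohort import ASSAYS, CohortConfig, generate_cohort

NFL = DEFAULT_ISOFORM_SPECS["NfL"]


def make_profiles(counts_list, calibrated=False):
    return [
        ParticleProfile(f"s{i}", {"NfL": c[0], "NfM": c[1], "NfH": c[2]},
                        calibrated=calibrated)
        for i, c in enumerate(counts_list)
    ]


class TestConversion:
    @pytest.mark.parametrize("conc,expected", [
        (0.0, 0.0),
        (68_000.0, 1.0),
        (6.8e-11, 1.0e-15),
    ])
    def test_to_molarity(self, conc, expected):
        assert to_molarity(conc, NFL) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("mol,expected", [
        (0.0, 0.0),
        (1.0, 6.0221415e23),
        (1.0e-15, 6.0221415e8),
    ])
    def test_to_particles(self, mol, expected):
        assert to_particles(mol) == pytest.approx(expected, rel=1e-12)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            to_molarity(-1.0, NFL)

    @given(st.floats(min_value=0, max_value=1e3), st.floats(min_value=1e-12, max_value=1.0))
    @settings(derandomize=True, max_examples=50)
    def test_conversion_linearity(self, alpha, conc):
        base = to_particles(to_molarity(conc, NFL))
        scaled = to_particles(to_molarity(alpha * conc, NFL))
        assert scaled == pytest.approx(alpha * base, rel=1e-9, abs=1e-12)

    @pytest.mark.parametrize("smi35,smi34,mode,expected", [
        (3.0, 2.0, "sum", 5.0),
        (3.0, 2.0, "smi35_only", 3.0),
        (3.0, 2.0, "smi34_only", 2.0),
        (0.0, 0.0, "sum", 0.0),
    ])
    def test_combine_nfh(self, smi35, smi34, mode, expected):
        assert combine_nfh(smi35, smi34, mode) == expected

    def test_combine_nfh_missing(self):
        with pytest.raises(ValueError):
            combine_nfh(None, None, "sum")


class TestCalibration:
    def test_factors_from_medians(self):
        profiles = make_profiles([(14e8, 3e8, 1e8)] * 3)
        f = calibration_factors(profiles)
        assert f.x == pytest.approx(5e-9)
        assert f.y == pytest.approx(1e-8)
        assert f.z == pytest.approx(2e-8)

    def test_factors_identity_at_target(self):
        f = calibration_factors(make_profiles([(7, 3, 2)] * 3))
        assert (f.x, f.y, f.z) == pytest.approx((1, 1, 1))

    def test_apply_calibration(self):
        f = CalibrationFactors(5e-9, 1e-8, 2e-8)
        p = apply_calibration(make_profiles([(14e8, 3e8, 1e8)])[0], f)
        assert p.calibrated
        assert p.as_array() == pytest.approx([7, 3, 2])

    def test_double_calibration_rejected(self):
        f = CalibrationFactors(1, 1, 1)
        p = apply_calibration(make_profiles([(1, 1, 1)])[0], f)
        with pytest.raises(ValueError):
            apply_calibration(p, f)

    def test_zero_median_rejected(self):
        with pytest.raises(ValueError):
            calibration_factors(make_profiles([(0, 1, 1)] * 3))

    def test_too_few_controls_rejected(self):
        with pytest.raises(ValueError):
            calibration_factors(make_profiles([(1, 1, 1)] * 2))

    def test_control_medians_hit_target_exactly(self, calibrated_cohort):
        ctrl = [p for p in calibrated_cohort if p.group == "control"]
        assert cohort_stoichiometry(ctrl) == pytest.approx((7, 3, 2), rel=1e-12)

    def test_recalibration_yields_unit_factors(self, calibrated_cohort):
        ctrl = [p for p in calibrated_cohort if p.group == "control"]
        f = calibration_factors(ctrl)
        assert (f.x, f.y, f.z) == pytest.approx((1, 1, 1), rel=1e-12)

    def test_single_profile_median_is_itself(self):
        p = make_profiles([(24, 2.4, 1.6)], calibrated=True)
        assert cohort_stoichiometry(p) == pytest.approx((24, 2.4, 1.6))

    def test_uncalibrated_cohort_rejected(self):
        with pytest.raises(ValueError):
            cohort_stoichiometry(make_profiles([(1, 1, 1)]))

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            cohort_stoichiometry([])

    @given(st.floats(min_value=1e-3, max_value=1e3))
    @settings(derandomize=True, max_examples=20, deadline=None)
    def test_assay_scale_invariance(self, alpha):
        """Rescaling one assay's raw output cancels out after calibration."""
        records = generate_cohort(CohortConfig(seed=11, n_control=9, n_als=9))

        def stoich(scale):
            profs = []
            for r in records:
                conc = dict(r.conc)
                conc["NfM"] *= scale
                profs.append(conc)
            from nfstoich.calibration import profile_from_concentrations

            profiles = [
                profile_from_concentrations(rec.subject_id, c, group=rec.group)
                for rec, c in zip(records, profs)
            ]
            ctrl = [p for p in profiles if p.group == "control"]
            cal = StoichCalibrator().fit(ctrl).apply_cohort(profiles)
            return np.array(
                cohort_stoichiometry([p for p in cal if p.group == "ALS"])
            )

        assert stoich(alpha) == pytest.approx(stoich(1.0), rel=1e-9)

    def test_unfitted_calibrator_rejected(self):
        with pytest.raises(RuntimeError):
            StoichCalibrator().apply(make_profiles([(1, 1, 1)])[0])


class TestDensitySummary:
    def test_normalisation(self):
        rng = np.random.default_rng(0)
        grid = density_summary(rng.lognormal(0, 0.5, 500))
        integral = np.trapezoid(grid[:, 1], grid[:, 0])
        assert 0.99 <= integral <= 1.01
        assert np.all(grid[:, 1] >= 0)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 200)
        g0 = density_summary(x)
        g1 = density_summary(x + 5.0)
        assert g1[:, 0] == pytest.approx(g0[:, 0] + 5.0, abs=1e-9)
        assert g1[:, 1] == pytest.approx(g0[:, 1], abs=1e-12)

    def test_large_sample_mode_near_zero(self):
        rng = np.random.default_rng(2)
        grid = density_summary(rng.standard_normal(10_000))
        mode = grid[np.argmax(grid[:, 1]), 0]
        assert abs(mode) < 0.1

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            density_summary([1.0])


def test_nfh_mode_changes_channel(default_records):
    p35 = profiles_from_records(default_records, nfh_mode="smi35_only")
    psum = profiles_from_records(default_records, nfh_mode="sum")
    assert all(
        b.counts["NfH"] >= a.counts["NfH"] for a, b in zip(p35, psum)
    )
    assert any(b.counts["NfH"] > a.counts["NfH"] for a, b in zip(p35, psum))
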