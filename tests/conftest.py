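import numpy as np
import pytest

from nfstoich import CohortConfig, StoichCalibrator, generate_cohort
from nfstoich.calibration import profiles_from_records


@pytest.fixture(scope="session")
def default_records():
    return generate_cohort(CohortConfig(seed=7))


@pytest.fixture(scope="session")
def calibrated_cohort(default_records):
    profiles = profiles_from_records(default_records)
    controls = [p for p in profiles if p.group == "control"]
    return StoichCalibrator().fit(controls).apply_cohort(profiles)


def recover_stoichiometries(seed: int):
    """Full convert -> calibrate -> median pipeline on one synthetic cohort."""
    from nfstoich import cohort_stoichiometry

    profiles = profiles_from_records(generate_cohort(CohortConfig(seed=seed)))
    controls = [p for p in profiles if p.group == "control"]
    calibrated = StoichCalibrator().fit(controls).apply_cohort(profiles)
    ctrl = cohort_stoichiometry([p for p in calibrated if p.group == "control"])
    als = cohort_stoichiometry([p for p in calibrated if p.group == "ALS"])
    return np.array(ctrl), np.array(als)
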