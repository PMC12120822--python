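import pytest

from lipidims.calibration import align_rt, calibrate_cohort
from lipidims.cohort import (
    CohortDesign,
    GenerativeModel,
    reference_ccs_table,
    simulate,
)

DEFAULT_SEED = 1


def zero_noise_model(**overrides) -> GenerativeModel:
    """Generator with all noise and distortions switched off."""
    params = dict(
        rt_noise_sd=0.0,
        mz_noise_ppm=0.0,
        ccs_noise_sd=0.0,
        ccs_scale_range=(1.0, 1.0),
        ccs_offset_range=(0.0, 0.0),
        rt_scale_range=(1.0, 1.0),
        rt_offset_range=(0.0, 0.0),
        intensity_log_sd=0.0,
    )
    params.update(overrides)
    return GenerativeModel(**params)


@pytest.fixture(scope="session")
def default_design():
    return CohortDesign(seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def default_model():
    return GenerativeModel()


@pytest.fixture(scope="session")
def default_sim(default_design, default_model):
    return simulate(default_design, default_model)


@pytest.fixture(scope="session")
def default_reference(default_design, default_model):
    return reference_ccs_table(default_design, default_model)


@pytest.fixture(scope="session")
def calibrated_cohort(default_sim, default_reference):
    calibrated, models = calibrate_cohort(default_sim.features, default_reference)
    return calibrated, models


@pytest.fixture(scope="session")
def aligned_cohort(calibrated_cohort):
    aligned, alignments = align_rt(calibrated_cohort[0])
    return aligned, alignments


@pytest.fixture(scope="session")
def zero_noise_sim(default_design):
    return simulate(default_design, zero_noise_model())


@pytest.fixture(scope="session")
def zero_noise_calibrated(zero_noise_sim, default_design):
    reference = reference_ccs_table(default_design, zero_noise_model())
    calibrated, _ = calibrate_cohort(zero_noise_sim.features, reference)
    aligned, _ = align_rt(calibrated)
    return aligned
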