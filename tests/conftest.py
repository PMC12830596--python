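import numpy as np
import pytest

from mitovar import CohortDesign, ControlLine, DeficiencyModel, Disparity, generate_cohort


def clean_design(**overrides):
    """Small design with no batch effects or disparity: intensities sit on
    the control line, so classifier behaviour is analytically predictable."""
    kwargs = dict(
        n_patients=1,
        biopsies_per_muscle=2,
        fibres_per_section=100,
        control_fibres=300,
        section_gain_sd=0.0,
        section_offset_sd=0.0,
        patient_disparity={"NDUFB8": Disparity(), "MT-CO1": Disparity()},
        deficiency=DeficiencyModel(
            mean_proportion={"NDUFB8": 0.30, "MT-CO1": 0.10},
            muscle_offset={"QD": 0.0, "TA": 0.0},
            spatial_drift_sd=0.0,
        ),
        deficient_shift=10.0,
        overabundance_rate=0.0,
        seed=11,
    )
    kwargs.update(overrides)
    return CohortDesign(**kwargs)


@pytest.fixture(scope="session")
def clean_cohort():
    return generate_cohort(clean_design())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
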