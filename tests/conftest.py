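import pytest

from emrforge.pipeline import run_pipeline
from emrforge.synthgen import SynthConfig, make_fixture_crosswalks


@pytest.fixture(scope="session")
def fixture_xwalks():
    """(icd10→icd9, icd9→ccs) fixture crosswalks with planted routes."""
    return make_fixture_crosswalks()


@pytest.fixture(scope="session")
def small_cfg():
    """Small but fully featured generator configuration."""
    return SynthConfig(
        n_patients=300,
        seed=11,
        n_young_patients=3,
        underage_visits_per_patient=2,
        n_prewindow_inpatient=4,
        n_no_pd_patients=5,
        n_birth1900_patients=3,
        n_invalid_male_patients=4,
    )


@pytest.fixture(scope="session")
def small_run(small_cfg):
    """Full pipeline artifacts on the small synthetic cohort."""
    return run_pipeline(small_cfg, run_validation_stage=False)


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline on generator defaults (5000 patients), incl. validation."""
    return run_pipeline(SynthConfig(), run_validation_stage=True)
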