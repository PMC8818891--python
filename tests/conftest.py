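import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from rwgscea import synthetic_data
from rwgscea.io import run_from_frames


@pytest.fixture(scope="session")
def study_fixture():
    """The packaged 38-proband study cohort."""
    return synthetic_data.paper_fixture()


@pytest.fixture(scope="session")
def study_result(study_fixture):
    """Full pipeline run on the packaged cohort: (CeaResult, report)."""
    fx = study_fixture
    return run_from_frames(
        fx.cohort, fx.ledger, fx.responses, fx.qaly_components, fx.sequencing
    )
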