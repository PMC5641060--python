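import pytest

from lncscna.pipeline import PipelineConfig, analyze_cohort
from lncscna.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort (seed 1), shared across the suite."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def results(cohort):
    """Full in-memory analysis of the shared cohort."""
    return analyze_cohort(cohort, PipelineConfig(seed=1))
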