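import numpy as np
import pytest

from pauselimit import PipelineConfig, generate_cohort, run_pipeline


@pytest.fixture(scope="session")
def recovery_run():
    """200-TU cohort at default study conditions, analyzed end-to-end.

    Shared by the parameter-recovery and directional-response tests."""
    cohort = generate_cohort(n_tus=200, seed=101)
    result = run_pipeline(cohort, PipelineConfig())
    return cohort, result


@pytest.fixture(scope="session")
def limit_run():
    """Larger cohort of velocity-eligible TUs (>35 kbp) for the
    pause-initiation-limit contrast, where the shuffled-null correlation
    bound needs several hundred TUs with d-hat estimates."""
    cohort = generate_cohort(n_tus=800, seed=202, length_range=(35_000, 200_000))
    result = run_pipeline(cohort, PipelineConfig())
    return cohort, result


@pytest.fixture(scope="session")
def small_run():
    """40-TU cohort for fast structural/pipeline tests."""
    cohort = generate_cohort(n_tus=40, seed=3)
    result = run_pipeline(cohort, PipelineConfig())
    return cohort, result


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
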