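import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20210210)


@pytest.fixture(scope="session")
def planted_workflow():
    """One full workflow run on a planted-enrichment fixture, shared by the
    pipeline tests (the run is deterministic and moderately expensive)."""
    from ocrenrich.pipeline import AnalysisConfig, run_workflow

    cfg = AnalysisConfig.scaled_synthetic(seed=5, effect=0.5)
    report, study = run_workflow(cfg)
    return cfg, report, study
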