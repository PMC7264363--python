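import pytest
from hypothesis import HealthCheck, settings

from surftopo.core import PipelineConfig
from surftopo.pipeline import run_pipeline
from surftopo.simulate import SimulationParams, simulate_study

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_study():
    """A 60-protein study under default (noisy) conditions."""
    return simulate_study(SimulationParams(n_proteins=60, seed=7))


@pytest.fixture(scope="session")
def clean_study():
    """The clean parameter-recovery regime: no contamination, complete
    labelling, mean support 5, 200 proteins."""
    params = SimulationParams(
        n_proteins=200,
        contamination_rate=0.0,
        label_efficiency=1.0,
        support_mean=5.0,
    )
    return simulate_study(params, seed=1)


@pytest.fixture(scope="session")
def clean_result(clean_study):
    config = PipelineConfig()
    result = run_pipeline(
        clean_study.proteins,
        clean_study.observations,
        config,
        reference_proteome=clean_study.reference_proteome(),
    )
    return config, result
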