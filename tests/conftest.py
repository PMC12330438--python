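import pytest

from svsieve.pipeline import RunConfig, run_pipeline
from svsieve.sim import SimulationConfig, simulate_cohort
from svsieve.types import ALIGNER_A, ALIGNER_B, ASSEMBLY, MergeParams


def perfect_config(seed: int = 3, **overrides) -> SimulationConfig:
    """Small error-free cohort: every caller sees every SV, no jittered
    sequences diverge, no genotype errors."""
    kwargs = dict(
        seed=seed,
        n_common_sv=500,
        n_controls=30,
        genotype_error_rate=0.0,
        seq_divergence=0.0,
        caller_sensitivity={ASSEMBLY: 1.0, ALIGNER_A: 1.0, ALIGNER_B: 1.0},
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def perfect_cohort():
    return simulate_cohort(perfect_config())


@pytest.fixture(scope="session")
def perfect_run():
    return run_pipeline(RunConfig(simulation=perfect_config()))


@pytest.fixture(scope="session")
def noisy_run():
    """Default (imperfect) study conditions at reduced scale."""
    return run_pipeline(RunConfig(simulation=SimulationConfig(
        seed=11, n_common_sv=400, n_controls=40)))


@pytest.fixture
def params():
    return MergeParams()
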