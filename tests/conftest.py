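import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")

from lctrace.simulate import (
    StudyDesign,
    default_panel,
    generate_feature_table,
    generate_raw_run,
)


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def standard_experiment():
    """The standard synthetic labeling time course (seed 7, CV 10%)."""
    design = StudyDesign(seed=7)
    return generate_feature_table(design, noise_cv=0.1, n_decoys=5, seed=7)


@pytest.fixture(scope="session")
def standard_raw_run(panel):
    """One raw centroided run at labeled fraction 0.5."""
    run, truth = generate_raw_run(panel, labeled_fractions=0.5,
                                  noise_cv=0.05, seed=3)
    return run, truth
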