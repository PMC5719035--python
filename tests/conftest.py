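import numpy as np
import pytest

from gpmap.synthetic import default_series, sample_landmarks


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_101)


@pytest.fixture(scope="session")
def small_series():
    """A reduced-size default series (faster GPA) with its landmark data."""
    series = default_series(seed=7, n_scale=0.4)
    configs, truth = sample_landmarks(series)
    return series, configs, truth


@pytest.fixture(scope="session")
def full_series_run():
    """One full-size simulated series pushed through the whole pipeline."""
    from gpmap import PipelineConfig, run_pipeline

    cfg = PipelineConfig(seed=1, series=default_series(), n_permutations=499)
    return run_pipeline(cfg)
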