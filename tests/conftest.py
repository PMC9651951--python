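import warnings

import numpy as np
import pytest

from timecells.synthgen import GeneratorConfig, generate_population

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_population():
    """A small but complete population: time cells + distractors + interneurons."""
    cfg = GeneratorConfig(n_time_cells=12, n_distractor_cells=4,
                          n_interneurons=2, trials_per_cell=30, seed=11)
    return generate_population(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
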