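import sys
from functools import lru_cache
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make _oracles importable

from emgstress.evaluate import prepare_windows
from emgstress.synth import GeneratorConfig, generate_cohort, micro_config


@lru_cache(maxsize=5)
def prepared_cohort(seed: int, n_subjects: int = 3):
    """Filtered + windowed default-condition cohort, cached across tests.

    float32 window storage keeps five cached cohorts within memory while
    leaving classifier inputs unchanged beyond ~1e-7 rounding.
    """
    cfg = GeneratorConfig(n_subjects=n_subjects, seed=seed)
    return prepare_windows(generate_cohort(cfg), dtype=np.float32)


@lru_cache(maxsize=2)
def prepared_micro(seed: int = 0):
    """Small 2-subject, 4-gesture cohort for fast protocol tests."""
    cfg = micro_config(seed=seed)
    return prepare_windows(generate_cohort(cfg))


@pytest.fixture(scope="session")
def micro_cohort():
    return generate_cohort(micro_config(seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
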