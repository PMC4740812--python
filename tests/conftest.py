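import numpy as np
import pytest

from tbpnoise.promoter_mc import PromoterParams
from tbpnoise.synthetic_data import GeneratorConfig


@pytest.fixture(scope="session")
def small_config():
    """A small but structurally complete generator configuration."""
    return GeneratorConfig(seed=7, n_genes=200, n_events=2000)


@pytest.fixture(scope="session")
def default_config():
    """The study-condition defaults (2,000 genes, 20,000 events)."""
    return GeneratorConfig(seed=11)


def random_params(rng: np.random.Generator, max_residence: float = 30.0):
    """A random valid PromoterParams draw (used by sampler/oracle checks)."""
    a = rng.uniform(0.05, 0.9)
    p_d = rng.uniform(0.0, 1.0 - a)
    p_e = rng.uniform(0.1, 0.95)
    t_off = rng.uniform(0.0, 1.0 - p_e)
    return PromoterParams(
        affinity=a,
        tfiid_recruit=p_d,
        engage=p_e,
        competition=rng.uniform(0.0, 1.0),
        t_off=t_off,
        residence_m=rng.uniform(1.0, max_residence),
        residence_s=rng.uniform(1.0, max_residence),
        residence_d=rng.uniform(1.0, max_residence),
        burst_s=5.0,
        burst_d=1.0,
    )
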