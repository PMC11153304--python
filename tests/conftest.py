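import numpy as np
import pandas as pd
import pytest

from coda24.cohort import StratumConfig, default_config, generate_cohort
from coda24.markers import build_outcomes


def small_config(n_ngm=300, n_igm=120, n_t2d=180):
    """Scaled-down synthetic cohort for fast unit tests."""
    cfg = default_config()
    cfg.strata = {
        name: StratumConfig(**{**s.__dict__, "n": n})
        for (name, s), n in zip(cfg.strata.items(), (n_ngm, n_igm, n_t2d))
    }
    return cfg


@pytest.fixture(scope="session")
def cohort():
    """Default-size synthetic cohort (2388 participants), seed 7."""
    table, truth = generate_cohort(seed=7)
    return table, truth


@pytest.fixture(scope="session")
def small_cohort():
    table, truth = generate_cohort(small_config(), seed=11)
    return table, truth


@pytest.fixture(scope="session")
def fitted_small(small_cohort):
    """Small cohort with z-scored outcome columns appended."""
    table, truth = small_cohort
    table = table.copy()
    z, scaler = build_outcomes(table)
    for o in z.columns:
        table[o] = z[o]
    return table, truth, scaler


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def random_composition(rng, n=1):
    """Random positive 5-part compositions closed to 1440."""
    from coda24.composition import close

    x = rng.lognormal(mean=np.log([540, 250, 60, 50, 480]), sigma=0.3, size=(n, 5))
    out = close(x)
    return out[0] if n == 1 else out
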