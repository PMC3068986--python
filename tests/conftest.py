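import numpy as np
import pandas as pd
import pytest

from crossr2 import SurvivalDataset


@pytest.fixture
def worked_dataset() -> SurvivalDataset:
    """Three subjects, all failing at distinct times, marker (1, 0, 0).

    Small enough that every risk-set quantity is hand-computable:
    risk-set means (1/3, 0, 0), unit-weight scores U = (2/3, 0, 0),
    robust scores W = (4/9, 1/9, 1/9), proportional index 2/3.
    """
    return SurvivalDataset(
        np.array([1.0, 2.0, 3.0]),
        np.array([1, 1, 1]),
        pd.DataFrame({"z": [1.0, 0.0, 0.0]}),
    )


def random_dataset(
    rng: np.random.Generator,
    n_range=(50, 500),
    censoring=(0.0, 0.5),
    allow_ties: bool = True,
    allow_constant: bool = False,
) -> SurvivalDataset:
    """A random survival dataset spanning the study conditions.

    Sample sizes, covariate laws and censoring fractions cover the
    simulation grid of the study (n in [50, 500], Bernoulli(0.5) /
    log-normal / uniform covariates standardised to variance 1/4, effect
    sizes up to e^beta = 4, censoring up to 50%); ties are induced by
    rounding times to a coarse grid, and constant markers can be mixed in.
    """
    n = int(rng.integers(*n_range))
    kind = rng.integers(0, 4 if allow_constant else 3)
    z = [
        rng.integers(0, 2, n).astype(float),
        (np.exp(0.5 * rng.standard_normal(n)) - np.exp(0.125))
        * np.sqrt(0.25 / ((np.e**0.25 - 1) * np.e**0.25)),
        rng.uniform(-np.sqrt(0.75), np.sqrt(0.75), n),
        np.full(n, 1.7),
    ][kind]
    beta = rng.uniform(-np.log(4), np.log(4))
    x = rng.exponential(1.0, n) * np.exp(-beta * z)
    pc = rng.uniform(*censoring)
    if pc > 0:
        # Exp(rate) censoring of Exp(1)-scale events: P(cens) ~ rate/(1+rate)
        c = rng.exponential((1.0 - pc) / pc, n)
    else:
        c = np.full(n, np.inf)
    t = np.minimum(x, c)
    e = (x <= c).astype(int)
    if allow_ties and rng.random() < 0.5:
        t = np.ceil(t * 8) / 8.0
    if e.sum() == 0:
        e[int(rng.integers(0, n))] = 1
    return SurvivalDataset(t, e, pd.DataFrame({"z": z}))
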