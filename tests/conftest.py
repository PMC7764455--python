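import numpy as np
import pandas as pd
import pytest

from ffqopt.datasets import esfffq
from ffqopt.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def qdef():
    return esfffq()


@pytest.fixture(scope="session")
def vegetable(qdef):
    return qdef.target("vegetable")


@pytest.fixture(scope="session")
def small_cohort():
    """A 120-respondent, 10-item cohort with two planted redundant pairs and
    two nutrient targets; used by benchmark- and pipeline-level tests."""
    items = tuple(f"q{i}" for i in range(10))
    config = SyntheticConfig(
        n_respondents=120,
        items=items,
        planted_pairs=(("q0", "q1", 0.9), ("q2", "q3", 0.9)),
        target_items={"nutA": items[:6], "nutB": items[4:9]},
        seed=11,
    )
    return generate_cohort(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_answers(rng, n_rows, items, n_levels=8):
    codes = rng.integers(0, n_levels, size=(n_rows, len(items)))
    return pd.DataFrame(codes, columns=list(items)).astype("Int64")
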