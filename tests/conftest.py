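import numpy as np
import pandas as pd
import pytest

from elemix import ELEMENTS, default_config, generate_pure_panel

SMALL_COUNTS = {"DE": 12, "IT": 12, "CH": 12, "FR": 12, "CN": 10, "US": 10}


@pytest.fixture(scope="session")
def default_world():
    """The full-size six-country world (206 samples)."""
    return default_config(seed=11)


@pytest.fixture(scope="session")
def default_panel(default_world):
    return generate_pure_panel(default_world)


@pytest.fixture(scope="session")
def separated_world():
    """Strongly separated countries, no instrument noise."""
    return default_config(seed=21, country_separation=5.0,
                          analytic_cv=0.0,
                          samples_per_country=SMALL_COUNTS)


@pytest.fixture(scope="session")
def separated_panel(separated_world):
    return generate_pure_panel(separated_world)


@pytest.fixture(scope="session")
def null_world():
    """No country effect at all: any classifier is guessing."""
    return default_config(seed=31, country_separation=0.0,
                          analytic_cv=0.05,
                          samples_per_country=SMALL_COUNTS)


@pytest.fixture(scope="session")
def null_panel(null_world):
    return generate_pure_panel(null_world)


def constant_parent_panel(n_per_country: int = 6) -> pd.DataFrame:
    """Two countries whose samples are exact copies of one profile each.

    Mixture geometry is then closed-form: every mixture at level L sits
    at the same point on the segment between the two parent profiles.
    """
    rng = np.random.default_rng(7)
    pa = 10.0 ** rng.normal(1.0, 0.5, size=len(ELEMENTS))
    pb = pa * 10.0 ** rng.choice([-0.5, 0.5], size=len(ELEMENTS))
    rows = []
    for c, prof in (("AA", pa), ("BB", pb)):
        for i in range(n_per_country):
            row = {"sample_id": f"{c}{i:02d}", "country": c,
                   "harvest_year": 2018}
            row.update(dict(zip(ELEMENTS, prof)))
            rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def constant_panel():
    return constant_parent_panel()
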