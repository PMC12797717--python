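import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import codiversity as cd

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")


@pytest.fixture(scope="session")
def scheme18():
    return cd.default_scheme()


@pytest.fixture(scope="session")
def scheme2():
    return cd.generic_scheme(2)


@pytest.fixture
def worked_gm(scheme2):
    """Two-group instance with every decomposition known in closed form.

    pi = (1/3, 2/3), p1 = (0.5, 0.5), p2 = (0.75, 0.25):
    S_1 = 0.5, S_2 = 0.375, S_12 = 0.5, pooled = (2/3, 1/3),
    S = 4/9, S_W = S_B = 2/9.
    """
    return cd.GroupedMortality(
        scheme2,
        ("a", "b"),
        np.array([1 / 3, 2 / 3]),
        (
            cd.CauseDistribution(scheme2, np.array([0.5, 0.5]), n=20),
            cd.CauseDistribution(scheme2, np.array([0.75, 0.25]), n=40),
        ),
    )


def random_grouped(rng, G=None, k=18, with_n=True):
    """A random valid GroupedMortality drawn from Dirichlet profiles."""
    if G is None:
        G = int(rng.integers(1, 26))
    scheme = cd.default_scheme() if k == 18 else cd.generic_scheme(k)
    P = rng.dirichlet(rng.uniform(0.2, 5.0, size=k), size=G)
    w = rng.dirichlet(np.full(G, 1.0))
    dists = tuple(
        cd.CauseDistribution(scheme, p, n=int(rng.integers(100, 10_000)) if with_n else None)
        for p in P
    )
    return cd.GroupedMortality(scheme, tuple(f"g{i}" for i in range(G)), w, dists)


@pytest.fixture
def deaths_frame():
    """Small two-group, two-cause deaths table matching the worked instance."""
    rows = [
        ("a", 2000, "f", "0-49", "cause_1", 10),
        ("a", 2000, "f", "0-49", "cause_2", 10),
        ("b", 2000, "f", "0-49", "cause_1", 30),
        ("b", 2000, "f", "0-49", "cause_2", 10),
    ]
    return pd.DataFrame(rows, columns=["group", "year", "sex", "age_group", "cause", "deaths"])
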