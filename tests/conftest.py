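import numpy as np
import pandas as pd
import pytest

from sarmap import make_lattice
from sarmap.synthetic import STRATA


@pytest.fixture(scope="session")
def lattice5():
    return make_lattice(5, 5, "queen")


@pytest.fixture(scope="session")
def lattice15():
    return make_lattice(15, 15, "queen")


def poisson_data(graph, theta, expected=10.0, seed=0):
    """O ~ Poisson(E * theta) with constant E per tract."""
    rng = np.random.default_rng(seed)
    E = np.full(graph.n, float(expected))
    O = rng.poisson(E * np.asarray(theta, dtype=float))
    return O.astype(float), E


def single_stratum_tables(tracts, pops, counts, sex="male", age_group="40-64"):
    """Population/count tables living in one (sex, age group) stratum."""
    pop = pd.DataFrame({"tract_id": tracts, "sex": sex, "age_group": age_group,
                        "value": pops})
    cnt = pd.DataFrame({"tract_id": tracts, "sex": sex, "age_group": age_group,
                        "value": counts})
    return cnt, pop


def full_random_tables(graph, seed=0, mean_pop=500, rate=0.01):
    """Random stratified tables over the full tract x sex x age-group domain."""
    rng = np.random.default_rng(seed)
    rows_p, rows_c = [], []
    for t in graph.tract_ids:
        for s, g in STRATA:
            n = int(rng.integers(0, 2 * mean_pop))
            rows_p.append({"tract_id": t, "sex": s, "age_group": g, "value": n})
            rows_c.append({"tract_id": t, "sex": s, "age_group": g,
                           "value": int(rng.poisson(n * rate))})
    return pd.DataFrame(rows_c), pd.DataFrame(rows_p)
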