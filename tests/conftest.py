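import numpy as np
import pytest

from ebpr_gsa import model as M
from ebpr_gsa.sampling import saltelli_design, transform
from ebpr_gsa.uncertainty import build_default_database


@pytest.fixture(scope="session")
def database():
    return build_default_database()


@pytest.fixture(scope="session")
def constants():
    return M.load_constants()


def _midpoint_values(database):
    values = {}
    for rec in database:
        spec = rec.resolve()
        if spec.kind == "uniform":
            values[rec.name] = 0.5 * (spec.params["a"] + spec.params["b"])
        elif spec.kind == "erlang":
            values[rec.name] = spec.params["k"] / spec.params["lam"]
    total = values["f_PHA_i"]
    for name, w in zip(("f_PHB_i", "f_PHV_i", "f_PH2MV_i"), (0.6, 0.25, 0.15)):
        values[name] = w * total
    return values


@pytest.fixture(scope="session")
def midpoint_values(database):
    return _midpoint_values(database)


@pytest.fixture(scope="session")
def midpoint_params(midpoint_values):
    return M.ModelParameters(
        np.array([midpoint_values[n] for n in M.PARAM_NAMES])
    )


@pytest.fixture(scope="session")
def random_matrix(database):
    """A small transformed Saltelli matrix for drawing random model inputs."""
    design = saltelli_design(8, len(database), seed=123, scramble=True)
    return transform(design, database)


@pytest.fixture(scope="session")
def random_states(midpoint_params):
    """Physically plausible random model states (strictly positive pools)."""
    rng = np.random.default_rng(42)
    n = 500
    states = np.empty((n, 11))
    states[:, 0] = rng.uniform(0.0, 0.25, n)          # S_O2
    states[:, 1] = rng.uniform(0.0, 1.5, n)           # S_HAc
    states[:, 2] = rng.uniform(0.0, 1.0, n)           # S_HPr
    states[:, 3] = rng.uniform(0.0, 3.0, n)           # S_PO4
    states[:, 4] = rng.uniform(1.0, 8.0, n)           # X_PAO
    states[:, 5:10] = rng.uniform(0.0, 2.0, (n, 5))   # intracellular pools
    states[:, 10] = 0.0
    return states
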