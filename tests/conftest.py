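import numpy as np
import pytest

from xapswitch import CellGeometry, table1


@pytest.fixture(scope="session")
def t1():
    """Reference parameter set (the canonical bistable scenario)."""
    return table1()


@pytest.fixture(scope="session")
def geom():
    """1 fL cytoplasm, K_a = 5e-5 M: Omega ~ 3.01e4 molecules/unit."""
    return CellGeometry()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20200507)


def random_table1_draws(rng, n):
    """Joint log-uniform draws from the estimated parameter ranges."""
    draws = []
    for _ in range(n):
        draws.append(dict(
            rho_m=10 ** rng.uniform(-5, -1),
            gamma_mp=10 ** rng.uniform(0.5, 1.5),
            rho_p=10 ** rng.uniform(1.5, 2.5),
            XapR_R=10 ** rng.uniform(-2, 2),
            c_a=10 ** rng.uniform(-1, 3),
            k_beta_i=10 ** rng.uniform(3, 5),
            k_beta_e=10 ** rng.uniform(1, 5),
            k_alpha=10 ** rng.uniform(1.2, 2.8),
            k_eta=10 ** rng.uniform(-3, 3),
            xi=rng.uniform(0.7, 0.9),
            K_beta_i=10 ** rng.uniform(-1, 3),
            K_beta_e=10 ** rng.uniform(0, 4),
            K_chiA=10 ** rng.uniform(1, 3),
            K_IA=10 ** rng.uniform(1, 3),
            deps_x=rng.uniform(2, 8),
            deps_coop=rng.uniform(0, 10),
        ))
    return draws
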