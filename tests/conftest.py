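import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from enzymof.design_space import Axis, enumerate_grid
from enzymof.oracle import Oracle, OracleConfig

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_grid():
    """Coarsened version of the default space: 17 x 21 x 15 = 5355 points."""
    return enumerate_grid(
        [
            Axis("ca_mM", 2.0, 98.0, 6.0),
            Axis("idc_mM", 22.5, 122.5, 5.0),
            Axis.from_levels("enzyme_mg_per_ml", 0.2, 1.96, 15),
        ]
    )


@pytest.fixture(scope="session")
def toy_grid():
    """5 x 5 x 5 grid for exhaustive brute-force comparisons."""
    return enumerate_grid(
        [
            Axis("ca_mM", 10.0, 90.0, 20.0),
            Axis("idc_mM", 25.0, 105.0, 20.0),
            Axis.from_levels("enzyme_mg_per_ml", 0.2, 1.8, 5),
        ]
    )


@pytest.fixture(scope="session")
def noiseless_oracle(small_grid):
    return Oracle(OracleConfig(noise_sd=0.0, replicates=1, seed=11), small_grid)


def constant_oracle_config(value: float = 0.5, **kw) -> OracleConfig:
    """Oracle whose EE and REA surfaces are flat at ``value`` (amp-0 bumps)."""
    params = {"base": value, "amp": 0.0, "center": (50.0, 70.0, 1.0), "width": (1.0, 1.0, 1.0)}
    return OracleConfig(
        surface_kind="gaussian_bump", ee_params=params, rea_params=params, **kw
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
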