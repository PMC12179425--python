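import numpy as np
import pandas as pd
import pytest

from twinace import SimSpec, StandardizedParams, simulate_dataset

TRAITS = ("motor", "social_communication")

#: fitted bivariate correlated-factors solution used as generating values
STUDY_STD = StandardizedParams(
    traits=TRAITS,
    A=(0.21, 0.12), C=(0.67, 0.78), E=(0.12, 0.10),
    r_a=-0.39, r_c=0.45, r_e=0.32,
)

N_MZ, N_DZ = 164, 131


def study_spec(seed: int = 0, n_mz: int = N_MZ, n_dz: int = N_DZ,
               missing_rate: float = 0.0) -> SimSpec:
    """Bivariate generating spec at the fitted study values (no covariates)."""
    return SimSpec(
        n_mz=n_mz, n_dz=n_dz, traits=TRAITS,
        means=(10.27, 34.22), total_var=(1.05**2, 1.65**2),
        ace=((0.21, 0.67, 0.12), (0.12, 0.78, 0.10)),
        r_a=-0.39, r_c=0.45, r_e=0.32,
        missing_rate=missing_rate, seed=seed,
    )


@pytest.fixture(scope="session")
def study_dataset() -> pd.DataFrame:
    """One complete-data draw at the study design size."""
    return simulate_dataset(study_spec(seed=20240531))


@pytest.fixture(scope="session")
def big_univariate_dataset() -> pd.DataFrame:
    """Large univariate draw (A=0.5, C=0.3, E=0.2) for closed-form checks."""
    spec = SimSpec(
        n_mz=50_000, n_dz=50_000, traits=("y",), means=(0.0,),
        total_var=(1.0,), ace=((0.5, 0.3, 0.2),), seed=7,
    )
    return simulate_dataset(spec)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
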