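import numpy as np
import pytest

from radicp.datamodel import CohortMetadata, FeatureTable
from radicp.simulate import SyntheticConfig, simulate_multicenter


def make_table(X, prefix="original_firstorder_F"):
    """Wrap a matrix in a FeatureTable with grammar-conformant names."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    return FeatureTable(
        [f"s{i}" for i in range(n)],
        [f"{prefix}{j}_T1_L1" for j in range(p)],
        X,
    )


def make_metadata(y, env=None, positive="wild-type"):
    """Binary 0/1 vector (1 = positive) -> CohortMetadata."""
    y = np.asarray(y, dtype=int)
    if env is None:
        env = ["c1"] * len(y)
    return CohortMetadata(
        [f"s{i}" for i in range(len(y))],
        list(env),
        ["wild-type" if v else "mutant" for v in y],
        positive,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A fast 2-environment cohort with clear causal/spurious separation."""
    cfg = SyntheticConfig(
        n_per_env=[120, 120],
        prevalence_per_env=[0.4, 0.4],
        causal_mean_shift_per_env=[0.0, 0.0],
        gamma_per_env=[0.0, 2.5],
        k_causal=2,
        k_spurious=2,
        k_noise=10,
        beta=[1.5, -1.5],
        seed=11,
    )
    return simulate_multicenter(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """The default 4-center cohort (7/12/36/22 cases)."""
    return simulate_multicenter(SyntheticConfig(seed=5))
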