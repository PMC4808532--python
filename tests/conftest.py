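import numpy as np
import pandas as pd
import pytest

from ttscreen import DesignSpec, MethylationMatrix, SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated study shared across read-only tests."""
    cfg = SimConfig(n_sites=120, n_samples=90, k=8, seed=42)
    M, cov, truth = simulate_dataset(cfg)
    return M, cov, truth, cfg


@pytest.fixture(scope="session")
def small_design(small_sim):
    M, cov, truth, cfg = small_sim
    return DesignSpec(cov, ["x1", "x2", "x1:x2"], ["x1:x2"])


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_matrix(values: np.ndarray) -> MethylationMatrix:
    g, n = values.shape
    return MethylationMatrix(
        [f"cg{i}" for i in range(g)], [f"s{j}" for j in range(n)], values
    )


@pytest.fixture()
def numeric_design():
    """20 samples, one numeric covariate; used for hand-checkable fits."""
    rng = np.random.default_rng(7)
    x1 = rng.normal(1.0, 1.0, 20)
    cov = pd.DataFrame({"x1": x1}, index=[f"s{j}" for j in range(20)])
    return cov
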