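import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from celldrop.matrix import ExpressionMatrix
from celldrop.pipeline import RunConfig, run_pipeline
from celldrop.simulate import SimulationConfig, simulate

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_matrix(values, log=False, kinds=None, cells=None, mols=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return ExpressionMatrix(
        values,
        cells or [f"c{i}" for i in range(n)],
        mols or [f"g{j}" for j in range(p)],
        kinds,
        log_transformed=log,
    )


@pytest.fixture(scope="session")
def standard_sim():
    """The standard study conditions: 300 cells, 4 types, 16-fold markers,
    Michaelis constant 10, 6 planted doublet-like outlier cells."""
    cfg = SimulationConfig(seed=1, n_outliers=6)
    m, truth = simulate(cfg)
    return cfg, m, truth


@pytest.fixture(scope="session")
def standard_run(standard_sim):
    """Full pipeline output on the standard synthetic dataset."""
    _, m, truth = standard_sim
    results, manifest = run_pipeline(m, RunConfig(seed=1))
    return m, truth, results, manifest
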