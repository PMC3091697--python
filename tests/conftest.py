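import numpy as np
import pandas as pd
import pytest

from gillzinc.preprocess import ExpressionDataset
from gillzinc.simdata import SimulationConfig, simulate_expression_dataset


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_reporters=600, seed=11)


@pytest.fixture(scope="session")
def small_experiment(small_config):
    """One seeded 600-reporter experiment in the full 2x5x5 design."""
    return simulate_expression_dataset(small_config)


@pytest.fixture(scope="session")
def noise_free_experiment():
    cfg = SimulationConfig(
        n_reporters=400,
        noise_sd=0.0,
        bias_coeffs=(0.0,),
        low_confidence_rate=0.0,
        seed=3,
    )
    return cfg, simulate_expression_dataset(cfg)


def make_dataset(M: np.ndarray, design_rows, reporters=None) -> ExpressionDataset:
    """Hand-built dataset helper: design_rows = [(array, condition, time, rep)]."""
    design = pd.DataFrame(
        design_rows, columns=["array", "condition", "time", "replicate"]
    ).set_index("array")
    M = pd.DataFrame(
        M,
        index=reporters or [f"r{i}" for i in range(len(M))],
        columns=design.index,
    )
    A = pd.DataFrame(10.0, index=M.index, columns=M.columns)
    conf = pd.DataFrame(True, index=M.index, columns=M.columns)
    return ExpressionDataset(M=M, A=A, confidence=conf, design=design)
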