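import warnings

import numpy as np
import pytest

from grndisc import (
    DegenerateDiscretizationWarning,
    ExpressionMatrix,
    RegulatoryNetwork,
    SimConfig,
    run_benchmark,
    simulate_suite,
)


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    values = np.array(
        [
            [0.0, 1.0, 2.0, 3.0],
            [4.0, 1.0, 3.0, 2.0],
            [5.0, 5.0, 5.0, 5.0],
        ]
    )
    return ExpressionMatrix(values, ("G1", "G2", "G3"), ("T1", "T2", "T3", "T4"))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_matrix(rng, n=10, m=25) -> ExpressionMatrix:
    values = np.exp(rng.normal(0, 1, size=(n, m)))
    return ExpressionMatrix(
        values,
        tuple(f"G{i}" for i in range(n)),
        tuple(f"T{j}" for j in range(m)),
    )


@pytest.fixture
def triangle_network() -> RegulatoryNetwork:
    return RegulatoryNetwork(("A", "B", "C"), frozenset({("A", "B")}))


# Shared scaled benchmark for the acceptance tests: 20 datasets at 15 genes
# (gene count reduced from 50 for runtime; the ANOVA d.f. depend only on the
# factor design, not on the gene count).
ECHO_CONFIG = SimConfig(
    n_genes=15,
    n_timepoints=25,
    n_datasets=20,
    n_edges=15,
    regulator_fraction=0.3,
    effect_size=1.0,
    source_amplitude=0.5,
    noise_sd=0.05,
    baseline_log_sd=1.0,
    seed=20100520,
)


@pytest.fixture(scope="session")
def scaled_benchmark_records():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateDiscretizationWarning)
        suite = simulate_suite(ECHO_CONFIG)
        return run_benchmark(suite)
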