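import numpy as np
import pandas as pd
import pytest

from idrw.simulate import SimulationConfig, simulate_cohort
from idrw.types import GOOD, POOR, LayerKind, OmicsMatrix, SampleLabels


def make_labels(n_good: int, n_poor: int) -> SampleLabels:
    names = [f"S{i:04d}" for i in range(n_good + n_poor)]
    return SampleLabels(
        pd.Series([GOOD] * n_good + [POOR] * n_poor, index=names, name="group")
    )


def make_expr(values: np.ndarray, genes=None, samples=None) -> OmicsMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{i:04d}" for i in range(values.shape[1])]
    return OmicsMatrix(
        LayerKind.MICROARRAY, pd.DataFrame(values, index=genes, columns=samples)
    )


@pytest.fixture(scope="session")
def mini_cohort():
    """Small planted-signal cohort shared by read-only tests."""
    config = SimulationConfig(
        n_good=20,
        n_poor=20,
        n_pathways=6,
        pathway_size=8,
        n_planted=1,
        delta_expr=2.0,
        edge_density=0.3,
        seed=7,
    )
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def null_cohort():
    """No planted signal anywhere."""
    config = SimulationConfig(
        n_good=20,
        n_poor=20,
        n_pathways=6,
        pathway_size=8,
        n_planted=1,
        delta_expr=0.0,
        delta_cna_gain=0.0,
        edge_density=0.3,
        seed=8,
    )
    return simulate_cohort(config)
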