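import numpy as np
import pytest

from fcnet import (
    CohortDesign,
    ConnectivityMatrix,
    EdgeEffect,
    default_parcellation,
)


@pytest.fixture(scope="session")
def small_parcellation():
    """16 ROIs over the eight canonical families."""
    return default_parcellation(16)


@pytest.fixture
def small_design(small_parcellation):
    labels, partition = small_parcellation
    return CohortDesign(
        roi_labels=labels,
        module_partition=partition,
        n_per_cell={("patient", "M"): 3, ("patient", "F"): 2,
                    ("control", "M"): 3, ("control", "F"): 2},
        series_length=120,
        seed=11,
    )


@pytest.fixture
def perturbed_design(small_parcellation):
    labels, partition = small_parcellation
    return CohortDesign(
        roi_labels=labels,
        module_partition=partition,
        n_per_cell={("patient", "M"): 4, ("patient", "F"): 4,
                    ("control", "M"): 4, ("control", "F"): 4},
        series_length=150,
        edge_effects=[EdgeEffect(labels[0], labels[8], 0.3, group="patient")],
        seed=13,
    )


def random_connectivity(n, seed, positive=True):
    """A symmetric zero-diagonal matrix usable as Fisher-z connectivity."""
    rng = np.random.default_rng(seed)
    z = rng.normal(0.3 if positive else 0.0, 0.3, size=(n, n))
    z = (z + z.T) / 2
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(subject_id=f"rand{seed}", z=z,
                              roi_labels=[f"r{i}" for i in range(n)])


@pytest.fixture
def connectivity_16():
    return random_connectivity(16, seed=5)
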