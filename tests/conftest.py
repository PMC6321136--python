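import math

import pytest

from pharmfish.datasets import ActivityDataset
from pharmfish.pharmacophore import Conformer
from pharmfish.synthetic import FingerprintGeneratorSpec, gen_fingerprint_dataset


@pytest.fixture(scope="session")
def benzene():
    """Planar benzene hexagon with 1.39 A bonds, alternating bond orders."""
    atoms = [("C",
              1.39 * math.cos(math.radians(60 * i)),
              1.39 * math.sin(math.radians(60 * i)), 0.0) for i in range(6)]
    bonds = [(i, (i + 1) % 6, 2 if i % 2 == 0 else 1) for i in range(6)]
    return Conformer("benzene", tuple(atoms), tuple(bonds))


@pytest.fixture(scope="session")
def planted_data():
    """Well-separated synthetic fingerprints: 50 actives vs 50 inactives."""
    return gen_fingerprint_dataset(FingerprintGeneratorSpec(seed=11), "planted")


@pytest.fixture(scope="session")
def svm_ensemble(planted_data):
    from pharmfish.ensemble import train_ensemble

    fps, dataset = planted_data
    return train_ensemble(dataset, fps, method="svm_linear", seed=11, cost=1.0)


@pytest.fixture(scope="session")
def nb_ensemble(planted_data):
    from pharmfish.ensemble import train_ensemble

    fps, dataset = planted_data
    return train_ensemble(dataset, fps, method="naive_bayes", seed=11)


def small_dataset(na: int, ni: int, dataset_id: str = "toy") -> ActivityDataset:
    records = tuple((f"a{i}", "active") for i in range(na)) + tuple(
        (f"i{i}", "inactive") for i in range(ni))
    return ActivityDataset(dataset_id, records)
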