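import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gsclust import (
    PlantedDesign,
    build_similarity_matrix,
    create_collection,
    generate_planted_collection,
    write_fixture_files,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_collection(rng: np.random.Generator, n_sets=6, universe=20, max_size=8):
    """A small random collection over a numbered gene universe."""
    genes = [f"g{i}" for i in range(universe)]
    records = []
    for i in range(n_sets):
        size = int(rng.integers(1, max_size + 1))
        members = rng.choice(genes, size=size, replace=False)
        records.append(
            dict(name=f"set{i}", genes=[str(g) for g in members], experiment="rand")
        )
    return create_collection(records)


@pytest.fixture(scope="session")
def planted():
    """The well-separated 3-group study condition with its ground truth."""
    coll, labels = generate_planted_collection(PlantedDesign(seed=7))
    return coll, labels


@pytest.fixture(scope="session")
def planted_rr(planted):
    coll, labels = planted
    return build_similarity_matrix(coll, "rr"), labels


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures")
    write_fixture_files(out)
    return out


@pytest.fixture
def tiny_collection():
    return create_collection(
        [
            dict(name="alpha", genes=["A", "B", "C"], experiment="e1"),
            dict(name="beta", genes=["B", "C", "D"], experiment="e1"),
            dict(name="gamma", genes=["X", "Y"], experiment="e1"),
        ]
    )
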