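from pathlib import Path

import networkx as nx
import numpy as np
import pytest
import yaml

from vaemda.datatypes import AssociationMatrix, DiseaseDAGSet, SimilarityMatrix
from vaemda.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def acceptance_config() -> dict:
    path = Path(__file__).with_name("acceptance_config.yaml")
    return yaml.safe_load(path.read_text())


@pytest.fixture
def toy_association() -> AssociationMatrix:
    values = np.array([[1, 0, 1], [0, 1, 0], [1, 1, 0], [0, 0, 1]], dtype=np.uint8)
    return AssociationMatrix(("m1", "m2", "m3", "m4"), ("d1", "d2", "d3"), values)


def make_dag(disease: str, edges: list[tuple[str, str]]) -> nx.DiGraph:
    """Parent -> child edges plus the disease node itself."""
    graph = nx.DiGraph()
    graph.add_node(disease)
    graph.add_edges_from(edges)
    return graph


@pytest.fixture
def shared_root_dags() -> DiseaseDAGSet:
    """Two diseases whose DAGs share only the root term r."""
    return DiseaseDAGSet(
        {"d1": make_dag("d1", [("r", "d1")]), "d2": make_dag("d2", [("r", "d2")])},
        {"d1": True, "d2": True},
    )


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(
        SyntheticSpec(nm=50, nd=30, latent_rank=3, density=0.1, noise=0.1, seed=0)
    )


def random_similarity(rng: np.random.Generator, ids: tuple[str, ...], role: str) -> SimilarityMatrix:
    n = len(ids)
    values = rng.random((n, n))
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(ids, values, role)
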