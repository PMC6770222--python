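"""Synthetic fixture datasets with planted low-rank structure.

Every external input of the pipeline is emulated: a bipartite association
matrix drawn from a planted low-rank Bernoulli model, a functional
similarity matrix derived from the miRNA latent factors (so it carries
signal independent of the association sample), and per-disease DAG
hierarchies built by cutting a hierarchical clustering of the disease
latent factors, so term-sharing correlates with true disease similarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import brentq
from scipy.special import expit

from .datatypes import AssociationMatrix, DiseaseDAGSet, SimilarityMatrix


@dataclass(frozen=True)
class SyntheticSpec:
    nm: int
    nd: int
    latent_rank: int = 4
    density: float = 0.1
    noise: float = 0.1
    dag_depth: int = 3
    fraction_without_dag: float = 0.0
    fraction_without_fs: float = 0.0
    seed: int = 0
    signal_scale: float = 3.0  # logit scale of the planted structure

    def __post_init__(self) -> None:
        if not 0 < self.density < 1:
            raise ValueError("density must be in (0, 1)")
        for name in ("fraction_without_dag", "fraction_without_fs"):
            if not 0 <= getattr(self, name) < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.latent_rank < 1:
            raise ValueError("latent_rank must be >= 1")
        if self.nm < 2 or self.nd < 2:
            raise ValueError("need at least 2 miRNAs and 2 diseases")
        if self.dag_depth < 1:
            raise ValueError("dag_depth must be >= 1")


@dataclass(frozen=True)
class SyntheticDataset:
    spec: SyntheticSpec
    associations: AssociationMatrix
    fs: SimilarityMatrix
    fs_coverage: np.ndarray
    dags: DiseaseDAGSet
    probabilities: np.ndarray  # planted P(association), nm x nd


def _solve_intercept(logits: np.ndarray, density: float) -> float:
    """Intercept b with mean(sigmoid(logits + b)) = density."""

    def gap(b: float) -> float:
        return float(expit(logits + b).mean()) - density

    lo, hi = -50.0, 50.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError("requested density is infeasible for these logits")
    return float(brentq(gap, lo, hi, xtol=1e-12))


def _build_dags(
    V: np.ndarray,
    disease_ids: tuple[str, ...],
    depth: int,
    covered: np.ndarray,
) -> DiseaseDAGSet:
    """Chain DAGs from nested cuts of a hierarchical clustering of V rows.

    Level l of the hierarchy cuts the dendrogram into 2**l clusters; each
    covered disease gets the chain ROOT -> L1 -> ... -> Ldepth -> disease.
    Cuts of one dendrogram are nested, so shared prefixes reflect latent
    proximity.
    """
    tree = linkage(V, method="ward")
    levels = []
    for level in range(1, depth + 1):
        n_clusters = min(2**level, len(disease_ids))
        levels.append(fcluster(tree, t=n_clusters, criterion="maxclust"))
    graphs: dict[str, nx.DiGraph] = {}
    coverage: dict[str, bool] = {}
    for j, disease in enumerate(disease_ids):
        coverage[disease] = bool(covered[j])
        if not covered[j]:
            continue
        chain = ["ROOT"]
        for level, assignment in enumerate(levels, start=1):
            chain.append(f"L{level}C{assignment[j]}")
        chain.append(disease)
        graph = nx.DiGraph()
        graph.add_node(disease)
        for parent, child in zip(chain, chain[1:]):
            graph.add_edge(parent, child)
        graphs[disease] = graph
    return DiseaseDAGSet(graphs, coverage)


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw a complete synthetic dataset from the planted low-rank model."""
    rng = np.random.default_rng(spec.seed)
    U = rng.standard_normal((spec.nm, spec.latent_rank))
    V = rng.standard_normal((spec.nd, spec.latent_rank))
    logits = (spec.signal_scale / np.sqrt(spec.latent_rank)) * (U @ V.T)
    b = _solve_intercept(logits, spec.density)
    P = expit(logits + b)
    A_values = (rng.random(P.shape) < P).astype(np.uint8)

    mirna_ids = tuple(f"m{i:04d}" for i in range(spec.nm))
    disease_ids = tuple(f"d{j:04d}" for j in range(spec.nd))
    A = AssociationMatrix(mirna_ids, disease_ids, A_values)

    # FS from the latent factors: rescaled cosine similarity plus symmetric noise.
    norms = np.linalg.norm(U, axis=1, keepdims=True)
    cosine = (U / norms) @ (U / norms).T
    fs_values = (cosine + 1.0) / 2.0
    if spec.noise > 0:
        jitter = rng.normal(0.0, spec.noise, size=fs_values.shape)
        fs_values = fs_values + (jitter + jitter.T) / 2.0
    fs_values = np.clip(fs_values, 0.0, 1.0)
    np.fill_diagonal(fs_values, 1.0)
    fs = SimilarityMatrix(mirna_ids, fs_values, "FS")

    n_no_dag = int(round(spec.fraction_without_dag * spec.nd))
    dag_covered = np.ones(spec.nd, dtype=bool)
    if n_no_dag:
        dag_covered[rng.choice(spec.nd, size=n_no_dag, replace=False)] = False
    dags = _build_dags(V, disease_ids, spec.dag_depth, dag_covered)

    n_no_fs = int(round(spec.fraction_without_fs * spec.nm))
    fs_coverage = np.ones(spec.nm, dtype=bool)
    if n_no_fs:
        fs_coverage[rng.choice(spec.nm, size=n_no_fs, replace=False)] = False

    return SyntheticDataset(spec, A, fs, fs_coverage, dags, P)


def holdout_split(
    A: AssociationMatrix, fraction: float, seed: int
) -> tuple[AssociationMatrix, list[tuple[int, int]]]:
    """Remove ceil(fraction * n_known) known pairs uniformly at random."""
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    pairs = A.known_pairs()
    n_out = int(np.ceil(fraction * len(pairs)))
    if n_out == 0:
        return A, []
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pairs), size=n_out, replace=False)
    held_out = [pairs[i] for i in sorted(chosen.tolist())]
    values = A.values.copy()
    for i, j in held_out:
        values[i, j] = 0
    return A.with_values(values), held_out
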