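"""Similarity construction: semantic (DAG-based), Gaussian profile kernel,
and the integrated disease/miRNA similarities.

Two semantic models are computed from per-disease ancestor DAGs: a decayed
contribution model (SS1) and an information-content model based on how many
DAGs contain each term (SS2).  The Gaussian interaction profile kernel
(KD/KM) is computed from rows/columns of the binary association matrix with
a bandwidth normalized by the mean squared profile norm.  Integration uses
semantic/functional similarity where available and the kernel otherwise.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
from scipy.spatial.distance import squareform, pdist

from .datatypes import DiseaseDAGSet, SimilarityMatrix

DEFAULT_DELTA = 0.5
DEFAULT_GAMMA_PRIME = 1.0


def decay_contributions(dags: DiseaseDAGSet, disease: str, delta: float) -> dict[str, float]:
    """Per-term decayed contributions D1_d(t) for one disease's DAG.

    D1_d(d) = 1 and D1_d(t) = delta * max over children t' of t (within the
    DAG) of D1_d(t'), i.e. the contribution decays by ``delta`` per layer of
    distance from the disease term along the steepest path.
    """
    if not 0 < delta < 1:
        raise ValueError("delta must be in (0, 1)")
    graph = dags.graphs[disease]
    contrib: dict[str, float] = {}
    # Every node has a path to the sink `disease`; process sinks-first.
    for term in reversed(list(nx.topological_sort(graph))):
        if term == disease:
            contrib[term] = 1.0
        else:
            contrib[term] = delta * max(contrib[c] for c in graph.successors(term))
    return contrib


def frequency_contributions(
    dags: DiseaseDAGSet, n_diseases: int | None = None
) -> dict[str, dict[str, float]]:
    """Per-term information contributions D2_d(t) for every covered disease.

    D2_d(t) = -log(number of DAGs containing t / n_diseases).  When
    ``n_diseases`` is None the number of covered diseases is used, so a term
    shared by every DAG contributes exactly zero.
    """
    covered = dags.covered()
    if n_diseases is None:
        n_diseases = len(covered)
    if n_diseases < 1:
        raise ValueError("n_diseases must be >= 1")
    term_counts: dict[str, int] = {}
    for disease in covered:
        for term in dags.terms(disease):
            term_counts[term] = term_counts.get(term, 0) + 1
    out: dict[str, dict[str, float]] = {}
    for disease in covered:
        contrib: dict[str, float] = {}
        for term in dags.terms(disease):
            count = term_counts[term]
            assert count >= 1, "term must appear in at least its own DAG"
            contrib[term] = -np.log(count / n_diseases)
        out[disease] = contrib
    return out


def _semantic_from_contributions(
    diseases: list[str], contribs: dict[str, dict[str, float]], role: str
) -> SimilarityMatrix:
    n = len(diseases)
    values = np.zeros((n, n))
    semantic_value = {d: sum(contribs[d].values()) for d in diseases}
    for a in range(n):
        da = diseases[a]
        values[a, a] = 1.0
        for b in range(a + 1, n):
            db = diseases[b]
            shared = set(contribs[da]) & set(contribs[db])
            denom = semantic_value[da] + semantic_value[db]
            if denom <= 0.0:
                s = 0.0  # degenerate: no informative terms on either side
            else:
                s = sum(contribs[da][t] + contribs[db][t] for t in shared) / denom
            values[a, b] = values[b, a] = s
    np.clip(values, 0.0, 1.0, out=values)
    return SimilarityMatrix(tuple(diseases), values, role)


def semantic_similarity_model1(
    dags: DiseaseDAGSet, delta: float = DEFAULT_DELTA
) -> SimilarityMatrix:
    """Decay-model semantic similarity SS1 over diseases with DAG coverage.

    SS1(i, j) = sum over shared terms t of (D1_i(t) + D1_j(t)) divided by
    (DV1(i) + DV1(j)), where DV1 is the sum of a disease's contributions.
    """
    covered = dags.covered()
    if not covered:
        raise ValueError("no disease has DAG coverage")
    contribs = {d: decay_contributions(dags, d, delta) for d in covered}
    return _semantic_from_contributions(covered, contribs, "SS1")


def semantic_similarity_model2(
    dags: DiseaseDAGSet, n_diseases: int | None = None
) -> SimilarityMatrix:
    """Frequency-model semantic similarity SS2 over diseases with DAG coverage."""
    covered = dags.covered()
    if not covered:
        raise ValueError("no disease has DAG coverage")
    contribs = frequency_contributions(dags, n_diseases)
    return _semantic_from_contributions(covered, contribs, "SS2")


def gip_kernel(
    profiles: np.ndarray,
    entity_ids: tuple[str, ...],
    role: str,
    gamma_prime: float = DEFAULT_GAMMA_PRIME,
) -> SimilarityMatrix:
    """Gaussian interaction profile kernel over rows of ``profiles``.

    K(a, b) = exp(-gamma * ||IP(a) - IP(b)||^2) with
    gamma = gamma_prime / mean_i ||IP(i)||^2.
    """
    if gamma_prime <= 0:
        raise ValueError("gamma_prime must be positive")
    profiles = np.asarray(profiles, dtype=float)
    mean_sq_norm = float(np.mean((profiles**2).sum(axis=1)))
    if mean_sq_norm == 0.0:
        raise ValueError("empty association matrix: all interaction profiles are zero")
    gamma = gamma_prime / mean_sq_norm
    sq_dists = squareform(pdist(profiles, metric="sqeuclidean"))
    values = np.exp(-gamma * sq_dists)
    np.fill_diagonal(values, 1.0)
    values = (values + values.T) / 2.0  # guard float asymmetry from pdist
    return SimilarityMatrix(entity_ids, values, role)


def _integrate(
    primary: np.ndarray,
    kernel: SimilarityMatrix,
    coverage: np.ndarray,
    role: str,
) -> SimilarityMatrix:
    coverage = np.asarray(coverage, dtype=bool)
    n = kernel.n
    if primary.shape != (n, n) or coverage.shape != (n,):
        raise ValueError("shape mismatch between similarity inputs")
    both = np.outer(coverage, coverage)
    values = np.where(both, primary, kernel.values)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(kernel.entity_ids, values, role)


def integrate_disease_similarity(
    ss1: SimilarityMatrix | None,
    ss2: SimilarityMatrix | None,
    kd: SimilarityMatrix,
    coverage: np.ndarray,
) -> SimilarityMatrix:
    """Integrated disease similarity SD.

    SD(i, j) is the average of the two semantic similarities when both
    diseases have DAG coverage, and the profile-kernel similarity KD(i, j)
    otherwise.  ``ss1``/``ss2`` are indexed over covered diseases only (in
    the order produced by the semantic operations); ``kd`` and ``coverage``
    span all diseases.
    """
    coverage = np.asarray(coverage, dtype=bool)
    primary = np.zeros((kd.n, kd.n))
    if coverage.any():
        if ss1 is None or ss2 is None:
            raise ValueError("semantic similarities required when coverage is nonempty")
        covered_ids = [kd.entity_ids[i] for i in np.nonzero(coverage)[0]]
        if list(ss1.entity_ids) != covered_ids or list(ss2.entity_ids) != covered_ids:
            raise ValueError("semantic similarity ids do not match covered diseases")
        idx = np.nonzero(coverage)[0]
        semantic = (ss1.values + ss2.values) / 2.0
        primary[np.ix_(idx, idx)] = semantic
    return _integrate(primary, kd, coverage, "SD")


def integrate_mirna_similarity(
    fs: SimilarityMatrix,
    km: SimilarityMatrix,
    coverage: np.ndarray,
) -> SimilarityMatrix:
    """Integrated miRNA similarity SM: FS where both covered, else KM."""
    if fs.entity_ids != km.entity_ids:
        raise ValueError("FS and KM are indexed over different miRNAs")
    return _integrate(fs.values, km, coverage, "SM")
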