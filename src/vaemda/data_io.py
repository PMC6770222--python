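"""Readers and writers for the pipeline's external file formats.

Formats are deliberately plain text: TSV association lists, CSV similarity
matrices with an id header row and column, TSV DAG edge tables, and a
long-format TSV score table.  All files use UTF-8 and '.' decimals.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import AssociationMatrix, DiseaseDAGSet, ScoreMatrix, SimilarityMatrix

logger = logging.getLogger(__name__)

#: Asymmetries up to this are silently symmetrized by averaging; larger ones error.
_SYMMETRIZE_ATOL = 1e-6


class ParseError(ValueError):
    """A file could not be parsed into a valid domain object."""


def read_association_list(
    path: str | Path,
    *,
    header: bool = False,
    sort_ids: bool = False,
) -> AssociationMatrix:
    """Read a two-column (mirna_id, disease_id) TSV into a binary matrix.

    Id ordering is first-appearance order in the file unless ``sort_ids`` is
    set, in which case ids are sorted lexicographically.  Duplicate rows
    collapse to a single 1 with a logged warning.
    """
    path = Path(path)
    mirna_ids: dict[str, int] = {}
    disease_ids: dict[str, int] = {}
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    with path.open(encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            if header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise ParseError(
                    f"{path}:{lineno}: expected two tab-separated columns, got {line!r}"
                )
            mirna, disease = fields
            if (mirna, disease) in seen:
                logger.warning(
                    "%s:%d: duplicate association (%s, %s) ignored",
                    path, lineno, mirna, disease,
                )
                continue
            seen.add((mirna, disease))
            mirna_ids.setdefault(mirna, len(mirna_ids))
            disease_ids.setdefault(disease, len(disease_ids))
            pairs.append((mirna, disease))
    if not pairs:
        raise ParseError(f"{path}: no associations found")
    m_order = sorted(mirna_ids) if sort_ids else list(mirna_ids)
    d_order = sorted(disease_ids) if sort_ids else list(disease_ids)
    m_index = {m: i for i, m in enumerate(m_order)}
    d_index = {d: j for j, d in enumerate(d_order)}
    values = np.zeros((len(m_order), len(d_order)), dtype=np.uint8)
    for mirna, disease in pairs:
        values[m_index[mirna], d_index[disease]] = 1
    return AssociationMatrix(tuple(m_order), tuple(d_order), values)


def read_similarity_matrix(path: str | Path, role: str) -> SimilarityMatrix:
    """Read a square CSV similarity table (ids in header row and first column).

    Asymmetries up to 1e-6 are symmetrized by averaging; larger asymmetries,
    NaN cells, values outside [0, 1] or a non-square table are errors.
    """
    path = Path(path)
    frame = pd.read_csv(path, index_col=0)
    row_ids = [str(x) for x in frame.index]
    col_ids = [str(x) for x in frame.columns]
    if row_ids != col_ids:
        raise ParseError(f"{path}: row ids differ from column ids (must be square)")
    values = frame.to_numpy(dtype=float)
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ParseError(f"{path}: NaN at ({row_ids[i]}, {col_ids[j]})")
    if (values < 0).any() or (values > 1).any():
        i, j = np.argwhere((values < 0) | (values > 1))[0]
        raise ParseError(
            f"{path}: value {values[i, j]!r} at ({row_ids[i]}, {col_ids[j]}) outside [0, 1]"
        )
    asym = np.abs(values - values.T)
    if asym.max(initial=0.0) > _SYMMETRIZE_ATOL:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise ParseError(
            f"{path}: asymmetry {asym[i, j]:.3g} at ({row_ids[i]}, {col_ids[j]}) "
            f"exceeds {_SYMMETRIZE_ATOL}"
        )
    values = (values + values.T) / 2.0
    return SimilarityMatrix(tuple(row_ids), values, role)


def write_similarity_matrix(sim: SimilarityMatrix, path: str | Path) -> None:
    """Write a similarity matrix as CSV with id header row and column."""
    frame = pd.DataFrame(sim.values, index=sim.entity_ids, columns=sim.entity_ids)
    frame.to_csv(path, float_format="%.17g")


def align_functional_similarity(
    fs: SimilarityMatrix, mirna_ids: tuple[str, ...]
) -> tuple[SimilarityMatrix, np.ndarray]:
    """Reindex an ingested FS matrix to the canonical miRNA ordering.

    miRNAs absent from the FS file get coverage False and zero off-diagonal
    similarity (the integration step substitutes the profile kernel for any
    pair involving them, so the placeholder values are never used).
    """
    n = len(mirna_ids)
    index = {m: i for i, m in enumerate(fs.entity_ids)}
    coverage = np.array([m in index for m in mirna_ids], dtype=bool)
    values = np.zeros((n, n))
    np.fill_diagonal(values, 1.0)
    covered = [i for i, m in enumerate(mirna_ids) if coverage[i]]
    src = [index[mirna_ids[i]] for i in covered]
    values[np.ix_(covered, covered)] = fs.values[np.ix_(src, src)]
    return SimilarityMatrix(tuple(mirna_ids), values, "FS"), coverage


def read_disease_dags(
    path: str | Path, all_diseases: list[str] | tuple[str, ...]
) -> DiseaseDAGSet:
    """Read a (disease_id, child_term, parent_term) edge TSV into per-disease DAGs.

    Diseases listed in ``all_diseases`` but absent from the file are flagged
    as having no DAG.  Every disease's edge set must form a DAG in which each
    term has a directed path (parent -> child) to the disease term.
    """
    path = Path(path)
    edges: dict[str, list[tuple[str, str]]] = {}
    with path.open(encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3 or not all(fields):
                raise ParseError(
                    f"{path}:{lineno}: expected (disease, child, parent), got {line!r}"
                )
            disease, child, parent = fields
            edges.setdefault(disease, []).append((parent, child))
    graphs: dict[str, nx.DiGraph] = {}
    coverage: dict[str, bool] = {}
    for disease in all_diseases:
        if disease not in edges:
            coverage[disease] = False
            continue
        graph = nx.DiGraph()
        graph.add_node(disease)
        graph.add_edges_from(edges[disease])
        if disease not in graph:
            raise ParseError(
                f"{path}: edges for {disease!r} never reference the disease term"
            )
        if not nx.is_directed_acyclic_graph(graph):
            raise ParseError(f"{path}: cycle in the DAG of disease {disease!r}")
        reach_d = nx.ancestors(graph, disease) | {disease}
        if set(graph.nodes) - reach_d:
            stray = sorted(set(graph.nodes) - reach_d)[0]
            raise ParseError(
                f"{path}: term {stray!r} in the DAG of {disease!r} has no path "
                "to the disease term"
            )
        graphs[disease] = graph
        coverage[disease] = True
    for disease in edges:
        if disease not in coverage:
            raise ParseError(
                f"{path}: disease {disease!r} has edges but is not in the disease list"
            )
    return DiseaseDAGSet(graphs, coverage)


def write_disease_dags(dags: DiseaseDAGSet, path: str | Path) -> None:
    """Write per-disease DAG edges as a (disease_id, child, parent) TSV."""
    with Path(path).open("w", encoding="utf-8") as handle:
        for disease in dags.diseases:
            if not dags.coverage[disease]:
                continue
            for parent, child in sorted(dags.graphs[disease].edges):
                handle.write(f"{disease}\t{child}\t{parent}\n")


def write_score_table(
    scores: ScoreMatrix, path: str | Path, known_mask: AssociationMatrix
) -> None:
    """Write scores as long-format TSV (mirna, disease, score, is_known).

    Rows are grouped by disease in id order; within a disease they are sorted
    by descending score with lexicographic miRNA id as the tie-breaker.  The
    byte output is deterministic for fixed input.
    """
    if scores.values.shape != known_mask.values.shape:
        raise ValueError("score matrix and known mask shapes disagree")
    with Path(path).open("w", encoding="utf-8", newline="\n") as handle:
        for j, disease in enumerate(scores.disease_ids):
            order = sorted(
                range(len(scores.mirna_ids)),
                key=lambda i: (-scores.values[i, j], scores.mirna_ids[i]),
            )
            for i in order:
                handle.write(
                    f"{scores.mirna_ids[i]}\t{disease}\t"
                    f"{scores.values[i, j]:.6f}\t{int(known_mask.values[i, j])}\n"
                )
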