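"""Core domain types shared across the pipeline.

All matrix-carrying types validate their invariants on construction so that
downstream code can rely on them without re-checking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np

#: Roles a square similarity matrix may play in the pipeline.
SIMILARITY_ROLES = ("SS1", "SS2", "FS", "KD", "KM", "SD", "SM")

#: Absolute tolerance for symmetry of similarity matrices.
SYMMETRY_ATOL = 1e-9


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


@dataclass(frozen=True)
class AssociationMatrix:
    """Binary adjacency between ``nm`` miRNAs (rows) and ``nd`` diseases (columns)."""

    mirna_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise ValidationError("association matrix must be 2-dimensional")
        if values.shape != (len(self.mirna_ids), len(self.disease_ids)):
            raise ValidationError(
                f"shape {values.shape} does not match id lists "
                f"({len(self.mirna_ids)} miRNAs, {len(self.disease_ids)} diseases)"
            )
        if len(set(self.mirna_ids)) != len(self.mirna_ids):
            raise ValidationError("duplicate miRNA ids")
        if len(set(self.disease_ids)) != len(self.disease_ids):
            raise ValidationError("duplicate disease ids")
        if not np.isin(values, (0, 1)).all():
            raise ValidationError("association matrix entries must be 0 or 1")
        object.__setattr__(self, "values", values.astype(np.uint8))

    @property
    def nm(self) -> int:
        return len(self.mirna_ids)

    @property
    def nd(self) -> int:
        return len(self.disease_ids)

    @property
    def n_known(self) -> int:
        """Number of known (value 1) associations."""
        return int(self.values.sum())

    def known_pairs(self) -> list[tuple[int, int]]:
        """Index pairs ``(i, j)`` of the known associations, row-major order."""
        rows, cols = np.nonzero(self.values)
        return list(zip(rows.tolist(), cols.tolist()))

    def with_values(self, values: np.ndarray) -> "AssociationMatrix":
        """Copy of this matrix with replaced entries (same id ordering)."""
        return AssociationMatrix(self.mirna_ids, self.disease_ids, values)


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square symmetric matrix of pairwise similarities in ``[0, 1]``.

    ``role`` labels which similarity this is (semantic SS1/SS2, functional FS,
    Gaussian profile kernel KD/KM, or integrated SD/SM).  The diagonal must be
    exactly 1 for every role.
    """

    entity_ids: tuple[str, ...]
    values: np.ndarray
    role: str

    def __post_init__(self) -> None:
        if self.role not in SIMILARITY_ROLES:
            raise ValidationError(f"unknown similarity role {self.role!r}")
        values = np.asarray(self.values, dtype=float)
        n = len(self.entity_ids)
        if values.shape != (n, n):
            raise ValidationError(
                f"similarity matrix shape {values.shape} does not match {n} ids"
            )
        if len(set(self.entity_ids)) != n:
            raise ValidationError("duplicate entity ids")
        if np.isnan(values).any():
            i, j = np.argwhere(np.isnan(values))[0]
            raise ValidationError(f"NaN similarity at ({i}, {j})")
        asym = np.abs(values - values.T)
        if asym.max(initial=0.0) > SYMMETRY_ATOL:
            i, j = np.unravel_index(np.argmax(asym), asym.shape)
            raise ValidationError(
                f"asymmetry {asym[i, j]:.3g} at ({i}, {j}) exceeds {SYMMETRY_ATOL}"
            )
        if (values < 0).any() or (values > 1).any():
            bad = np.argwhere((values < 0) | (values > 1))[0]
            i, j = int(bad[0]), int(bad[1])
            raise ValidationError(
                f"similarity {values[i, j]!r} at ({i}, {j}) outside [0, 1]"
            )
        if not np.allclose(np.diag(values), 1.0, atol=1e-9):
            i = int(np.argmax(np.abs(np.diag(values) - 1.0)))
            raise ValidationError(f"diagonal entry {values[i, i]!r} at ({i}, {i}) != 1")
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return len(self.entity_ids)


@dataclass(frozen=True)
class DiseaseDAGSet:
    """Per-disease ancestor DAGs used for semantic similarity.

    ``graphs[d]`` is a directed graph with edges parent -> child whose node
    set is ``T(d)``: the disease term ``d`` plus all of its ancestors.  Every
    node has a directed path to ``d``.  ``coverage[d]`` is True when a DAG is
    available for disease ``d``.
    """

    graphs: Mapping[str, nx.DiGraph]
    coverage: Mapping[str, bool]

    def __post_init__(self) -> None:
        for disease, graph in self.graphs.items():
            if not self.coverage.get(disease, False):
                raise ValidationError(f"graph present for uncovered disease {disease!r}")
            if disease not in graph:
                raise ValidationError(f"disease term {disease!r} missing from its DAG")
            if not nx.is_directed_acyclic_graph(graph):
                raise ValidationError(f"cycle in DAG of disease {disease!r}")
            reach_d = nx.ancestors(graph, disease) | {disease}
            if set(graph.nodes) - reach_d:
                stray = sorted(set(graph.nodes) - reach_d)[0]
                raise ValidationError(
                    f"term {stray!r} in DAG of {disease!r} has no path to the disease"
                )

    def terms(self, disease: str) -> frozenset[str]:
        """The ancestor term set ``T(d)`` (including ``d`` itself)."""
        if not self.coverage.get(disease, False):
            raise KeyError(f"disease {disease!r} has no DAG")
        return frozenset(self.graphs[disease].nodes)

    def covered(self) -> list[str]:
        return [d for d, ok in self.coverage.items() if ok]

    @property
    def diseases(self) -> list[str]:
        return list(self.coverage)


@dataclass(frozen=True)
class ScoreMatrix:
    """Final nm x nd association scores with provenance of the two VAEs."""

    mirna_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]
    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.mirna_ids), len(self.disease_ids)):
            raise ValidationError("score matrix shape does not match id lists")
        if (values <= 0).any() or (values >= 1).any():
            raise ValidationError("association scores must lie strictly in (0, 1)")
        object.__setattr__(self, "values", values)
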