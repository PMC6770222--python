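"""Construction of the two spliced training matrices.

The miRNA-side matrix SSM concatenates the association matrix A with the
integrated miRNA similarity SM row-wise; the disease-side matrix SSD does
the same with A-transpose and the integrated disease similarity SD.  Each
spliced matrix carries a column map so downstream code can slice the
association block back out without re-deriving offsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import AssociationMatrix, SimilarityMatrix


@dataclass(frozen=True)
class SplicedFeatureMatrix:
    """A training matrix: association block followed by a similarity block."""

    values: np.ndarray
    side: str  # "miRNA" (SSM) or "disease" (SSD)
    n_assoc_cols: int
    row_ids: tuple[str, ...]
    assoc_col_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if self.side not in ("miRNA", "disease"):
            raise ValueError(f"unknown side {self.side!r}")
        if (values < 0).any() or (values > 1).any():
            raise ValueError("spliced matrix entries must lie in [0, 1]")
        assoc = values[:, : self.n_assoc_cols]
        if not np.isin(assoc, (0, 1)).all():
            raise ValueError("association block must be binary")
        object.__setattr__(self, "values", values)

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def association_block(self) -> np.ndarray:
        return self.values[:, : self.n_assoc_cols]

    @property
    def similarity_block(self) -> np.ndarray:
        return self.values[:, self.n_assoc_cols :]


def build_ssm(A: AssociationMatrix, SM: SimilarityMatrix) -> SplicedFeatureMatrix:
    """SSM: nm x (nd + nm); first nd columns are A, last nm columns are SM."""
    if SM.entity_ids != A.mirna_ids:
        raise ValueError("SM must be indexed identically to the miRNA axis of A")
    values = np.concatenate([A.values.astype(float), SM.values], axis=1)
    return SplicedFeatureMatrix(
        values, "miRNA", A.nd, A.mirna_ids, A.disease_ids
    )


def build_ssd(A: AssociationMatrix, SD: SimilarityMatrix) -> SplicedFeatureMatrix:
    """SSD: nd x (nm + nd); first nm columns are A-transpose, last nd are SD."""
    if SD.entity_ids != A.disease_ids:
        raise ValueError("SD must be indexed identically to the disease axis of A")
    values = np.concatenate([A.values.T.astype(float), SD.values], axis=1)
    return SplicedFeatureMatrix(
        values, "disease", A.nm, A.disease_ids, A.mirna_ids
    )
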