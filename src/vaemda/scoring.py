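"""Turn trained VAEs into association scores.

Inference is deterministic: each spliced row is encoded to its latent mean
(no sampling) and decoded; the association-block columns of the
reconstruction are the side's score block.  The miRNA-side and disease-side
blocks are averaged into the final score matrix.
"""

from __future__ import annotations

import numpy as np

from .datatypes import AssociationMatrix, ScoreMatrix
from .splicing import SplicedFeatureMatrix
from .vae import TrainedVAE, decode, encode


def reconstruct_side(model: TrainedVAE, data: SplicedFeatureMatrix) -> np.ndarray:
    """Deterministic reconstruction of the association block of ``data``.

    Returns an (n_rows x n_assoc_cols) block: nm x nd for the miRNA side,
    nd x nm for the disease side.
    """
    if model.input_dim != data.width:
        raise ValueError(
            f"model input_dim {model.input_dim} != spliced width {data.width}"
        )
    mu, _ = encode(model, data.values)
    x_hat = decode(model, mu)
    return x_hat[:, : data.n_assoc_cols]


def combine_scores(
    s1: np.ndarray,
    s2: np.ndarray,
    mirna_ids: tuple[str, ...],
    disease_ids: tuple[str, ...],
    provenance: dict | None = None,
) -> ScoreMatrix:
    """Average the miRNA-side block ``s1`` (nm x nd) with the transposed
    disease-side block ``s2`` (nd x nm)."""
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if s2.T.shape != s1.shape:
        raise ValueError(f"score block shapes disagree: {s1.shape} vs {s2.shape}^T")
    return ScoreMatrix(
        mirna_ids, disease_ids, (s1 + s2.T) / 2.0, provenance or {}
    )


def rank_candidates(
    scores: ScoreMatrix, known: AssociationMatrix, disease: str, k: int
) -> list[tuple[str, float]]:
    """Top-``k`` unknown miRNAs for one disease, by descending score.

    Ties break on lexicographic miRNA id.  Known associations are excluded.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if disease not in scores.disease_ids:
        raise KeyError(f"unknown disease id {disease!r}")
    if scores.mirna_ids != known.mirna_ids or scores.disease_ids != known.disease_ids:
        raise ValueError("score matrix and known mask are indexed differently")
    j = scores.disease_ids.index(disease)
    candidates = [
        (scores.mirna_ids[i], float(scores.values[i, j]))
        for i in range(len(scores.mirna_ids))
        if known.values[i, j] == 0
    ]
    candidates.sort(key=lambda item: (-item[1], item[0]))
    return candidates[:k]
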