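"""End-to-end orchestration shared by the CLI and the evaluation harness.

Given an association matrix (possibly with held-out entries zeroed), disease
DAGs and a functional-similarity matrix with coverage masks, this module
recomputes the profile-kernel similarities, re-integrates SD/SM, rebuilds
the spliced matrices, trains the two VAEs and produces the score matrix.
"""

from __future__ import annotations

import hashlib
from dataclasses import replace

import numpy as np

from .datatypes import AssociationMatrix, DiseaseDAGSet, ScoreMatrix, SimilarityMatrix
from .scoring import combine_scores, reconstruct_side
from .similarity import (
    DEFAULT_DELTA,
    DEFAULT_GAMMA_PRIME,
    gip_kernel,
    integrate_disease_similarity,
    integrate_mirna_similarity,
    semantic_similarity_model1,
    semantic_similarity_model2,
)
from .splicing import build_ssd, build_ssm
from .vae import TrainedVAE, VAEConfig, train_vae


def derive_seed(*parts) -> int:
    """Stable 32-bit seed derived from arbitrary labelled parts."""
    digest = hashlib.sha256(":".join(map(str, parts)).encode()).digest()
    return int.from_bytes(digest[:4], "big")


def compute_integrated_similarities(
    A: AssociationMatrix,
    dags: DiseaseDAGSet,
    fs: SimilarityMatrix,
    fs_coverage: np.ndarray,
    *,
    delta: float = DEFAULT_DELTA,
    gamma_prime: float = DEFAULT_GAMMA_PRIME,
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """(SD, SM) from the current association matrix and the static inputs.

    The profile kernels are always recomputed from ``A`` (this is what makes
    in-fold recomputation leak-free); the semantic similarities depend only
    on the DAGs and are recomputed here for simplicity since they are cheap
    relative to VAE training.
    """
    dag_coverage = np.array(
        [dags.coverage.get(d, False) for d in A.disease_ids], dtype=bool
    )
    kd = gip_kernel(A.values.T, A.disease_ids, "KD", gamma_prime)
    km = gip_kernel(A.values, A.mirna_ids, "KM", gamma_prime)
    ss1 = ss2 = None
    if dag_coverage.any():
        ss1 = semantic_similarity_model1(dags, delta)
        ss2 = semantic_similarity_model2(dags)
    sd = integrate_disease_similarity(ss1, ss2, kd, dag_coverage)
    sm = integrate_mirna_similarity(fs, km, np.asarray(fs_coverage, dtype=bool))
    return sd, sm


def predict_scores(
    A: AssociationMatrix,
    dags: DiseaseDAGSet,
    fs: SimilarityMatrix,
    fs_coverage: np.ndarray,
    vae_config: VAEConfig | None = None,
    *,
    seed: int = 0,
    delta: float = DEFAULT_DELTA,
    gamma_prime: float = DEFAULT_GAMMA_PRIME,
) -> ScoreMatrix:
    """Full pipeline: similarities -> spliced matrices -> two VAEs -> scores.

    ``vae_config.input_dim`` is overridden to the spliced width (nd + nm);
    the two VAEs get independent seeds derived from ``seed``.
    """
    sd, sm = compute_integrated_similarities(
        A, dags, fs, fs_coverage, delta=delta, gamma_prime=gamma_prime
    )
    ssm = build_ssm(A, sm)
    ssd = build_ssd(A, sd)
    if vae_config is None:
        vae_config = VAEConfig(input_dim=ssm.width)
    seed1 = derive_seed(seed, "vae1")
    seed2 = derive_seed(seed, "vae2")
    vae1 = train_vae(ssm, replace(vae_config, input_dim=ssm.width, seed=seed1))
    vae2 = train_vae(ssd, replace(vae_config, input_dim=ssd.width, seed=seed2))
    return scores_from_models(A, vae1, vae2, ssm, ssd, seed=seed)


def scores_from_models(
    A: AssociationMatrix,
    vae1: TrainedVAE,
    vae2: TrainedVAE,
    ssm,
    ssd,
    *,
    seed: int | None = None,
) -> ScoreMatrix:
    s1 = reconstruct_side(vae1, ssm)
    s2 = reconstruct_side(vae2, ssd)
    provenance = {
        "seed": seed,
        "vae1_seed": vae1.config.seed,
        "vae2_seed": vae2.config.seed,
    }
    return combine_scores(s1, s2, A.mirna_ids, A.disease_ids, provenance)
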