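"""Cross-validation schemes and rank-based ROC/AUC.

Supported schemes: global/local leave-one-out (one fold per known pair),
repeated k-fold over known pairs, and global/local leave-one-disease-out
(one fold per disease, holding out all of its known pairs).  Within every
fold the profile-kernel similarities are recomputed from the masked
association matrix, the integrated similarities and spliced matrices are
rebuilt, and both VAEs are retrained, so no held-out label leaks into
training.

Ranking convention: each held-out pair is compared against the pairs that
are unknown in the ORIGINAL association matrix (all of them globally, or
those of the pair's disease locally); rank = 1 + (# candidates scoring
higher) + 0.5 * (# ties).  The scheme-level AUC is the mean over test pairs
of (N - rank + 1) / N, which equals the Mann-Whitney tie-corrected AUC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .datatypes import AssociationMatrix, DiseaseDAGSet, SimilarityMatrix
from .pipeline import derive_seed, predict_scores
from .vae import TrainingDivergedError, VAEConfig

logger = logging.getLogger(__name__)

SCHEMES = ("global-LOOCV", "local-LOOCV", "kfold", "global-LODOCV", "local-LODOCV")


@dataclass(frozen=True)
class FoldSpec:
    """One cross-validation fold: the held-out known pairs and bookkeeping."""

    scheme: str
    test_pairs: tuple[tuple[int, int], ...]
    rep: int
    fold_index: int
    seed: int

    def train_matrix(self, A: AssociationMatrix) -> AssociationMatrix:
        """A with the held-out entries zeroed."""
        values = A.values.copy()
        for i, j in self.test_pairs:
            if values[i, j] != 1:
                raise ValueError(f"test pair ({i}, {j}) is not a known association")
            values[i, j] = 0
        return A.with_values(values)


@dataclass
class EvaluationResult:
    scheme: str
    auc: float
    rep_aucs: list[float]
    mean_auc: float
    std_auc: float
    std_defined: bool
    per_pair: list[dict] = field(default_factory=list)
    roc: list[tuple[float, float]] = field(default_factory=list)
    failed_folds: list[int] = field(default_factory=list)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "auc": self.auc,
            "rep_aucs": self.rep_aucs,
            "mean_auc": self.mean_auc,
            "std_auc": self.std_auc,
            "std_defined": self.std_defined,
            "n_test_pairs": len(self.per_pair),
            "failed_folds": self.failed_folds,
            "seed": self.seed,
            "per_pair": self.per_pair,
            "roc": [[float(x), float(y)] for x, y in self.roc],
        }


def make_folds(
    A: AssociationMatrix,
    scheme: str,
    k: int = 5,
    reps: int = 1,
    seed: int = 0,
) -> list[FoldSpec]:
    """Build the fold list for a scheme.

    LOOCV yields one fold per known pair; k-fold yields ``reps`` independent
    seeded partitions of the known pairs into ``k`` near-equal subsets;
    LODOCV yields one fold per disease with at least one known pair
    (diseases with none are skipped with a warning).
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    # Seeds depend only on the scheme family: global and local ranking share
    # the same folds and trained models, which keeps the single-disease
    # equivalence between local and global AUC exact.
    base = scheme.split("-")[-1]
    pairs = A.known_pairs()
    if not pairs:
        raise ValueError("association matrix has no known pairs")
    folds: list[FoldSpec] = []
    if scheme in ("global-LOOCV", "local-LOOCV"):
        for idx, pair in enumerate(pairs):
            folds.append(
                FoldSpec(scheme, (pair,), 0, idx, derive_seed(seed, base, 0, idx))
            )
    elif scheme == "kfold":
        if k < 2:
            raise ValueError("k must be >= 2")
        for rep in range(reps):
            rng = np.random.default_rng(derive_seed(seed, base, rep, "partition"))
            order = rng.permutation(len(pairs))
            # Near-equal subsets: the first (len % k) folds get one extra pair.
            splits = np.array_split(order, k)
            for fold_index, split in enumerate(splits):
                test = tuple(pairs[i] for i in split)
                folds.append(
                    FoldSpec(
                        scheme, test, rep, fold_index,
                        derive_seed(seed, base, rep, fold_index),
                    )
                )
    else:  # LODOCV
        for j, disease in enumerate(A.disease_ids):
            test = tuple((int(i), j) for i in np.nonzero(A.values[:, j])[0])
            if not test:
                warnings.warn(
                    f"disease {disease!r} has no known associations; fold skipped"
                )
                continue
            folds.append(
                FoldSpec(scheme, test, 0, j, derive_seed(seed, base, 0, j))
            )
    return folds


def run_fold(
    A: AssociationMatrix,
    fold: FoldSpec,
    dags: DiseaseDAGSet,
    fs: SimilarityMatrix,
    fs_coverage: np.ndarray,
    vae_config: VAEConfig | None = None,
):
    """Retrain the full pipeline on the fold's masked matrix and score all pairs."""
    if not fold.test_pairs:
        raise ValueError("fold has an empty test set")
    masked = fold.train_matrix(A)
    return predict_scores(
        masked, dags, fs, fs_coverage, vae_config, seed=fold.seed
    )


def rank_test_pairs(
    scores: np.ndarray,
    A_original: AssociationMatrix,
    test_pairs: tuple[tuple[int, int], ...],
    mode: str,
) -> list[tuple[float, int]]:
    """Midranks of the test pairs among the unknown pairs of the original A.

    Returns (rank, n_candidates) per test pair.  ``mode`` is "global" (all
    unknown pairs) or "local" (unknown pairs of the test pair's disease).
    Candidates are always drawn from the ORIGINAL matrix, so held-out
    positives from the same fold are never counted as negatives.
    """
    if mode not in ("global", "local"):
        raise ValueError(f"mode must be 'global' or 'local', got {mode!r}")
    scores = np.asarray(scores, dtype=float)
    unknown = A_original.values == 0
    out: list[tuple[float, int]] = []
    if mode == "global":
        cand_scores = scores[unknown]
        for i, j in test_pairs:
            out.append((_midrank(scores[i, j], cand_scores), cand_scores.size))
    else:
        for i, j in test_pairs:
            cand_scores = scores[unknown[:, j], j]
            out.append((_midrank(scores[i, j], cand_scores), cand_scores.size))
    return out


def _midrank(test_score: float, candidate_scores: np.ndarray) -> float:
    higher = int((candidate_scores > test_score).sum())
    ties = int((candidate_scores == test_score).sum())
    return 1.0 + higher + 0.5 * ties


def auc_from_ranks(ranks_and_counts: list[tuple[float, int]]) -> float:
    """Mean over test pairs of the fraction of candidates they outrank."""
    if not ranks_and_counts:
        raise ValueError("no ranks to aggregate")
    fracs = [(n - rank + 1.0) / n for rank, n in ranks_and_counts]
    return float(np.mean(fracs))


def roc_auc(test_scores, candidate_scores) -> EvaluationResult:
    """ROC curve and AUC for one pooled scoring of tests vs candidates.

    The AUC is the Mann-Whitney statistic P(test > candidate) + 0.5 P(tie);
    the ROC curve is a threshold sweep over the pooled scores and its
    trapezoidal area equals the AUC exactly.
    """
    test_scores = np.asarray(test_scores, dtype=float)
    candidate_scores = np.asarray(candidate_scores, dtype=float)
    if test_scores.size == 0 or candidate_scores.size == 0:
        raise ValueError("test and candidate score lists must be nonempty")
    nt, nc = test_scores.size, candidate_scores.size

    pooled = np.concatenate([test_scores, candidate_scores])
    ranks = rankdata(pooled)  # midranks
    auc = (ranks[:nt].sum() - nt * (nt + 1) / 2) / (nt * nc)

    # Threshold sweep: descending unique scores, tie groups collapsed.
    order = np.argsort(-pooled, kind="stable")
    labels = np.concatenate([np.ones(nt), np.zeros(nc)])[order]
    sorted_scores = pooled[order]
    tp = np.cumsum(labels)
    fp = np.cumsum(1 - labels)
    distinct = np.nonzero(np.diff(sorted_scores))[0]
    idx = np.append(distinct, len(pooled) - 1)
    roc = [(0.0, 0.0)] + [
        (fp[i] / nc, tp[i] / nt) for i in idx
    ]
    fpr = np.array([p[0] for p in roc])
    tpr = np.array([p[1] for p in roc])
    area = float(np.trapezoid(tpr, fpr))
    if abs(area - auc) > 1e-9:  # pragma: no cover - internal consistency guard
        raise AssertionError(f"trapezoid area {area} != Mann-Whitney AUC {auc}")
    return EvaluationResult(
        scheme="pooled",
        auc=float(auc),
        rep_aucs=[float(auc)],
        mean_auc=float(auc),
        std_auc=0.0,
        std_defined=False,
        roc=roc,
    )


def aggregate(rep_aucs: list[float]) -> tuple[float, float, bool]:
    """(mean, sample std, std_defined) over per-repetition AUCs."""
    if not rep_aucs:
        raise ValueError("no repetition AUCs")
    mean = float(np.mean(rep_aucs))
    if len(rep_aucs) < 2:
        return mean, 0.0, False
    return mean, float(np.std(rep_aucs, ddof=1)), True


def evaluate_scheme(
    A: AssociationMatrix,
    dags: DiseaseDAGSet,
    fs: SimilarityMatrix,
    fs_coverage: np.ndarray,
    scheme: str,
    *,
    k: int = 5,
    reps: int = 1,
    seed: int = 0,
    subsample: int | None = None,
    vae_config: VAEConfig | None = None,
) -> EvaluationResult:
    """Run a full cross-validation scheme and aggregate the AUC.

    ``subsample`` evaluates only a seeded random subset of folds (useful for
    leave-one-out schemes, which otherwise retrain two VAEs per known pair).
    """
    folds = make_folds(A, scheme, k=k, reps=reps, seed=seed)
    if subsample is not None and subsample < len(folds):
        rng = np.random.default_rng(derive_seed(seed, scheme.split("-")[-1], "subsample"))
        keep = sorted(rng.choice(len(folds), size=subsample, replace=False).tolist())
        folds = [folds[i] for i in keep]
    mode = "local" if scheme.startswith("local") else "global"

    per_pair: list[dict] = []
    failed: list[int] = []
    by_rep: dict[int, list[tuple[float, int]]] = {}
    for fold in folds:
        try:
            scores = run_fold(A, fold, dags, fs, fs_coverage, vae_config)
        except TrainingDivergedError as exc:
            logger.warning("fold %d failed: %s", fold.fold_index, exc)
            failed.append(fold.fold_index)
            continue
        ranked = rank_test_pairs(scores.values, A, fold.test_pairs, mode)
        by_rep.setdefault(fold.rep, []).extend(ranked)
        for (i, j), (rank, n_cand) in zip(fold.test_pairs, ranked):
            per_pair.append(
                {
                    "mirna": A.mirna_ids[i],
                    "disease": A.disease_ids[j],
                    "score": float(scores.values[i, j]),
                    "rank": rank,
                    "n_candidates": n_cand,
                    "rep": fold.rep,
                    "fold": fold.fold_index,
                }
            )
    if not by_rep:
        raise RuntimeError("every fold failed; no AUC can be computed")
    rep_aucs = [auc_from_ranks(by_rep[rep]) for rep in sorted(by_rep)]
    mean, std, std_defined = aggregate(rep_aucs)
    all_ranks = [r for ranked in by_rep.values() for r in ranked]
    # Plotting curve: TPR at each normalized-rank threshold, FPR ~ threshold.
    norm = np.sort([rank / n for rank, n in all_ranks])
    roc = [(0.0, 0.0)] + [
        (float(t), float(np.mean(norm <= t))) for t in norm
    ] + [(1.0, 1.0)]
    return EvaluationResult(
        scheme=scheme,
        auc=auc_from_ranks(all_ranks),
        rep_aucs=rep_aucs,
        mean_auc=mean,
        std_auc=std,
        std_defined=std_defined,
        per_pair=per_pair,
        roc=roc,
        failed_folds=failed,
        seed=seed,
    )
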