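"""Comparison baselines: relevance analysis and NMF metagene ranking.

Relevance analysis ranks features by the mutual information between the
feature profile and the phenotype profile.  The NMF baseline factorizes
the (filtered) binary matrix into nonnegative metagenes ``V ~ W H`` with
``k`` typically equal to the number of phenotypes, assigns the metagene
with the higher mean expression in the target class to that phenotype,
and ranks features by their coefficient in that metagene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from logicmine.errors import ValidationError
from logicmine.logic import mutual_information_from_counts


@dataclass
class RankedFeatureList:
    """Feature ids ordered by non-increasing score."""

    feature_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValidationError("scores must be non-increasing")

    def top(self, k: int) -> list[str]:
        return self.feature_ids[:k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.feature_ids) + 1),
                "feature": self.feature_ids,
                "score": self.scores,
            }
        )


def mi_rank(m: pd.DataFrame, pheno_row: np.ndarray) -> RankedFeatureList:
    """Rank features by I(feature; phenotype) in bits, descending.

    Ties keep the matrix row order (stable sort), making output
    deterministic; a feature and its negation score identically.
    """
    c = np.asarray(pheno_row).astype(np.uint8)
    if c.min() == c.max():
        raise ValidationError("phenotype row is constant")
    M = m.to_numpy().astype(np.uint8)
    if M.shape[1] != c.size:
        raise ValidationError("matrix and phenotype have different specimen counts")
    n = M.shape[1]
    na = M.sum(axis=1, dtype=np.int64)
    n11 = M @ c.astype(np.int64)
    mi = mutual_information_from_counts(n11, na, int(c.sum()), n)
    order = np.argsort(-mi, kind="stable")
    return RankedFeatureList(
        feature_ids=[str(m.index[i]) for i in order], scores=mi[order]
    )


def filter_sparse_rows(m: pd.DataFrame, min_ones: int = 1) -> pd.DataFrame:
    """Drop rows with fewer than ``min_ones`` ones (NMF feasibility filter)."""
    keep = m.to_numpy().sum(axis=1) >= min_ones
    return m.loc[m.index[keep]]


def _nnls_rows(B: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Solve min ||B x - v||, x >= 0 for every column v of V (exact NNLS)."""
    out = np.empty((B.shape[1], V.shape[1]))
    for j in range(V.shape[1]):
        out[:, j], _ = nnls(B, V[:, j])
    return out


def nmf_rank(
    m: pd.DataFrame,
    k: int,
    target_columns: np.ndarray | list | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
    rng: np.random.Generator | int | None = None,
) -> tuple[RankedFeatureList, np.ndarray, np.ndarray, list[float]]:
    """Nonnegative factorization V ~ W H by alternating exact NNLS.

    Each half-step solves its nonnegative least-squares subproblem to
    optimality, so the squared reconstruction residual is non-increasing
    across iterations.  Features are ranked by their coefficient in the
    phenotype-associated metagene: the metagene whose H row has the higher
    mean over ``target_columns`` (boolean mask or column indices); without
    a target, metagene 0 is used.

    Returns (ranking, W, H, residual trace).
    """
    V = m.to_numpy().astype(np.float64)
    f, s = V.shape
    if k >= min(f, s):
        raise ValidationError(f"k={k} must be smaller than both matrix dimensions {V.shape}")
    if (V.sum(axis=1) == 0).any():
        raise ValidationError("matrix has all-zero rows; filter_sparse_rows first")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    W = rng.random((f, k)) + 0.1
    H = rng.random((k, s)) + 0.1
    residuals: list[float] = []
    prev = np.inf
    for _ in range(max_iter):
        H = _nnls_rows(W, V)
        W = _nnls_rows(H.T, V.T).T
        # guard against dead metagenes (all-zero column of W)
        dead = W.sum(axis=0) == 0
        if dead.any():
            W[:, dead] = rng.random((f, int(dead.sum()))) * 1e-3
        res = float(np.linalg.norm(V - W @ H))
        residuals.append(res)
        if prev - res < tol:
            break
        prev = res
    else:
        warnings.warn(f"NMF did not converge in {max_iter} iterations; residual {res:.6g}")
    if target_columns is None:
        metagene = 0
    else:
        idx = np.asarray(target_columns)
        cols = idx if idx.dtype != bool else np.where(idx)[0]
        metagene = int(np.argmax(H[:, cols].mean(axis=1)))
    scores = W[:, metagene]
    order = np.argsort(-scores, kind="stable")
    ranking = RankedFeatureList(
        feature_ids=[str(m.index[i]) for i in order], scores=scores[order]
    )
    return ranking, W, H, residuals
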