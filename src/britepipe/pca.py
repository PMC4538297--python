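"""Sample-space principal component analysis of expression profiles.

Samples are the observations and probes the variables, so the scores are
sample coordinates — the representation used to compare culture
conditions globally. Rows are median-centered first (the centering the
profiling pipeline applies to log2 values); within ``pca_scores`` each
probe is additionally mean-centered so that constant probe offsets have
no effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .beadarray import ExpressionMatrix


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x k, columns PC1..PCk
    variance_fractions: np.ndarray  # all components, nonincreasing, sums to 1
    k: int


def median_center(m: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each probe's (row) median; output row medians are 0."""
    if m.scale != "log2":
        raise ValueError("median_center expects a log2-scale matrix")
    med = m.data.median(axis=1, skipna=True)
    return ExpressionMatrix(m.data.sub(med, axis=0), scale="log2")


def pca_scores(m: ExpressionMatrix, k: int = 2) -> PCAResult:
    """SVD-based PCA with samples as observations.

    Variance fraction i is the i-th eigenvalue of the sample covariance
    over the eigenvalue total (all components). Component signs are fixed
    by making the largest-magnitude probe loading positive. Requesting
    more components than the matrix rank is an error.
    """
    X = m.data.to_numpy(dtype=float).T  # samples x probes
    if np.isnan(X).any():
        raise ValueError("PCA input must not contain missing values")
    X = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    tol = s.max() * max(X.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int(np.sum(s > tol))
    if k > rank:
        raise ValueError(f"k={k} exceeds matrix rank {rank}")
    # deterministic sign: largest-|loading| entry of each component positive
    for i in range(rank):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    lam = s**2
    frac = lam / lam.sum() if lam.sum() > 0 else lam
    scores = U[:, :k] * s[:k]
    df = pd.DataFrame(
        scores, index=m.sample_ids, columns=[f"PC{i+1}" for i in range(k)]
    )
    return PCAResult(scores=df, variance_fractions=frac, k=k)
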