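"""Reference linear projections: PCA (unsupervised) and LDA (supervised).

These are the baselines the evolutionary projection is compared against.  PCA
maximizes retained variance and is blind to labels, so it fails when the class
signal lives on low-variance directions; LDA maximizes the between- to
within-class scatter ratio but is restricted to at most C-1 output dimensions.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg

from .evolve import TransformationMatrix

__all__ = ["pca_projection", "lda_projection"]


def _fix_signs(W: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|entry| of each column positive."""
    W = W.copy()
    for j in range(W.shape[1]):
        i = int(np.argmax(np.abs(W[:, j])))
        if W[i, j] < 0:
            W[:, j] = -W[:, j]
    return W


def pca_projection(features: np.ndarray, d_out: int) -> TransformationMatrix:
    """Top-``d_out`` principal directions of the centered feature matrix.

    Computed by singular-value decomposition; columns are the leading right
    singular vectors of ``X - mean(X)``.
    """
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("features must be 2-D")
    n, d = X.shape
    if n <= d_out:
        raise ValueError("need more samples than output dimensions")
    Xc = X - X.mean(axis=0)
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(n, d) * np.finfo(float).eps)) if s.size else 0
    if d_out > rank:
        raise ValueError(f"d_out={d_out} exceeds data rank {rank}")
    W = _fix_signs(Vt[:d_out].T)
    return TransformationMatrix(W=W, provenance={"method": "pca", "d_out": d_out})


def lda_projection(
    features: np.ndarray,
    labels: np.ndarray,
    ridge: float | None = None,
) -> TransformationMatrix:
    """Fisher discriminant directions; ``d_out = C - 1`` for C classes.

    Columns are the leading eigenvectors of ``Sw^{-1} Sb``.  If the
    within-class scatter ``Sw`` is singular, a ridge term ``ridge * I`` must be
    supplied; otherwise an error is raised.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    classes = np.unique(y)
    C = classes.size
    if C < 2:
        raise ValueError("LDA requires at least two classes")
    d = X.shape[1]
    mean = X.mean(axis=0)
    Sw = np.zeros((d, d))
    Sb = np.zeros((d, d))
    for c in classes:
        Xc = X[y == c]
        mc = Xc.mean(axis=0)
        diff = Xc - mc
        Sw += diff.T @ diff
        dm = (mc - mean)[:, None]
        Sb += Xc.shape[0] * (dm @ dm.T)
    if ridge is not None:
        Sw = Sw + ridge * np.eye(d)
    # Solve the generalized symmetric problem Sb v = lambda Sw v.
    try:
        evals, evecs = scipy.linalg.eigh(Sb, Sw)
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError) as exc:
        raise ValueError(
            "within-class scatter is singular; pass a ridge value"
        ) from exc
    order = np.argsort(evals)[::-1][: C - 1]
    W = _fix_signs(evecs[:, order])
    return TransformationMatrix(
        W=W, provenance={"method": "lda", "d_out": C - 1, "ridge": ridge}
    )
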