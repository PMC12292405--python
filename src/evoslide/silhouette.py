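"""Silhouette score used as the fitness of the evolutionary projection search.

The silhouette contrasts, for each sample *i*, the mean distance ``a_i`` to the
other members of its own cluster with the smallest mean distance ``b_i`` to any
other cluster::

    S = mean_i (b_i - a_i) / max(a_i, b_i)

Conventions for degenerate cases (needed because the zero projection matrix is
reachable during evolution):

* a singleton cluster member contributes ``s_i = 0``;
* if ``max(a_i, b_i) = 0`` (all points involved coincide) then ``s_i = 0``.

Distances are Euclidean.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["silhouette"]


def silhouette(points: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette coefficient of ``points`` under cluster ``labels``.

    Parameters
    ----------
    points : (n, d) array
        Sample coordinates; a 1-D array is treated as n points in 1-D.
    labels : (n,) array
        Cluster assignment for every point.  At least two distinct clusters,
        each non-empty, are required.

    Returns
    -------
    float in [-1, 1].

    Raises
    ------
    ValueError
        If fewer than two points, fewer than two clusters, or mismatched
        shapes are supplied.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim == 1:
        pts = pts[:, None]
    if pts.ndim != 2:
        raise ValueError("points must be a 2-D array (n samples x d features)")
    lab = np.asarray(labels)
    n = pts.shape[0]
    if lab.shape != (n,):
        raise ValueError("labels must be one per point")
    if n < 2:
        raise ValueError("silhouette requires at least two points")
    uniq, inv, counts = np.unique(lab, return_inverse=True, return_counts=True)
    k = uniq.size
    if k < 2:
        raise ValueError("silhouette undefined for a single cluster")

    if not np.isfinite(pts).all():
        raise ValueError("points contain non-finite values")

    dist = cdist(pts, pts)
    # Sum of distances from each point to every cluster: (n, k).
    onehot = np.zeros((n, k))
    onehot[np.arange(n), inv] = 1.0
    sums = dist @ onehot

    own = counts[inv]
    with np.errstate(invalid="ignore", divide="ignore"):
        a = sums[np.arange(n), inv] / np.maximum(own - 1, 1)
    # Mean distance to each *other* cluster; own column masked out.
    mean_other = sums / counts[None, :]
    mean_other[np.arange(n), inv] = np.inf
    b = mean_other.min(axis=1)

    denom = np.maximum(a, b)
    s = np.zeros(n)
    ok = denom > 0
    s[ok] = (b[ok] - a[ok]) / denom[ok]
    s[own == 1] = 0.0  # singleton convention
    return float(s.mean())
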