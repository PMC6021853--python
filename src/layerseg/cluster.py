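"""1-D mean-shift clustering used for probability and gradient values.

Mean shift finds the modes of a kernel density estimate, so the number of
clusters is determined by the data and the kernel bandwidth rather than fixed
in advance.  When no bandwidth is supplied it is estimated from the sample
with scikit-learn's quantile-based rule, which is deterministic for a given
sample.
"""

from __future__ import annotations

import numpy as np
from sklearn.cluster import MeanShift, estimate_bandwidth

__all__ = ["mean_shift_1d", "nearest_centroid"]


def mean_shift_1d(
    values: np.ndarray,
    bandwidth: float | None = None,
    quantile: float = 0.07,
) -> np.ndarray:
    """Cluster scalar values with mean shift; return the mode (centroid) values.

    Returns the sorted (ascending) unique cluster centroids.  Degenerate
    inputs (fewer than two distinct values, or a vanishing estimated
    bandwidth) yield a single centroid at the sample mean.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("cannot cluster an empty set of values")
    if np.ptp(x) == 0:
        return np.array([x[0]])
    if bandwidth is None:
        bandwidth = estimate_bandwidth(x.reshape(-1, 1), quantile=quantile)
    if not np.isfinite(bandwidth) or bandwidth <= 0:
        # the quantile rule degenerates when nearest neighbours are exact
        # duplicates; fall back to Silverman's rule of thumb
        iqr = float(np.subtract(*np.percentile(x, [75, 25])))
        scale = min(x.std(), iqr / 1.34) or float(x.std())
        bandwidth = 0.9 * scale * x.size ** -0.2
    if not np.isfinite(bandwidth) or bandwidth <= 0:
        return np.array([float(x.mean())])
    ms = MeanShift(bandwidth=bandwidth).fit(x.reshape(-1, 1))
    centroids = np.unique(ms.cluster_centers_[:, 0])
    return centroids


def nearest_centroid(values: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Index (into ``centroids``) of the closest centroid for each value."""
    v = np.asarray(values, dtype=float).ravel()
    c = np.asarray(centroids, dtype=float).ravel()
    return np.abs(v[:, None] - c[None, :]).argmin(axis=1)
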