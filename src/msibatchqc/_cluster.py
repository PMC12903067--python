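"""Shared spherical k-means helper.

Cosine-distance k-means is realized as Euclidean k-means on L2-normalized
rows (the two are equivalent up to a constant for unit vectors), which is
how segmentation and the multivariate evaluation both cluster pixel spectra.
"""

from __future__ import annotations

import numpy as np
from sklearn.cluster import KMeans


def spherical_kmeans(
    x: np.ndarray, k: int, seed: int | None = 0, replicates: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster rows of *x* by cosine similarity.

    Rows are L2-normalized and clustered with Euclidean k-means using
    ``replicates`` restarts (best inertia kept). Zero rows are not allowed.

    Returns ``(labels, centroids)`` with centroids on the unit sphere scale.
    """
    x = np.asarray(x, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > x.shape[0]:
        raise ValueError(f"k={k} exceeds number of rows {x.shape[0]}")
    norms = np.linalg.norm(x, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero rows cannot be clustered by cosine distance")
    xn = x / norms[:, None]
    km = KMeans(n_clusters=k, n_init=replicates, random_state=seed)
    labels = km.fit_predict(xn)
    return labels, km.cluster_centers_
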