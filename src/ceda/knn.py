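"""Nearest-neighbor classification with a documented tie rule.

The adaptive classifier of the pipeline is a plain 1-nearest-neighbor rule
in Euclidean distance.  Ties are broken deterministically in favor of the
lowest training-point index, which keeps every downstream result
reproducible bit-for-bit.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["knn1_predict"]


def knn1_predict(
    train_points: np.ndarray,
    train_labels: np.ndarray,
    query_points: np.ndarray,
) -> np.ndarray:
    """Label each query with the label of its nearest training point.

    Euclidean distance; ties go to the lowest training-point index.
    """
    Xtr = np.asarray(train_points, dtype=float)
    Q = np.asarray(query_points, dtype=float)
    y = np.asarray(train_labels)
    if Xtr.ndim != 2 or Q.ndim != 2:
        raise ValueError("train and query points must be 2-D matrices")
    if Xtr.shape[0] == 0:
        raise ValueError("empty training set")
    if y.shape != (Xtr.shape[0],):
        raise ValueError("train_labels length does not match train_points")
    if Xtr.shape[1] != Q.shape[1]:
        raise ValueError(
            f"dimension mismatch: train d={Xtr.shape[1]}, query d={Q.shape[1]}"
        )
    dist = cdist(Q, Xtr, metric="euclidean")
    nearest = np.argmin(dist, axis=1)  # argmin returns the first (lowest) index
    return y[nearest]
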