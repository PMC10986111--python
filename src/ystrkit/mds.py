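"""Classical (Torgerson) multidimensional scaling of a distance matrix.

Given a symmetric dissimilarity matrix D (here: pairwise FST between
populations, negatives clamped to zero upstream), double-centre the
squared distances, B = -1/2 J D^2 J with J = I - 11'/k, eigendecompose,
and take coordinates v_i * sqrt(lambda_i) along the top-m positive
eigenvalues. When D is exactly Euclidean-embeddable in m dimensions the
embedding reproduces it to numerical precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError

__all__ = ["MdsEmbedding", "classical_mds"]


@dataclass
class MdsEmbedding:
    """Coordinates (k x m), all k eigenvalues (descending), fit quality.

    ``goodness`` is the proportion of positive-eigenvalue mass captured by
    the retained m axes.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    goodness: float

    @property
    def m(self) -> int:
        return self.coordinates.shape[1]


def classical_mds(matrix, m: int = 2, labels=None) -> MdsEmbedding:
    """Torgerson MDS of a symmetric non-negative dissimilarity matrix.

    ``matrix`` may be a labelled DataFrame or a plain array. ``m`` must be
    <= k-1. Axis signs are fixed by forcing the largest-magnitude
    coordinate of each axis positive, so plots are deterministic. An
    all-zero matrix embeds every point at the origin (not an error).
    """
    if isinstance(matrix, pd.DataFrame):
        labels = list(matrix.index) if labels is None else list(labels)
        D = matrix.to_numpy(dtype=float)
    else:
        D = np.asarray(matrix, dtype=float)
    k = D.shape[0]
    if D.shape != (k, k):
        raise ValidationError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValidationError("distance matrix must be symmetric")
    if np.any(D < -1e-12):
        raise ValidationError("negative dissimilarities; clamp before MDS")
    if not 1 <= m <= k - 1:
        raise ConfigError(f"embedding dimension m={m} must satisfy 1 <= m <= k-1")
    if labels is None:
        labels = [f"pop{i}" for i in range(k)]

    D2 = D * D
    J = np.eye(k) - np.ones((k, k)) / k
    B = -0.5 * J @ D2 @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    coords = np.zeros((k, m))
    for axis in range(m):
        lam = evals[axis]
        if lam > 1e-12:
            coords[:, axis] = evecs[:, axis] * np.sqrt(lam)
    # deterministic axis orientation
    for axis in range(m):
        col = coords[:, axis]
        if col.any() and col[np.argmax(np.abs(col))] < 0:
            coords[:, axis] = -col

    pos = evals[evals > 1e-12]
    captured = float(np.sum(np.clip(evals[:m], 0.0, None)))
    goodness = captured / float(pos.sum()) if pos.size else 1.0
    frame = pd.DataFrame(
        coords, index=labels, columns=[f"dim{i + 1}" for i in range(m)]
    )
    return MdsEmbedding(coordinates=frame, eigenvalues=evals, goodness=goodness)
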