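"""LCMV (linearly constrained minimum variance) source projection.

For a vertex with 3-column leadfield L (sensors x 3 orientations) and sensor
covariance S, the spatial filter

    W = (L^T S^-1 L)^-1 L^T S^-1,      S^-1 ~ (S + lambda I)^-1,

minimizes projected source power subject to unit gain at the vertex
(W L = I).  The 3 orientation time courses Y = W X are collapsed onto one
series by projecting on the leading eigenvector of W S W^dagger.  Intended
for toy-scale leadfields; head-model construction is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

__all__ = [
    "Leadfield",
    "BeamformerWeights",
    "compute_weights",
    "project_and_collapse",
    "project_rois",
]


@dataclass
class Leadfield:
    """Leadfield matrix G (sensors x 3*vertices) with per-vertex 3-column blocks."""

    G: np.ndarray

    def __post_init__(self) -> None:
        self.G = np.atleast_2d(np.asarray(self.G, dtype=float))
        if self.G.shape[1] % 3 != 0:
            raise ValueError("leadfield column count must be a multiple of 3")

    @property
    def n_sensors(self) -> int:
        return self.G.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.G.shape[1] // 3

    def block(self, j: int) -> np.ndarray:
        """3-column leadfield of vertex j (sensors x 3)."""
        return self.G[:, 3 * j : 3 * j + 3]


@dataclass
class BeamformerWeights:
    """Unit-gain spatial filter for one vertex (3 x sensors)."""

    W: np.ndarray
    lam: float
    collapse_vector: np.ndarray | None = None


def compute_weights(
    L: np.ndarray,
    Sigma: np.ndarray,
    lam: float = 1e-7,
    trace_scaled: bool = False,
) -> BeamformerWeights:
    """LCMV weights for one vertex.

    ``lam`` is an additive ridge on the sensor covariance; with
    ``trace_scaled`` it multiplies mean(trace(Sigma))/k instead of being
    absolute.  Raises for rank-deficient leadfield blocks.
    """
    L = np.atleast_2d(np.asarray(L, dtype=float))
    Sigma = np.asarray(Sigma)
    k = Sigma.shape[0]
    if Sigma.shape != (k, k) or L.shape[0] != k:
        raise ValueError("dimension mismatch between leadfield and covariance")
    if np.linalg.matrix_rank(L) < L.shape[1]:
        raise ValueError("rank-deficient leadfield block")
    ridge = lam * (np.trace(Sigma).real / k) if trace_scaled else lam
    Sreg = Sigma + ridge * np.eye(k)
    Sinv_L = linalg.solve(Sreg, L, assume_a="pos")
    M = L.T.conj() @ Sinv_L                      # 3 x 3
    W = linalg.solve(M, Sinv_L.T.conj())          # 3 x k
    gain = W @ L
    if not np.allclose(gain, np.eye(L.shape[1]), atol=1e-8):
        raise AssertionError("unit-gain constraint violated")
    return BeamformerWeights(W=np.asarray(W), lam=float(lam))


def _collapse_vector(W: np.ndarray, Sigma: np.ndarray) -> np.ndarray:
    """Leading eigenvector of W Sigma W^dagger with a deterministic sign.

    Sign fixed so that the largest-magnitude component is positive; the sign
    only affects the phase of the collapsed series, not any magnitude or
    fourth-order statistic.
    """
    P = W @ Sigma @ W.T.conj()
    vals, vecs = np.linalg.eigh(P)
    v = vecs[:, -1]
    pivot = np.argmax(np.abs(v))
    if v[pivot].real < 0 or (v[pivot].real == 0 and v[pivot].imag < 0):
        v = -v
    return v


def project_and_collapse(
    X: np.ndarray,
    weights: BeamformerWeights,
    Sigma: np.ndarray | None = None,
) -> np.ndarray:
    """Project sensor data through W and collapse the 3 orientations.

    ``Y = W X`` (3 x samples); the output is ``v^dagger Y`` with ``v`` the
    leading eigenvector of W Sigma W^dagger (Sigma defaults to the empirical
    covariance X X^dagger / n).  Linear in X.
    """
    X = np.atleast_2d(np.asarray(X))
    W = weights.W
    if X.shape[0] != W.shape[1]:
        raise ValueError("sensor count mismatch")
    if Sigma is None:
        Sigma = X @ X.T.conj() / X.shape[1]
    v = _collapse_vector(W, Sigma)
    weights.collapse_vector = v
    Y = W @ X
    return v.conj() @ Y


def project_rois(
    X: np.ndarray,
    leadfield: Leadfield,
    roi_labels,
    lam: float = 1e-7,
) -> tuple[np.ndarray, list]:
    """One collapsed time series per region of interest.

    ``roi_labels`` maps each vertex to a label; per ROI the vertex leadfield
    blocks are horizontally stacked, reduced to 3 effective columns via SVD
    (dominant spatial subspace), and run through the same unit-gain +
    eigen-collapse pipeline.
    """
    X = np.atleast_2d(np.asarray(X))
    labels = np.asarray(roi_labels)
    if labels.size != leadfield.n_vertices:
        raise ValueError("one ROI label per vertex required")
    Sigma = X @ X.T.conj() / X.shape[1]
    uniq = [l for l in dict.fromkeys(labels.tolist())]
    out = np.empty((len(uniq), X.shape[1]), dtype=complex)
    for i, lab in enumerate(uniq):
        idx = np.flatnonzero(labels == lab)
        Lroi = np.hstack([leadfield.block(j) for j in idx])
        if Lroi.shape[1] > 3:
            U, s, _ = np.linalg.svd(Lroi, full_matrices=False)
            Lroi = U[:, :3] * s[:3]
        w = compute_weights(Lroi, Sigma, lam=lam)
        out[i] = project_and_collapse(X, w, Sigma)
    return out, uniq
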