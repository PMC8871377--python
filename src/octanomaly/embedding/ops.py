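"""Hypersphere feature operations: L2-Norm + Scale and the constrained softmax loss.

The embedding is trained so that every feature lies on a hypersphere of
radius ``alpha``: the raw backbone descriptor f(x) is L2-normalized and
rescaled (``alpha * f / ||f||``) before the final affine classification
layer.  Fixing the feature norm removes the "easy" way for softmax to
lower its loss (inflating the norm of easy samples) and instead tightens
classes in angular space, which is what makes the features a good
reference population for density-based outlier scoring.
"""

from __future__ import annotations

import numpy as np

NORM_RTOL = 1e-5


class ZeroFeatureError(ValueError):
    """Raised when a raw feature vector is (numerically) zero.

    A zero vector has no direction, so its projection onto the alpha-sphere
    is undefined; surfacing this explicitly catches dead backbones instead
    of propagating NaNs.
    """


def l2_norm_scale(raw_feature: np.ndarray, alpha: float) -> np.ndarray:
    """Project raw feature vectors onto the sphere of radius ``alpha``.

    Accepts a single vector or a matrix of row vectors; the output has the
    same shape with every (row) vector of Euclidean norm ``alpha``.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    f = np.asarray(raw_feature, dtype=np.float64)
    single = f.ndim == 1
    f2 = np.atleast_2d(f)
    norms = np.linalg.norm(f2, axis=1)
    if np.any(norms < 1e-12):
        raise ZeroFeatureError("cannot project a zero feature vector onto the sphere")
    out = alpha * f2 / norms[:, None]
    return out[0] if single else out


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-probability of the true class (log-sum-exp stable)."""
    z = np.atleast_2d(np.asarray(logits, dtype=np.float64))
    y = np.asarray(labels, dtype=np.intp).ravel()
    zmax = z.max(axis=1, keepdims=True)
    lse = zmax[:, 0] + np.log(np.exp(z - zmax).sum(axis=1))
    return float(np.mean(lse - z[np.arange(len(y)), y]))


def l2_softmax_loss(
    features: np.ndarray,
    labels: np.ndarray,
    W: np.ndarray,
    b: np.ndarray,
    alpha: float,
    norm_rtol: float = NORM_RTOL,
) -> float:
    """Softmax cross-entropy over logits ``W^T f + b`` for on-sphere features.

    ``features`` is M x d with every row of norm ``alpha`` (checked — a
    violation means the L2-Norm layer is missing upstream), ``W`` is d x C
    and ``b`` length C.  Returns a scalar >= 0; equals ``log C`` whenever
    all logits are equal (e.g. ``W = 0, b = 0``).
    """
    F = np.atleast_2d(np.asarray(features, dtype=np.float64))
    y = np.asarray(labels, dtype=np.intp).ravel()
    W = np.asarray(W, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64).ravel()
    if F.shape[0] != y.shape[0]:
        raise ValueError("features and labels disagree in length")
    if W.shape != (F.shape[1], b.shape[0]):
        raise ValueError(f"W must be d x C = {F.shape[1]} x {b.shape[0]}, got {W.shape}")
    C = b.shape[0]
    if np.any((y < 0) | (y >= C)):
        raise ValueError("labels must lie in {0, ..., C-1}")
    norms = np.linalg.norm(F, axis=1)
    if np.any(np.abs(norms - alpha) > norm_rtol * alpha):
        worst = float(np.max(np.abs(norms - alpha)))
        raise ValueError(
            f"feature norms deviate from alpha={alpha} by up to {worst:.3g}; "
            "apply l2_norm_scale before the loss"
        )
    return softmax_cross_entropy(F @ W + b, y)
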