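"""Shape similarity between reporter-cDNA and input-insert coverage curves.

A genuine silencer depletes the reporter curve while the insert curve keeps
its shape, so over a candidate window the two curves should be dissimilar.
Four metrics are supported: cosine distance, Euclidean distance, Pearson
correlation, and gradient similarity (Pearson correlation of the two
curves' finite-difference slopes). One threshold is applied on a common
"higher = more similar" score scale:

    cosine    -> 1 - distance
    euclidean -> 1 / (1 + distance)
    pearson   -> the correlation
    gradient  -> the correlation

Windows whose score exceeds the threshold (default 0.9) look too much like
their input and are discarded. The reported similarity index is
-log2(cosine distance): larger index = more similar curves.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "METRICS",
    "CoverageCurve",
    "SimilarityResult",
    "cosine_distance",
    "euclidean_distance",
    "pearson_correlation",
    "gradient_similarity",
    "similarity_index",
    "compute_similarity",
    "passes_similarity",
]

METRICS = ("cosine", "euclidean", "pearson", "gradient")


@dataclass(frozen=True)
class CoverageCurve:
    """Coverage y sampled at strictly increasing genomic positions x."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=np.float64)
        y = np.asarray(self.y, dtype=np.float64)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if len(x) != len(y):
            raise ValueError("x and y must have equal length")
        if len(x) < 2:
            raise ValueError("curve needs at least 2 points")
        if np.any(np.diff(x) <= 0):
            raise ValueError("x must be strictly increasing")


@dataclass(frozen=True)
class SimilarityResult:
    metric: str
    raw_value: float          # the metric's native value (distance or correlation)
    similarity_score: float   # common higher-is-more-similar scale
    similarity_index: float   # -log2(cosine distance); inf when distance is 0


def cosine_distance(u, v) -> float:
    """1 − cosine similarity of the two count vectors.

    An all-zero vector makes the cosine undefined; the distance is then
    reported as the maximum 1.0 (a reporter curve depleted to zero is the
    strongest silencer signal and must not be discarded on a technicality).
    """
    u, v = _pair(u, v)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        warnings.warn("all-zero vector in cosine distance; returning 1.0")
        return 1.0
    d = 1.0 - float(np.dot(u, v)) / (nu * nv)
    # clamp float noise around exactly parallel vectors
    return min(max(d, 0.0), 2.0)


def euclidean_distance(u, v) -> float:
    u, v = _pair(u, v)
    return float(np.linalg.norm(u - v))


def pearson_correlation(u, v) -> float:
    """Product-moment correlation; zero-variance input yields 0 with a warning."""
    u, v = _pair(u, v)
    if len(u) < 2:
        raise ValueError("need at least 2 points for a correlation")
    du = u - u.mean()
    dv = v - v.mean()
    su = float(np.dot(du, du))
    sv = float(np.dot(dv, dv))
    if su == 0.0 or sv == 0.0:
        warnings.warn("zero-variance vector in Pearson correlation; returning 0.0")
        return 0.0
    r = float(np.dot(du, dv)) / math.sqrt(su * sv)
    return min(max(r, -1.0), 1.0)


def gradient_similarity(curve_u: CoverageCurve, curve_v: CoverageCurve) -> float:
    """Pearson correlation of the two curves' slopes G(i) = Δy/Δx.

    Both curves must be sampled on the same x grid of length >= 3. Adding a
    constant to either curve's y does not change its gradients, so this
    metric ignores depth offsets and compares shape only.
    """
    if len(curve_u.x) != len(curve_v.x) or np.any(curve_u.x != curve_v.x):
        raise ValueError("curves must share one x grid")
    if len(curve_u.x) < 3:
        raise ValueError("need at least 3 points so gradients have length >= 2")
    gu = np.diff(curve_u.y) / np.diff(curve_u.x)
    gv = np.diff(curve_v.y) / np.diff(curve_v.x)
    return pearson_correlation(gu, gv)


def similarity_index(distance: float) -> float:
    """−log2(cosine distance); +inf at distance 0 (identical shapes)."""
    if distance < 0:
        raise ValueError("distance must be >= 0")
    if distance == 0.0:
        return math.inf
    return -math.log2(distance)


def compute_similarity(
    curve_u: CoverageCurve, curve_v: CoverageCurve, metric: str = "cosine"
) -> SimilarityResult:
    """Evaluate one metric on a pair of curves and map it to the common scale."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if metric == "cosine":
        raw = cosine_distance(curve_u.y, curve_v.y)
        score = 1.0 - raw
    elif metric == "euclidean":
        raw = euclidean_distance(curve_u.y, curve_v.y)
        score = 1.0 / (1.0 + raw)
    elif metric == "pearson":
        raw = pearson_correlation(curve_u.y, curve_v.y)
        score = raw
    else:
        raw = gradient_similarity(curve_u, curve_v)
        score = raw
    cos_d = raw if metric == "cosine" else cosine_distance(curve_u.y, curve_v.y)
    return SimilarityResult(
        metric=metric,
        raw_value=raw,
        similarity_score=score,
        similarity_index=similarity_index(cos_d),
    )


def passes_similarity(
    window_curves: tuple[CoverageCurve, CoverageCurve],
    metric: str = "cosine",
    threshold: float = 0.9,
) -> bool:
    """True when the window should be kept (score <= threshold).

    A score above the threshold means the reporter curve tracks the input
    curve too closely to be a silencer, so the window is discarded.
    """
    res = compute_similarity(window_curves[0], window_curves[1], metric)
    return not res.similarity_score > threshold


def _pair(u, v) -> tuple[np.ndarray, np.ndarray]:
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError("expected two 1-D arrays of equal length")
    return u, v
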