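"""Spatial distances, kernel weights and bandwidth selection.

Each regression location i gets a diagonal weight matrix W(u_i, v_i) whose
entries decay with the distance from location i to every other location.
The kernel family and bandwidth are user choices; the gaussian kernel with a
fixed bandwidth is the default because it never produces zero-weight rows at
small n. An adaptive bandwidth resolves, per location, to the distance of the
k-th nearest neighbour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .exceptions import (
    BandwidthSelectionError,
    DegenerateWeightsError,
    GwnrError,
    InvalidInputError,
)

__all__ = [
    "Coordinates",
    "WeightScheme",
    "pairwise_distance",
    "kernel_weights",
    "resolve_bandwidth",
    "select_bandwidth",
    "EARTH_RADIUS_KM",
]

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0

KERNELS = ("gaussian", "bisquare", "tricube")
METRICS = ("euclidean", "haversine")


@dataclass(frozen=True)
class Coordinates:
    """Planar or geographic coordinates of the n spatial units."""

    u: np.ndarray
    v: np.ndarray
    metric: str = "euclidean"

    def __post_init__(self):
        u = np.asarray(self.u, dtype=float).ravel()
        v = np.asarray(self.v, dtype=float).ravel()
        if u.size != v.size:
            raise InvalidInputError("u and v must have equal length")
        if u.size < 2:
            raise InvalidInputError("at least two locations are required")
        if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
            raise InvalidInputError("coordinates must be finite")
        if self.metric not in METRICS:
            raise InvalidInputError(f"metric must be one of {METRICS}, got {self.metric!r}")
        if self.metric == "haversine":
            if np.any(np.abs(u) > 180) or np.any(np.abs(v) > 90):
                raise InvalidInputError(
                    "haversine expects lon in [-180, 180] and lat in [-90, 90]"
                )
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "v", v)

    @property
    def n(self) -> int:
        return self.u.size


@dataclass(frozen=True)
class WeightScheme:
    """Kernel family plus either a fixed bandwidth or an adaptive rank k.

    Exactly one of ``bandwidth`` (a distance) and ``adaptive_k`` (a neighbour
    count, >= 2) must be set.
    """

    kernel: str = "gaussian"
    bandwidth: float | None = None
    adaptive_k: int | None = None

    def __post_init__(self):
        if self.kernel not in KERNELS:
            raise InvalidInputError(f"kernel must be one of {KERNELS}, got {self.kernel!r}")
        if (self.bandwidth is None) == (self.adaptive_k is None):
            raise InvalidInputError("set exactly one of bandwidth and adaptive_k")
        if self.bandwidth is not None and not (
            np.isfinite(self.bandwidth) and self.bandwidth > 0
        ):
            raise InvalidInputError(f"bandwidth must be positive, got {self.bandwidth}")
        if self.adaptive_k is not None and (
            int(self.adaptive_k) != self.adaptive_k or self.adaptive_k < 2
        ):
            raise InvalidInputError(f"adaptive_k must be an integer >= 2, got {self.adaptive_k}")


def _haversine_matrix(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    lam = np.radians(lon)
    phi = np.radians(lat)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = np.sin(dphi / 2) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2
    a = np.clip(a, 0.0, 1.0)
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def pairwise_distance(coords: Coordinates) -> np.ndarray:
    """Symmetric n x n distance matrix (great-circle km under haversine)."""
    if coords.metric == "euclidean":
        d = squareform(pdist(np.column_stack([coords.u, coords.v])))
    else:
        d = _haversine_matrix(coords.u, coords.v)
    np.fill_diagonal(d, 0.0)
    off = d[~np.eye(coords.n, dtype=bool)]
    if np.any(off == 0.0):
        logger.info("duplicated coordinates detected (%d zero off-diagonal distances)",
                    int(np.sum(off == 0.0)) // 2)
    return d


def resolve_bandwidth(d_row: np.ndarray, scheme: WeightScheme) -> float:
    """Scalar bandwidth for one location (k-th nearest distance if adaptive)."""
    if scheme.bandwidth is not None:
        return float(scheme.bandwidth)
    d_sorted = np.sort(np.asarray(d_row, dtype=float))
    b = float(d_sorted[scheme.adaptive_k - 1])  # position 0 is the point itself
    if b <= 0:
        raise InvalidInputError(
            f"adaptive bandwidth resolved to {b}; increase adaptive_k beyond duplicated points"
        )
    return b


def kernel_weights(d_row, scheme: WeightScheme, location: int = -1) -> np.ndarray:
    """Diagonal of W(u_i, v_i) from one row of the distance matrix.

    gaussian: exp(-(d/b)^2 / 2); bisquare: (1-(d/b)^2)^2 for d < b else 0;
    tricube: (1-(d/b)^3)^3 for d < b else 0. Weight 1 at distance 0, and
    non-increasing in distance.
    """
    d = np.asarray(d_row, dtype=float)
    if np.any(d < 0) or not np.all(np.isfinite(d)):
        raise InvalidInputError("distances must be finite and non-negative")
    b = resolve_bandwidth(d, scheme)
    if scheme.kernel == "gaussian":
        w = np.exp(-0.5 * (d / b) ** 2)
    elif scheme.kernel == "bisquare":
        w = np.where(d < b, (1 - (d / b) ** 2) ** 2, 0.0)
    else:  # tricube
        w = np.where(d < b, (1 - (d / b) ** 3) ** 3, 0.0)
    if not np.any(w > 0):
        raise DegenerateWeightsError(location)
    return w


def select_bandwidth(data, spec, candidates: Sequence[float]):
    """Pick the bandwidth minimizing the leave-one-out CV score.

    For each candidate, every location i is refit with its own weight w_ii
    forced to zero and the squared prediction errors are summed. Ties go to
    the larger bandwidth (the smoother model). Candidates for which any
    local fit is degenerate are skipped; if all are, selection fails.
    """
    from dataclasses import replace

    from .fitting import loo_cv_score

    candidates = sorted(float(b) for b in candidates)
    if not candidates:
        raise InvalidInputError("candidate bandwidth grid is empty")
    best_b, best_score = None, np.inf
    for b in candidates:
        scheme = replace(spec.weights, bandwidth=b, adaptive_k=None)
        try:
            score = loo_cv_score(data, replace(spec, weights=scheme))
        except GwnrError:
            logger.info("bandwidth %g degenerate, skipped", b)
            continue
        if score < best_score or (score == best_score and best_b is not None and b > best_b):
            best_b, best_score = b, score
    if best_b is None:
        raise BandwidthSelectionError("every candidate bandwidth was degenerate")
    return best_b
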