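"""Model specification and design-matrix construction for a spatial dataset.

A :class:`SpatialDataset` holds the response, the predictors split by role
(spline vs fourier) and the coordinates. A :class:`ModelSpec` holds the basis
hyperparameters shared by the global and the geographically weighted fits,
the spatial weight scheme, and the test level alpha.

Knots default to sample quantiles of each spline predictor at equispaced
levels (R knots at levels 1/(R+1), ..., R/(R+1)); explicit knot vectors
override the rule per predictor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .basis import (
    DesignMatrix,
    FourierSpec,
    SplineSpec,
    assemble_design,
    fourier_block,
    spline_block,
)
from .exceptions import InvalidInputError
from .weights import Coordinates, WeightScheme

__all__ = ["ModelSpec", "SpatialDataset", "build_design", "resolve_spline_specs"]


@dataclass(frozen=True)
class ModelSpec:
    """Basis hyperparameters, weight scheme and significance level.

    Parameters
    ----------
    degree
        Truncated-spline degree M, shared by all spline predictors.
    n_knots
        Number of quantile knots R per spline predictor (ignored for
        predictors with an explicit entry in ``knots``).
    knots
        Optional explicit knot vectors, one sequence per spline predictor
        (``None`` entries fall back to the quantile rule).
    harmonics
        Number of cosine harmonics H per fourier predictor.
    rescale_fourier
        If True, affinely map each fourier predictor onto [0, 2*pi] before
        building its cosine block. Off by default: periodic predictors are
        used in raw units.
    weights
        Spatial kernel and bandwidth.
    alpha
        Significance level for the goodness-of-fit test.
    """

    degree: int = 1
    n_knots: int = 1
    knots: tuple | None = None
    harmonics: int = 1
    rescale_fourier: bool = False
    weights: WeightScheme = field(default_factory=lambda: WeightScheme(kernel="gaussian", bandwidth=0.5))
    alpha: float = 0.05

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise InvalidInputError(f"alpha must lie in (0, 1), got {self.alpha}")
        if int(self.degree) != self.degree or self.degree < 1:
            raise InvalidInputError(f"degree must be a positive integer, got {self.degree}")
        if int(self.n_knots) != self.n_knots or self.n_knots < 0:
            raise InvalidInputError(f"n_knots must be a non-negative integer, got {self.n_knots}")
        if self.knots is not None:
            object.__setattr__(
                self,
                "knots",
                tuple(None if k is None else tuple(float(t) for t in k) for k in self.knots),
            )

    @property
    def fourier_spec(self) -> FourierSpec:
        return FourierSpec(self.harmonics)

    def design_width(self, n_spline: int, n_fourier: int) -> int:
        return 2 + n_spline * (self.degree + self.n_knots) + n_fourier * (1 + self.harmonics)


@dataclass(frozen=True)
class SpatialDataset:
    """Response, role-split predictors and coordinates for n spatial units."""

    y: np.ndarray
    spline_predictors: np.ndarray  # n x P (P may be 0)
    fourier_predictors: np.ndarray  # n x Q (Q may be 0)
    coords: Coordinates
    spline_names: tuple[str, ...] = ()
    fourier_names: tuple[str, ...] = ()

    def __post_init__(self):
        y = np.asarray(self.y, dtype=float).ravel()
        xs = np.asarray(self.spline_predictors, dtype=float)
        zs = np.asarray(self.fourier_predictors, dtype=float)
        if xs.size == 0:
            xs = xs.reshape(y.size, 0)
        if zs.size == 0:
            zs = zs.reshape(y.size, 0)
        if xs.ndim == 1:
            xs = xs[:, None]
        if zs.ndim == 1:
            zs = zs[:, None]
        for name, arr in (("y", y), ("spline_predictors", xs), ("fourier_predictors", zs)):
            if not np.all(np.isfinite(arr)):
                raise InvalidInputError(f"{name} contains missing or non-finite values")
        if xs.shape[0] != y.size or zs.shape[0] != y.size or self.coords.n != y.size:
            raise InvalidInputError("response, predictors and coordinates disagree on n")
        if xs.shape[1] + zs.shape[1] < 1:
            raise InvalidInputError("at least one predictor is required")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "spline_predictors", xs)
        object.__setattr__(self, "fourier_predictors", zs)
        if not self.spline_names:
            object.__setattr__(self, "spline_names", tuple(f"x{p + 1}" for p in range(xs.shape[1])))
        if not self.fourier_names:
            object.__setattr__(self, "fourier_names", tuple(f"z{q + 1}" for q in range(zs.shape[1])))

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def n_spline(self) -> int:
        return self.spline_predictors.shape[1]

    @property
    def n_fourier(self) -> int:
        return self.fourier_predictors.shape[1]


def quantile_knots(x: np.ndarray, n_knots: int) -> tuple[float, ...]:
    """R knots at equispaced quantile levels 1/(R+1), ..., R/(R+1)."""
    if n_knots == 0:
        return ()
    levels = np.arange(1, n_knots + 1) / (n_knots + 1)
    return tuple(float(t) for t in np.quantile(np.asarray(x, dtype=float), levels))


def resolve_spline_specs(data: SpatialDataset, spec: ModelSpec) -> list[SplineSpec]:
    """One SplineSpec per spline predictor, with knots resolved."""
    specs = []
    for p in range(data.n_spline):
        explicit = None
        if spec.knots is not None and p < len(spec.knots):
            explicit = spec.knots[p]
        if explicit is not None:
            knots = tuple(float(t) for t in explicit)
        else:
            knots = quantile_knots(data.spline_predictors[:, p], spec.n_knots)
        specs.append(SplineSpec(degree=spec.degree, knots=knots))
    return specs


def build_design(data: SpatialDataset, spec: ModelSpec) -> DesignMatrix:
    """Assemble the mixed design matrix Q* for a dataset under a model spec."""
    spline_specs = resolve_spline_specs(data, spec)
    f_spec = spec.fourier_spec
    s_blocks = [
        spline_block(data.spline_predictors[:, p], spline_specs[p]) for p in range(data.n_spline)
    ]
    z_blocks = []
    for q in range(data.n_fourier):
        z = data.fourier_predictors[:, q]
        if spec.rescale_fourier:
            lo, hi = z.min(), z.max()
            if hi > lo:
                z = 2 * np.pi * (z - lo) / (hi - lo)
        z_blocks.append(fourier_block(z, f_spec))
    return assemble_design(
        s_blocks,
        z_blocks,
        spline_specs=spline_specs,
        fourier_specs=[f_spec] * data.n_fourier,
        spline_names=data.spline_names,
        fourier_names=data.fourier_names,
    )
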