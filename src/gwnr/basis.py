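"""Mixed truncated-power-spline + Fourier-series basis.

The mixed nonparametric regression family models the response as a sum of
per-predictor smooth components: spline-role predictors enter through a
truncated power basis of degree ``M`` with ``R`` interior knots
(``x, x^2, ..., x^M, (x - t_1)_+^M, ..., (x - t_R)_+^M``), while
periodic-role predictors enter through a linear term plus cosine harmonics
(``z, cos z, cos 2z, ..., cos Hz``). Both the global model and its
geographically weighted extension share one design matrix, assembled here:

    [ 1 | spline block_1 ... spline block_P | 1/2 | fourier block_1 ... fourier block_Q ]

with width ``m = 2 + P (M + R) + Q (1 + H)``. The constant 1/2 column carries
the free constant of the Fourier part, so the fitted periodic component reads
``(1/2) theta_0 + gamma z + sum_h theta_h cos(h z)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import InvalidInputError

__all__ = [
    "SplineSpec",
    "FourierSpec",
    "DesignMatrix",
    "truncated_power",
    "spline_block",
    "fourier_block",
    "assemble_design",
]


@dataclass(frozen=True)
class SplineSpec:
    """Truncated-power-spline hyperparameters for one predictor.

    Parameters
    ----------
    degree
        Polynomial degree ``M`` (also the power of the truncated terms), >= 1.
    knots
        Strictly increasing knot locations, in the units of the predictor.
        May be empty, in which case the block is a plain degree-``M`` polynomial.
    """

    degree: int
    knots: tuple[float, ...] = ()

    def __post_init__(self):
        if int(self.degree) != self.degree or self.degree < 1:
            raise InvalidInputError(f"spline degree must be a positive integer, got {self.degree}")
        knots = tuple(float(t) for t in self.knots)
        if not all(np.isfinite(knots)):
            raise InvalidInputError("knots must be finite")
        if any(b <= a for a, b in zip(knots, knots[1:])):
            raise InvalidInputError(f"knots must be strictly increasing, got {knots}")
        object.__setattr__(self, "knots", knots)

    @property
    def n_columns(self) -> int:
        return self.degree + len(self.knots)


@dataclass(frozen=True)
class FourierSpec:
    """Cosine-series hyperparameters for one periodic predictor.

    ``harmonics`` is the number of cosine terms ``H`` >= 0; with ``H = 0``
    the block reduces to the linear term alone.
    """

    harmonics: int = 1

    def __post_init__(self):
        if int(self.harmonics) != self.harmonics or self.harmonics < 0:
            raise InvalidInputError(
                f"harmonics must be a non-negative integer, got {self.harmonics}"
            )

    @property
    def n_columns(self) -> int:
        return 1 + self.harmonics


@dataclass(frozen=True)
class DesignMatrix:
    """The shared n x m design matrix with labelled columns."""

    values: np.ndarray
    column_labels: tuple[str, ...] = field(default=())

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise InvalidInputError("design matrix must be two-dimensional")
        if not np.all(np.isfinite(values)):
            raise InvalidInputError("design matrix contains non-finite entries")
        if len(self.column_labels) != values.shape[1]:
            raise InvalidInputError("one label per design column is required")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "column_labels", tuple(self.column_labels))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]


def truncated_power(x, t: float, degree: int):
    """Evaluate the truncated power function ``(x - t)_+^M``.

    Zero for ``x <= t`` and ``(x - t)^M`` above the knot; continuous with
    ``M - 1`` continuous derivatives at ``t``. Vectorized over ``x``.
    """
    if int(degree) != degree or degree < 1:
        raise InvalidInputError(f"degree must be a positive integer, got {degree}")
    x = np.asarray(x, dtype=float)
    if not (np.all(np.isfinite(x)) and np.isfinite(t)):
        raise InvalidInputError("truncated_power requires finite x and t")
    out = np.where(x > t, x - t, 0.0) ** degree
    return float(out) if out.ndim == 0 else out


def spline_block(x, spec: SplineSpec) -> np.ndarray:
    """Columns ``x, x^2, ..., x^M, (x - t_1)_+^M, ..., (x - t_R)_+^M``.

    A knot outside the closed range of ``x`` is allowed but flagged with a
    warning, since it yields a zero or collinear column.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 1:
        raise InvalidInputError("spline_block requires at least one observation")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("spline_block requires finite x")
    lo, hi = x.min(), x.max()
    for t in spec.knots:
        if not (lo < t < hi):
            warnings.warn(
                f"knot {t} lies outside the open range ({lo}, {hi}) of its predictor; "
                "the resulting column is zero or collinear",
                stacklevel=2,
            )
    cols = [x**p for p in range(1, spec.degree + 1)]
    cols += [truncated_power(x, t, spec.degree) for t in spec.knots]
    return np.column_stack(cols)


def fourier_block(z, spec: FourierSpec) -> np.ndarray:
    """Columns ``z, cos(z), cos(2 z), ..., cos(H z)`` (radians)."""
    z = np.asarray(z, dtype=float).ravel()
    if not np.all(np.isfinite(z)):
        raise InvalidInputError("fourier_block requires finite z")
    cols = [z] + [np.cos(h * z) for h in range(1, spec.harmonics + 1)]
    return np.column_stack(cols)


def _spline_labels(name: str, spec: SplineSpec) -> list[str]:
    labels = [name if p == 1 else f"{name}^{p}" for p in range(1, spec.degree + 1)]
    labels += [f"({name}-{t:g})+^{spec.degree}" for t in spec.knots]
    return labels


def _fourier_labels(name: str, spec: FourierSpec) -> list[str]:
    return [name] + [f"cos({h}{name})" if h > 1 else f"cos({name})" for h in range(1, spec.harmonics + 1)]


def assemble_design(
    spline_blocks: Sequence[np.ndarray],
    fourier_blocks: Sequence[np.ndarray],
    spline_specs: Sequence[SplineSpec] = (),
    fourier_specs: Sequence[FourierSpec] = (),
    spline_names: Sequence[str] | None = None,
    fourier_names: Sequence[str] | None = None,
) -> DesignMatrix:
    """Stack per-predictor basis blocks into the mixed design matrix.

    Column order is ``[1, spline blocks..., 1/2, fourier blocks...]``; the
    width obeys ``m = 2 + P (M + R) + Q (1 + H)``. Rank deficiency is not
    checked here (it is a fit-time error).
    """
    if len(spline_blocks) + len(fourier_blocks) < 1:
        raise InvalidInputError("at least one predictor block is required")
    sizes = {np.asarray(b).shape[0] for b in list(spline_blocks) + list(fourier_blocks)}
    if len(sizes) != 1:
        raise InvalidInputError(f"blocks disagree on n: {sorted(sizes)}")
    n = sizes.pop()

    spline_names = list(spline_names or (f"x{p + 1}" for p in range(len(spline_blocks))))
    fourier_names = list(fourier_names or (f"z{q + 1}" for q in range(len(fourier_blocks))))

    parts = [np.ones((n, 1))]
    labels = ["intercept"]
    for p, block in enumerate(spline_blocks):
        block = np.asarray(block, dtype=float)
        parts.append(block)
        if p < len(spline_specs):
            labels += _spline_labels(spline_names[p], spline_specs[p])
        else:
            labels += [f"{spline_names[p]}[{j}]" for j in range(block.shape[1])]
    parts.append(np.full((n, 1), 0.5))
    labels.append("half")
    for q, block in enumerate(fourier_blocks):
        block = np.asarray(block, dtype=float)
        parts.append(block)
        if q < len(fourier_specs):
            labels += _fourier_labels(fourier_names[q], fourier_specs[q])
        else:
            labels += [f"{fourier_names[q]}[{j}]" for j in range(block.shape[1])]
    return DesignMatrix(np.hstack(parts), tuple(labels))
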