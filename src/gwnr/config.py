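"""Run configuration: column roles, model hyperparameters, I/O settings.

A run config comes from a YAML key-value file, optionally overridden by CLI
flags. It names the response column, the spline-role and fourier-role
predictor columns and the coordinate columns, and carries every ModelSpec
and WeightScheme field plus alpha, seed and output settings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import InvalidInputError
from .model import ModelSpec, SpatialDataset
from .weights import Coordinates, WeightScheme

__all__ = ["RunConfig", "load_config", "load_dataset", "write_json_report"]


@dataclass(frozen=True)
class RunConfig:
    """Validated description of one fit/test run."""

    data: str
    response: str
    spline: tuple[str, ...]
    fourier: tuple[str, ...]
    u: str = "u"
    v: str = "v"
    metric: str = "euclidean"
    degree: int = 1
    n_knots: int = 1
    knots: tuple | None = None
    harmonics: int = 1
    rescale_fourier: bool = False
    kernel: str = "gaussian"
    bandwidth: float | None = None
    adaptive_k: int | None = None
    alpha: float = 0.05
    decimal_comma: bool = False
    outdir: str = "."
    seed: int = 0
    verbosity: str = "INFO"

    def __post_init__(self):
        roles = list(self.spline) + list(self.fourier) + [self.response, self.u, self.v]
        dupes = {c for c in roles if roles.count(c) > 1}
        if dupes:
            raise InvalidInputError(f"columns assigned to more than one role: {sorted(dupes)}")
        if not (0 < self.alpha < 1):
            raise InvalidInputError(f"alpha must lie in (0, 1), got {self.alpha}")
        if len(self.spline) + len(self.fourier) < 1:
            raise InvalidInputError("at least one predictor column is required")
        object.__setattr__(self, "spline", tuple(self.spline))
        object.__setattr__(self, "fourier", tuple(self.fourier))

    def model_spec(self) -> ModelSpec:
        if self.bandwidth is None and self.adaptive_k is None:
            raise InvalidInputError("set a bandwidth or adaptive_k (or run bandwidth selection)")
        scheme = WeightScheme(
            kernel=self.kernel, bandwidth=self.bandwidth, adaptive_k=self.adaptive_k
        )
        return ModelSpec(
            degree=self.degree,
            n_knots=self.n_knots,
            knots=self.knots,
            harmonics=self.harmonics,
            rescale_fourier=self.rescale_fourier,
            weights=scheme,
            alpha=self.alpha,
        )


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Read a YAML run config; keyword overrides win over file values."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise InvalidInputError(f"config file {path} must hold a mapping")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    known = RunConfig.__dataclass_fields__
    unknown = set(raw) - set(known)
    if unknown:
        raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def load_dataset(cfg: RunConfig) -> SpatialDataset:
    """Read the CSV named in the config and split columns by role."""
    path = Path(cfg.data)
    if not path.exists():
        raise InvalidInputError(f"data file not found: {path}")
    decimal = "," if cfg.decimal_comma else "."
    # round_trip float parsing: re-reading our own reports must be lossless
    df = pd.read_csv(path, decimal=decimal, float_precision="round_trip")
    needed = [cfg.response, *cfg.spline, *cfg.fourier, cfg.u, cfg.v]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise InvalidInputError(f"missing columns in {path}: {missing}")
    for c in needed:
        col = pd.to_numeric(df[c], errors="coerce")
        bad = df.index[col.isna()].tolist()
        if bad:
            raise InvalidInputError(f"non-numeric or missing cells in column {c!r}, rows {bad[:10]}")
        df[c] = col
    coords = Coordinates(u=df[cfg.u].to_numpy(), v=df[cfg.v].to_numpy(), metric=cfg.metric)
    return SpatialDataset(
        y=df[cfg.response].to_numpy(),
        spline_predictors=df[list(cfg.spline)].to_numpy() if cfg.spline else np.empty((len(df), 0)),
        fourier_predictors=df[list(cfg.fourier)].to_numpy() if cfg.fourier else np.empty((len(df), 0)),
        coords=coords,
        spline_names=cfg.spline,
        fourier_names=cfg.fourier,
    )


def _round_floats(obj, sig: int = 10):
    if isinstance(obj, float):
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    return obj


def write_json_report(payload: dict, path: str | Path) -> None:
    """Serialize a report with floats fixed to 10 significant digits.

    Two runs with identical config therefore produce byte-identical files.
    """
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_round_floats(payload), fh, indent=2, sort_keys=True)
        fh.write("\n")
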