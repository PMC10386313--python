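"""Unit-variance (autoscaling) preprocessing tolerant of missing entries.

The scaler is fitted on calibration samples only — per-variable mean and
standard deviation over *observed* entries — and then applied to any matrix
with the same variables, so validation data never leak into the fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import ProfileMatrix


class ScalingError(ValueError):
    pass


@dataclass
class Scaler:
    """Per-variable centering and scaling record."""

    center: np.ndarray
    scale: np.ndarray
    var_names: list[str]
    fitted_on: list[str]

    def to_dict(self) -> dict:
        return {
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "var_names": self.var_names,
            "fitted_on": self.fitted_on,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Scaler":
        return cls(
            center=np.asarray(d["center"], float),
            scale=np.asarray(d["scale"], float),
            var_names=list(d["var_names"]),
            fitted_on=list(d["fitted_on"]),
        )


def fit_scaler(matrix: ProfileMatrix, sample_ids: Sequence[str] | None = None) -> Scaler:
    """Fit autoscaling statistics on the observed cells of a sample subset.

    Each variable needs at least two observed entries and non-zero variance
    within the subset; the standard deviation uses the n-1 denominator.
    """
    sub = matrix if sample_ids is None else matrix.subset_ids(list(sample_ids))
    center = np.empty(sub.n_variables)
    scale = np.empty(sub.n_variables)
    for j in range(sub.n_variables):
        obs = sub.values[sub.mask[:, j], j]
        if obs.size < 2:
            raise ScalingError(
                f"variable {sub.var_names[j]!r} has {obs.size} observed value(s) "
                "in the scaling subset; need at least 2"
            )
        center[j] = obs.mean()
        scale[j] = obs.std(ddof=1)
        if not np.isfinite(scale[j]) or scale[j] <= 0:
            raise ScalingError(
                f"variable {sub.var_names[j]!r} has zero variance in the scaling subset"
            )
    return Scaler(center=center, scale=scale, var_names=list(sub.var_names), fitted_on=list(sub.sample_ids))


def _check_vars(scaler: Scaler, matrix: ProfileMatrix) -> None:
    if list(matrix.var_names) != list(scaler.var_names):
        raise ScalingError("variable set of matrix does not match the fitted scaler")


def transform(scaler: Scaler, matrix: ProfileMatrix) -> ProfileMatrix:
    """(x - center) / scale on observed cells; mask and tags unchanged."""
    _check_vars(scaler, matrix)
    out = matrix.copy()
    out.values = (out.values - scaler.center) / scaler.scale
    out.values[~out.mask] = np.nan
    return out


def inverse_transform(scaler: Scaler, matrix: ProfileMatrix) -> ProfileMatrix:
    """Exact inverse of :func:`transform` on observed cells."""
    _check_vars(scaler, matrix)
    out = matrix.copy()
    out.values = out.values * scaler.scale + scaler.center
    out.values[~out.mask] = np.nan
    return out
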