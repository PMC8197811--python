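"""Linear descriptor–barrier scaling and barrier prediction.

Across a series of active-site environments the activation barrier is an
approximately linear function of either reactive descriptor (a
Brønsted–Evans–Polanyi-type scaling).  This module fits that line by
unweighted ordinary least squares, barrier on descriptor, and uses it to
predict the barrier of a held-out environment — e.g. scoring the aqueous
reaction from the enzyme-series fit.  Predictions outside the fitted
descriptor range are allowed but flagged as extrapolations.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import statsmodels.api as sm

from .descriptors import DescriptorRow

__all__ = [
    "ScalingModel",
    "Prediction",
    "ScalingError",
    "fit_scaling",
    "predict_barrier",
    "compare_environments",
]


class ScalingError(ValueError):
    """Degenerate or invalid scaling fit."""


@dataclass
class ScalingModel:
    """An OLS line barrier = slope * descriptor + intercept.

    slope in kcal/mol per unit descriptor (Å for dcat, e for qcat),
    intercept and residual_se in kcal/mol.  x_mean/x_sxx/x_min/x_max keep
    enough of the design to form prediction standard errors and to flag
    extrapolation without retaining the raw data.
    """

    descriptor: str
    slope: float
    intercept: float
    r_squared: float
    residual_se: float
    n: int
    x_mean: float
    x_sxx: float
    x_min: float
    x_max: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ScalingError(f"a scaling fit needs n >= 2 points, got {self.n}")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ScalingError(f"r_squared {self.r_squared} outside [0, 1]")
        for name in ("slope", "intercept", "residual_se"):
            if not math.isfinite(getattr(self, name)):
                raise ScalingError(f"non-finite {name} in scaling model")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ScalingModel":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class Prediction:
    """A predicted barrier with its standard error of prediction (kcal/mol)."""

    value: float
    se: float
    extrapolated: bool


def fit_scaling(rows: list[DescriptorRow], descriptor: str) -> ScalingModel:
    """Fit barrier on descriptor by unweighted OLS.

    Rows lacking the chosen descriptor or a barrier are excluded.  All
    descriptor values identical is a degenerate design and raises.  With
    exactly two points the line interpolates them exactly; r² is then
    reported as 1 with a warning because the variance decomposition is
    undefined at zero residual degrees of freedom.
    """
    if descriptor not in ("dcat", "qcat"):
        raise ValueError(f"descriptor must be 'dcat' or 'qcat', got {descriptor!r}")
    pts = [
        (getattr(r, descriptor), r.barrier)
        for r in rows
        if getattr(r, descriptor) is not None and r.barrier is not None
    ]
    if len(pts) < 2:
        raise ScalingError(
            f"need >= 2 rows with {descriptor} and barrier, got {len(pts)}"
        )
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.ptp(x) == 0.0:
        raise ScalingError(
            f"degenerate fit: all {descriptor} values equal ({x[0]})"
        )
    res = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = res.params
    n = len(x)
    if n == 2:
        warnings.warn(
            "scaling fit with n=2: line interpolates exactly; r² reported as 1 "
            "but carries no information",
            stacklevel=2,
        )
        r2, resid_se = 1.0, 0.0
    else:
        r2 = float(res.rsquared)
        resid_se = float(np.sqrt(res.mse_resid))
    return ScalingModel(
        descriptor=descriptor,
        slope=float(slope),
        intercept=float(intercept),
        r_squared=min(max(r2, 0.0), 1.0),
        residual_se=resid_se,
        n=n,
        x_mean=float(x.mean()),
        x_sxx=float(np.sum((x - x.mean()) ** 2)),
        x_min=float(x.min()),
        x_max=float(x.max()),
    )


def predict_barrier(model: ScalingModel, x: float) -> Prediction:
    """Predict the barrier at descriptor value x.

    The standard error is the prediction-interval SE for a new
    observation, s·sqrt(1 + 1/n + (x − x̄)²/Sxx).  Extrapolation beyond
    the fitted descriptor range is permitted but flagged.
    """
    if not math.isfinite(x):
        raise ValueError(f"descriptor value must be finite, got {x}")
    value = model.slope * x + model.intercept
    se = model.residual_se * math.sqrt(
        1.0 + 1.0 / model.n + (x - model.x_mean) ** 2 / model.x_sxx
    )
    extrapolated = x < model.x_min or x > model.x_max
    return Prediction(value=float(value), se=float(se), extrapolated=extrapolated)


def compare_environments(
    rows: list[DescriptorRow], reference: str
) -> dict[str, float]:
    """Barrier differences, each environment minus the reference, kcal/mol.

    Negative values mean the environment lowers the barrier relative to
    the reference — catalysis.  The reference maps to exactly 0.
    """
    by_label = {r.label: r for r in rows}
    if reference not in by_label:
        raise KeyError(
            f"unknown reference label {reference!r}; have {sorted(by_label)}"
        )
    ref = by_label[reference]
    if ref.barrier is None:
        raise ScalingError(f"reference environment {reference!r} has no barrier")
    out = {}
    for r in rows:
        if r.barrier is None:
            continue
        out[r.label] = r.barrier - ref.barrier
    return out
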