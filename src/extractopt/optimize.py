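"""Desirability-based maximization of a fitted response surface.

The single-response desirability is the linear "larger is better" ramp
d(y) = (y - y_min) / (y_max - y_min) clipped to [0, 1], with anchors taken
from the prediction range over the search grid.  Optimization is a dense
grid evaluation over the cuboidal design region followed by a bounded local
polish from the best grid point; for a quadratic surface this reliably
finds the box-constrained maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .exceptions import ValidationError
from .rsm import QuadraticModel

__all__ = [
    "desirability_max",
    "desirability_composite",
    "OptimumResult",
    "SurfaceGrid",
    "optimize_response",
    "surface_grid",
]

#: Default grid steps (ethanol %, time min, temperature degC).  Finer than
#: the 2.5/5-unit resolution at which optima are conventionally reported.
DEFAULT_GRID_STEPS = (0.5, 0.5, 0.25)


def desirability_max(y, y_min: float, y_max: float):
    """Larger-is-better linear desirability, clipped to [0, 1]."""
    if not y_max > y_min:
        raise ValidationError(f"y_max ({y_max}) must exceed y_min ({y_min})")
    d = (np.asarray(y, dtype=float) - y_min) / (y_max - y_min)
    d = np.clip(d, 0.0, 1.0)
    return float(d) if d.ndim == 0 else d


def desirability_composite(desirabilities) -> float:
    """Geometric-mean aggregation of several single-response desirabilities.

    Provided for multi-response use; the reproduction workflow optimizes
    each response separately.
    """
    d = np.asarray(desirabilities, dtype=float)
    if np.any((d < 0) | (d > 1)):
        raise ValidationError("desirabilities must lie in [0, 1]")
    return float(np.prod(d) ** (1.0 / len(d)))


@dataclass(frozen=True)
class OptimumResult:
    settings: tuple[float, float, float]
    predicted: float
    desirability: float
    method: str
    ties: tuple[tuple[float, float, float], ...] = ()


@dataclass(frozen=True)
class SurfaceGrid:
    """Predicted-response grid over one factor pair, third factor held fixed."""

    pair: tuple[str, str]
    fixed: tuple[str, float]
    axis_a: np.ndarray
    axis_b: np.ndarray
    values: np.ndarray  # shape (len(axis_a), len(axis_b))

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per grid cell."""
        aa, bb = np.meshgrid(self.axis_a, self.axis_b, indexing="ij")
        return pd.DataFrame(
            {
                self.pair[0]: aa.ravel(),
                self.pair[1]: bb.ravel(),
                "predicted": self.values.ravel(),
            }
        )


def _grid_axis(low: float, high: float, step: float) -> np.ndarray:
    n = int(round((high - low) / step))
    axis = low + step * np.arange(n + 1)
    axis[-1] = high  # guard against FP drift; the bound itself is always on the grid
    return axis


def optimize_response(
    model: QuadraticModel,
    bounds=None,
    grid_steps=DEFAULT_GRID_STEPS,
    polish: bool = True,
    tie_tol: float = 1e-9,
) -> OptimumResult:
    """Maximize the fitted response over the cuboidal design region.

    Dense grid search (default steps 0.5 %, 0.5 min, 0.25 degC) followed by
    an L-BFGS-B polish from the best grid point.  All grid points tied with
    the maximum (within ``tie_tol``) are reported; the first in
    lexicographic factor order is the canonical answer.
    """
    if bounds is None:
        bounds = [(f.low, f.high) for f in model.factors]
    bounds = [(float(lo), float(hi)) for lo, hi in bounds]
    for (lo, hi) in bounds:
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValidationError(f"invalid bounds ({lo}, {hi})")
    axes = [_grid_axis(lo, hi, s) for (lo, hi), s in zip(bounds, grid_steps)]
    if any(len(a) == 0 for a in axes):
        raise ValidationError("empty optimization grid")

    mesh = np.meshgrid(*axes, indexing="ij")
    points = np.column_stack([m.ravel() for m in mesh])
    values = model.predict(points, warn_extrapolation=False)
    y_min, y_max = float(values.min()), float(values.max())

    best = float(values.max())
    tie_idx = np.where(values >= best - tie_tol)[0]
    tie_points = points[tie_idx]
    # Lexicographic canonical representative among ties.
    order = np.lexsort(tuple(tie_points[:, k] for k in (2, 1, 0)))
    tie_points = tie_points[order]
    x_best = tie_points[0]

    method = f"grid(steps={tuple(grid_steps)})"
    if polish:
        res = minimize(
            lambda x: -model.predict(x, warn_extrapolation=False),
            x0=x_best,
            bounds=bounds,
            method="L-BFGS-B",
        )
        if res.success and -res.fun > best + tie_tol:
            x_best = np.clip(res.x, [b[0] for b in bounds], [b[1] for b in bounds])
            best = float(-res.fun)
            tie_points = x_best[None, :]
        method += "+L-BFGS-B"

    predicted = float(model.predict(x_best, warn_extrapolation=False))
    if y_max > y_min:
        desirability = desirability_max(predicted, y_min, y_max)
    else:
        desirability = 1.0  # constant surface: everything is equally optimal
    return OptimumResult(
        settings=tuple(float(v) for v in x_best),
        predicted=predicted,
        desirability=desirability,
        method=method,
        ties=tuple(tuple(float(v) for v in p) for p in tie_points),
    )


def surface_grid(
    model: QuadraticModel,
    pair: tuple[str, str],
    fixed_value: float,
    n_points: int = 41,
) -> SurfaceGrid:
    """Prediction grid over two factors with the third held fixed.

    Factor names may be the factor labels (``"ethanol"``) or positional
    aliases ``"X1"``/``"X2"``/``"X3"``.
    """
    names = [f.name for f in model.factors]
    aliases = {f"X{k + 1}": names[k] for k in range(3)}

    def _resolve(name: str) -> int:
        name = aliases.get(name, name)
        if name not in names:
            raise ValidationError(
                f"unknown factor {name!r}; available: {names + list(aliases)}"
            )
        return names.index(name)

    ia, ib = _resolve(pair[0]), _resolve(pair[1])
    if ia == ib:
        raise ValidationError("surface pair must name two distinct factors")
    ic = ({0, 1, 2} - {ia, ib}).pop()
    f_fixed = model.factors[ic]
    if not (f_fixed.low <= fixed_value <= f_fixed.high):
        raise ValidationError(
            f"fixed value {fixed_value} outside [{f_fixed.low}, {f_fixed.high}] "
            f"for factor {f_fixed.name!r}"
        )
    fa, fb = model.factors[ia], model.factors[ib]
    axis_a = np.linspace(fa.low, fa.high, n_points)
    axis_b = np.linspace(fb.low, fb.high, n_points)
    aa, bb = np.meshgrid(axis_a, axis_b, indexing="ij")
    points = np.zeros((aa.size, 3))
    points[:, ia] = aa.ravel()
    points[:, ib] = bb.ravel()
    points[:, ic] = fixed_value
    values = model.predict(points, warn_extrapolation=False).reshape(aa.shape)
    return SurfaceGrid(
        pair=(fa.name, fb.name),
        fixed=(f_fixed.name, float(fixed_value)),
        axis_a=axis_a,
        axis_b=axis_b,
        values=values,
    )
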