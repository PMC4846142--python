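"""Clamped two-variable response surfaces and sampling-adequacy maps.

Artificial inputs are built by clamping all model variables but two to
their cohort means and sweeping the remaining pair across their observed
ranges in 5% increments (a 21 x 21 grid).  The mean predicted status over
the ensemble maps the fitted response; the across-model SD at each node
maps model disagreement — regions where it stays near zero are adequately
sampled, regions where it grows need more fish.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort
from .ensemble import EnsembleResult, FeatureSpec, design_matrix

__all__ = ["SurfaceGrid", "AdequacySummary", "clamp_grid", "predict_surface",
           "adequacy_summary", "surface_to_frame", "save_surface"]


@dataclass
class SurfaceGrid:
    var_x: str
    var_y: str
    x_values: np.ndarray
    y_values: np.ndarray
    clamped: dict[str, float]
    spec: FeatureSpec
    mean_surface: np.ndarray | None = None  # shape (len(y), len(x))
    sd_surface: np.ndarray | None = None


@dataclass
class AdequacySummary:
    threshold: float
    fraction_above: float
    hotspots: list[tuple[float, float, float]] = field(default_factory=list)
    max_sd: float = 0.0


def clamp_grid(
    cohort: Cohort,
    spec: FeatureSpec,
    var_x: str,
    var_y: str,
    step: float = 0.05,
) -> SurfaceGrid:
    """Lay out the grid coordinates and clamp values for one variable pair.

    Ranges are the observed min-max of the modeling (complete-case) cohort;
    clamps are its arithmetic column means; ``step`` is the grid increment
    as a fraction of each range (0.05 -> 21 nodes per axis, endpoints
    included).
    """
    if var_x == var_y:
        raise ValueError("var_x and var_y must differ")
    for v in (var_x, var_y):
        if v not in spec.variables:
            raise ValueError(f"{v!r} is not in the feature spec")
    if not 0 < step <= 0.5:
        raise ValueError("step must be in (0, 0.5]")
    X, _, _, _ = design_matrix(cohort, spec)
    cols = {v: i for i, v in enumerate(spec.variables)}
    n_nodes = int(round(1.0 / step)) + 1

    def axis(v: str) -> np.ndarray:
        col = X[:, cols[v]]
        lo, hi = col.min(), col.max()
        if hi == lo:
            raise ValueError(f"{v}: zero observed range, cannot sweep")
        return lo + (hi - lo) * step * np.arange(n_nodes)

    clamped = {
        v: float(X[:, cols[v]].mean())
        for v in spec.variables
        if v not in (var_x, var_y)
    }
    return SurfaceGrid(var_x=var_x, var_y=var_y, x_values=axis(var_x),
                       y_values=axis(var_y), clamped=clamped, spec=spec)


def predict_surface(result: EnsembleResult, grid: SurfaceGrid) -> SurfaceGrid:
    """Fill a grid with per-node ensemble mean and SD predictions.

    Every model predicts the whole grid; ``mean_surface[i, j]`` averages
    the models at node (y_i, x_j) and ``sd_surface`` is their SD (ddof=1).
    """
    if grid.spec != result.spec:
        raise ValueError("grid and ensemble were built from different feature specs")
    vars_ = result.spec.variables
    cols = {v: i for i, v in enumerate(vars_)}
    nx, ny = len(grid.x_values), len(grid.y_values)
    Xg = np.empty((nx * ny, len(vars_)))
    for v, c in grid.clamped.items():
        Xg[:, cols[v]] = c
    xv, yv = np.meshgrid(grid.x_values, grid.y_values)  # shape (ny, nx)
    Xg[:, cols[grid.var_x]] = xv.ravel()
    Xg[:, cols[grid.var_y]] = yv.ravel()
    preds = np.stack([run.model.predict(Xg) for run in result.models])
    grid.mean_surface = preds.mean(axis=0).reshape(ny, nx)
    grid.sd_surface = preds.std(axis=0, ddof=1).reshape(ny, nx)
    return grid


def adequacy_summary(grid: SurfaceGrid, threshold: float) -> AdequacySummary:
    """Summarize where the ensemble disagrees with itself.

    Reports the fraction of grid nodes whose across-model SD exceeds
    ``threshold`` and lists those nodes as (x, y, sd) hotspots, highest SD
    first.  A zero surface (identical models) yields fraction 0 and no
    hotspots.
    """
    if grid.sd_surface is None:
        raise ValueError("grid has no sd_surface; run predict_surface first")
    sd = grid.sd_surface
    above = sd > threshold
    hotspots = [
        (float(grid.x_values[j]), float(grid.y_values[i]), float(sd[i, j]))
        for i, j in zip(*np.nonzero(above))
    ]
    hotspots.sort(key=lambda t: -t[2])
    return AdequacySummary(
        threshold=threshold,
        fraction_above=float(above.mean()),
        hotspots=hotspots,
        max_sd=float(sd.max()),
    )


def surface_to_frame(grid: SurfaceGrid) -> pd.DataFrame:
    """Long-format table: one row per node with mean and SD predictions."""
    if grid.mean_surface is None:
        raise ValueError("grid is not filled; run predict_surface first")
    xv, yv = np.meshgrid(grid.x_values, grid.y_values)
    return pd.DataFrame({
        "var_x": grid.var_x,
        "var_y": grid.var_y,
        "x": xv.ravel(),
        "y": yv.ravel(),
        "mean_prediction": grid.mean_surface.ravel(),
        "sd_prediction": grid.sd_surface.ravel(),
    })


def save_surface(grid: SurfaceGrid, path: str | Path) -> Path:
    path = Path(path)
    surface_to_frame(grid).to_csv(path, index=False, float_format="%.10g")
    return path


def plot_surface(grid: SurfaceGrid, which: str = "mean", ax=None):
    """Optional heatmap rendering (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if grid.mean_surface is None:
        raise ValueError("grid is not filled; run predict_surface first")
    data = grid.mean_surface if which == "mean" else grid.sd_surface
    if ax is None:
        _, ax = plt.subplots()
    im = ax.pcolormesh(grid.x_values, grid.y_values, data, shading="auto")
    ax.set_xlabel(grid.var_x)
    ax.set_ylabel(grid.var_y)
    ax.figure.colorbar(im, ax=ax, label=f"{which} predicted status")
    return ax
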