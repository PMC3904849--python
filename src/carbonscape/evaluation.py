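"""Spatial hold-out evaluation: checkerboard partition and accuracy metrics.

Calibration and validation regions alternate like a checkerboard of large
square cells (50 km on a side at full scale; scaled down for synthetic
runs), so that validation pixels are far from any training data and
adjacency leakage between train and test is ruled out.  Metrics are
computed over validation pixels: pooled RMSE, adjusted r-squared of an
observed-on-predicted regression, per-cell net bias (mean residual) with
its excess kurtosis, and error binned by distance from the calibration
LiDAR coverage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .raster import Grid

__all__ = [
    "CheckerboardPartition",
    "checkerboard_partition",
    "rmse",
    "adjusted_r2",
    "net_bias_per_cell",
    "performance_by_distance",
]

CALIBRATION = "calibration"
VALIDATION = "validation"


@dataclass
class CheckerboardPartition:
    """Alternating calibration/validation tiling of a rectangular extent.

    Cells are indexed (i, j) from the extent's NW corner; cell (0, 0) is
    calibration, and role alternates with the parity of i + j, so 4-adjacent
    cells always have opposite roles.  Partial cells at the S/E edges are
    kept and carry their parity role.
    """

    origin_x: float
    origin_y: float
    width: float
    height: float
    cell_size: float

    def __post_init__(self) -> None:
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        if self.width < self.cell_size and self.height < self.cell_size:
            pass  # a single (partial) cell is still a valid tiling
        self.n_cells_y = max(1, int(np.ceil(self.height / self.cell_size - 1e-12)))
        self.n_cells_x = max(1, int(np.ceil(self.width / self.cell_size - 1e-12)))

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Cell indices (i = row from north, j = col from west) of map points."""
        j = np.clip(((np.asarray(x) - self.origin_x) // self.cell_size).astype(int), 0, self.n_cells_x - 1)
        i = np.clip(((self.origin_y - np.asarray(y)) // self.cell_size).astype(int), 0, self.n_cells_y - 1)
        return i, j

    def role_counts(self) -> dict[str, int]:
        ii, jj = np.meshgrid(np.arange(self.n_cells_y), np.arange(self.n_cells_x), indexing="ij")
        calib = (ii + jj) % 2 == 0
        return {CALIBRATION: int(calib.sum()), VALIDATION: int((~calib).sum())}

    def calibration_mask(self, grid: Grid) -> np.ndarray:
        """Boolean pixel mask of the calibration cells on a grid geometry."""
        x, y = grid.pixel_centers()
        i, j = self.cell_of(x, y)
        return (i + j) % 2 == 0

    def cell_index_grid(self, grid: Grid) -> tuple[np.ndarray, np.ndarray]:
        x, y = grid.pixel_centers()
        return self.cell_of(x, y)


def checkerboard_partition(extent, cell_size: float) -> CheckerboardPartition:
    """Build the partition from a Grid or an (origin_x, origin_y, width, height) tuple."""
    if isinstance(extent, Grid):
        return CheckerboardPartition(
            origin_x=extent.origin_x,
            origin_y=extent.origin_y,
            width=extent.n_cols * extent.cell_size,
            height=extent.n_rows * extent.cell_size,
            cell_size=cell_size,
        )
    ox, oy, w, h = extent
    return CheckerboardPartition(origin_x=ox, origin_y=oy, width=w, height=h, cell_size=cell_size)


def _joint_residuals(pred: Grid, obs: Grid, mask: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    valid = pred.valid_mask() & obs.valid_mask()
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)
    if not valid.any():
        raise ValueError("no jointly valid pixels under the mask")
    p = np.asarray(pred.values, dtype=float)[valid]
    o = np.asarray(obs.values, dtype=float)[valid]
    return p, o


def rmse(pred: Grid, obs: Grid, mask: np.ndarray | None = None) -> float:
    """Root-mean-square error over masked, jointly valid pixels (Mg C ha^-1)."""
    p, o = _joint_residuals(pred, obs, mask)
    return float(np.sqrt(np.mean((p - o) ** 2)))


def adjusted_r2(pred: Grid, obs: Grid, mask: np.ndarray | None = None) -> float:
    """Adjusted r-squared of the OLS regression of observed on predicted.

    Single-predictor fit, so adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - 2).
    """
    p, o = _joint_residuals(pred, obs, mask)
    n = p.size
    if n < 3:
        raise ValueError(f"adjusted r2 needs >= 3 pixels, got {n}")
    if np.var(p) == 0 or np.var(o) == 0:
        raise ValueError("zero variance in predictions or observations")
    r = stats.pearsonr(p, o).statistic
    r2 = r * r
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - 2))


def net_bias_per_cell(
    pred: Grid,
    obs: Grid,
    partition: CheckerboardPartition,
    mask: np.ndarray | None = None,
) -> tuple[pd.DataFrame, float]:
    """Mean residual per checkerboard cell and the excess kurtosis of those biases.

    Returns a table with one row per cell holding at least one jointly valid
    masked pixel (columns ``cell_i, cell_j, role, n, bias, residual_sum``;
    bias in Mg C ha^-1 per pixel, i.e. per hectare on 1-ha pixels), plus the
    Fisher excess kurtosis of the bias list (NaN when fewer than 4 cells or
    when the biases have zero variance).
    """
    valid = pred.valid_mask() & obs.valid_mask()
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)
    if not valid.any():
        raise ValueError("no jointly valid pixels under the mask")
    i, j = partition.cell_index_grid(pred)
    resid = np.asarray(pred.values, dtype=float) - np.asarray(obs.values, dtype=float)
    df = pd.DataFrame({
        "cell_i": i[valid], "cell_j": j[valid], "resid": resid[valid],
    })
    grouped = df.groupby(["cell_i", "cell_j"])["resid"].agg(["count", "mean", "sum"])
    grouped = grouped.reset_index().rename(
        columns={"count": "n", "mean": "bias", "sum": "residual_sum"}
    )
    grouped["role"] = np.where(
        (grouped["cell_i"] + grouped["cell_j"]) % 2 == 0, CALIBRATION, VALIDATION
    )
    biases = grouped["bias"].to_numpy()
    if biases.size < 4 or np.var(biases) == 0:
        kurt = float("nan")
    else:
        kurt = float(stats.kurtosis(biases, fisher=True, bias=True))
    return grouped[["cell_i", "cell_j", "role", "n", "bias", "residual_sum"]], kurt


def performance_by_distance(
    pred: Grid,
    obs: Grid,
    dist: Grid,
    bin_edges,
    mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """RMSE and mean bias binned by distance from calibration LiDAR coverage.

    ``dist`` is the distance-transform grid of the calibration coverage.
    Bins are ``[e_k, e_{k+1})`` with the last bin closed on the right at the
    final edge; pixels beyond the last edge are excluded.  Empty bins are
    reported with n = 0.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be increasing with at least two values")
    valid = pred.valid_mask() & obs.valid_mask() & dist.valid_mask()
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)
    d = np.asarray(dist.values, dtype=float)[valid]
    resid = (np.asarray(pred.values, dtype=float) - np.asarray(obs.values, dtype=float))[valid]
    # right-closed final bin so the maximum distance is not dropped
    which = np.digitize(d, edges, right=False) - 1
    which[d == edges[-1]] = edges.size - 2
    rows = []
    for k in range(edges.size - 1):
        sel = which == k
        n = int(sel.sum())
        if n:
            rows.append((edges[k], edges[k + 1], n,
                         float(np.sqrt(np.mean(resid[sel] ** 2))), float(np.mean(resid[sel]))))
        else:
            rows.append((edges[k], edges[k + 1], 0, float("nan"), float("nan")))
    return pd.DataFrame(rows, columns=["dist_lo", "dist_hi", "n", "rmse", "bias"])
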