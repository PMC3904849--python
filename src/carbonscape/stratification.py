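"""Stratification upscaling: quantile bins x habitat classes -> median carbon.

The baseline upscaler partitions the landscape into classes by binning the
six continuous covariates (soil, PV, NPV fractional cover; elevation, slope,
aspect) into closed-left / open-right intervals ``[x, y)``, intersecting the
bin combination with the categorical habitat map, and assigning every pixel
of a class the median observed carbon density of its LiDAR-sampled pixels.

The shipped default scheme (:func:`default_scheme`) reproduces the 20-bin
allocation used operationally in western Amazonian carbon mapping: 2 soil,
8 PV, 3 NPV, 4 elevation, 2 slope and 1 aspect intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import Grid
from .synthetic import Landscape

__all__ = [
    "STRAT_VARIABLES",
    "StratScheme",
    "ClassMap",
    "MedianTable",
    "quantile_breaks",
    "default_scheme",
    "classify",
    "fit_class_medians",
    "predict_stratified",
    "StratifiedUpscaler",
    "StratifiedUpscalerResults",
]

#: fixed variable order: fractional covers first, then terrain
STRAT_VARIABLES = ("soil", "pv", "npv", "elevation", "slope", "aspect")

#: landscape attribute per stratification variable
_LAYER_OF = {
    "soil": "frac_soil",
    "pv": "frac_pv",
    "npv": "frac_npv",
    "elevation": "elevation",
    "slope": "slope",
    "aspect": "aspect",
}

NODATA_CLASS = -1


def quantile_breaks(values, n_bins: int) -> tuple[list[float], bool]:
    """Interior breakpoints at quantiles k/n_bins, k = 1..n_bins-1.

    Uses the linear-interpolation quantile definition.  Duplicate
    breakpoints (heavily tied data) are collapsed, which can yield fewer
    bins than requested; the second return value flags that collapse.
    """
    if n_bins < 1:
        raise ValueError(f"n_bins must be >= 1, got {n_bins}")
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("no valid values to compute quantile breaks from")
    if n_bins == 1:
        return [], False
    qs = np.arange(1, n_bins) / n_bins
    breaks = np.quantile(arr, qs, method="linear")
    unique = sorted(set(float(b) for b in breaks))
    return unique, len(unique) < n_bins - 1


@dataclass
class StratScheme:
    """Per-variable ordered breakpoints defining [x, y) intervals.

    ``breaks[var]`` holds the interior breakpoints; an empty list means the
    single interval ``[lower, inf)``.  ``lower[var]`` is the domain minimum
    that the first interval starts at (0 for all six variables here: the
    covers are percentages and the terrain variables are non-negative).
    A value below ``lower`` is a classification error.
    """

    breaks: dict[str, list[float]]
    lower: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for var in STRAT_VARIABLES:
            if var not in self.breaks:
                raise ValueError(f"scheme is missing variable {var!r}")
            b = list(self.breaks[var])
            if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
                raise ValueError(f"breakpoints for {var!r} must be strictly increasing: {b}")
            self.breaks[var] = b
            self.lower.setdefault(var, 0.0)

    def n_bins(self, var: str) -> int:
        return len(self.breaks[var]) + 1

    @property
    def total_intervals(self) -> int:
        return sum(self.n_bins(v) for v in STRAT_VARIABLES)

    def bin_index(self, var: str, values: np.ndarray) -> np.ndarray:
        """Bin index per value under the closed-left/open-right convention.

        A value equal to a breakpoint falls in the upper interval
        (breakpoints mark "greater than or equal to").
        """
        vals = np.asarray(values, dtype=float)
        if np.any(vals < self.lower[var]):
            bad = int(np.count_nonzero(vals < self.lower[var]))
            raise ValueError(
                f"{bad} value(s) of {var!r} fall below the first interval start "
                f"{self.lower[var]} — mis-specified scheme?"
            )
        return np.searchsorted(self.breaks[var], vals, side="right")


def default_scheme() -> StratScheme:
    """The shipped 20-interval default scheme (2+8+3+4+2+1 across variables)."""
    return StratScheme(
        breaks={
            "soil": [5.0],
            "pv": [85.0, 88.0, 90.0, 91.0, 92.0, 93.0, 94.0],
            "npv": [6.0, 13.0],
            "elevation": [136.0, 193.0, 443.0],
            "slope": [1.5],
            "aspect": [],
        }
    )


@dataclass
class ClassMap:
    """Grid of packed class identifiers plus the decoding radices.

    Identifiers are mixed-radix integers over (bin index per variable,
    habitat code) — bijective, compact and raster-storable.  Nodata pixels
    carry :data:`NODATA_CLASS`.
    """

    grid: Grid
    scheme: StratScheme
    n_habitat: int

    def _radices(self) -> list[int]:
        return [self.scheme.n_bins(v) for v in STRAT_VARIABLES] + [self.n_habitat]

    def encode(self, bins: dict[str, np.ndarray], habitat: np.ndarray) -> np.ndarray:
        code = np.zeros(habitat.shape, dtype=np.int64)
        for var in STRAT_VARIABLES:
            code = code * self.scheme.n_bins(var) + bins[var]
        return code * self.n_habitat + habitat

    def decode(self, class_id: int) -> dict[str, int]:
        """Recover (bin per variable, habitat) from a packed identifier."""
        out: dict[str, int] = {}
        rem = int(class_id)
        for var, radix in zip(
            reversed(STRAT_VARIABLES + ("habitat",)), reversed(self._radices())
        ):
            out[var] = rem % radix
            rem //= radix
        return out


def classify(landscape: Landscape, scheme: StratScheme) -> ClassMap:
    """Intersect per-variable bins with the habitat map into one class raster.

    Each pixel's six bin indices (``[x, y)`` convention: a value equal to a
    breakpoint belongs to the upper interval) are packed together with its
    habitat code.  A pixel with nodata in any layer gets the nodata class.
    """
    habitat = np.asarray(landscape.habitat.values, dtype=np.int64)
    valid = landscape.habitat.valid_mask()
    bins: dict[str, np.ndarray] = {}
    for var in STRAT_VARIABLES:
        layer: Grid = getattr(landscape, _LAYER_OF[var])
        valid &= layer.valid_mask()
    cm = ClassMap(grid=None, scheme=scheme, n_habitat=int(habitat.max()) + 1)  # type: ignore[arg-type]
    for var in STRAT_VARIABLES:
        layer = getattr(landscape, _LAYER_OF[var])
        vals = np.where(valid, np.asarray(layer.values, dtype=float), scheme.lower[var])
        bins[var] = scheme.bin_index(var, vals)
    codes = cm.encode(bins, np.where(valid, habitat, 0))
    codes[~valid] = NODATA_CLASS
    cm.grid = landscape.habitat.like(codes, nodata=NODATA_CLASS)
    return cm


@dataclass
class MedianTable:
    """Mapping class identifier -> median ACD, with provenance.

    ``table`` columns: ``class_id``, ``n`` (sampled pixels), ``median``
    (Mg C ha^-1), ``fallback`` in {"class", "habitat", "global"} recording
    whether the value came from the class's own samples, from pixels sharing
    its habitat code, or from the global median of all sampled pixels.
    """

    table: pd.DataFrame
    global_median: float

    def lookup(self) -> dict[int, float]:
        return dict(zip(self.table["class_id"].to_numpy(), self.table["median"].to_numpy()))

    def to_csv(self, path, class_map: ClassMap | None = None) -> None:
        df = self.table.copy()
        if class_map is not None:
            decoded = pd.DataFrame([class_map.decode(c) for c in df["class_id"]])
            df = pd.concat([df.reset_index(drop=True), decoded], axis=1)
        df.to_csv(path, index=False)


def fit_class_medians(class_map: ClassMap, acd_obs: Grid, lidar_mask: Grid) -> MedianTable:
    """Median observed ACD per class over LiDAR-sampled pixels.

    The median uses the even-count convention (mean of the two middle
    values).  Classes present in the map but unsampled resolve through a
    deterministic fallback chain: median over sampled pixels sharing the
    class's habitat code, then the global median of all sampled pixels; the
    provenance of each value is recorded.
    """
    codes = np.asarray(class_map.grid.values)
    sampled = (
        np.asarray(lidar_mask.values).astype(bool)
        & acd_obs.valid_mask()
        & (codes != NODATA_CLASS)
    )
    if not sampled.any():
        raise ValueError("no sampled pixels: cannot fit class medians")
    obs = np.asarray(acd_obs.values, dtype=float)[sampled]
    obs_codes = codes[sampled]
    n_hab = class_map.n_habitat
    df = pd.DataFrame({"class_id": obs_codes, "acd": obs})
    per_class = df.groupby("class_id")["acd"].agg(["median", "count"])
    global_median = float(np.median(obs))
    per_habitat = df.assign(habitat=df["class_id"] % n_hab).groupby("habitat")["acd"].median()

    all_classes = np.unique(codes[codes != NODATA_CLASS])
    rows = []
    for cid in all_classes:
        cid = int(cid)
        if cid in per_class.index:
            rows.append((cid, int(per_class.loc[cid, "count"]), float(per_class.loc[cid, "median"]), "class"))
        else:
            hab = cid % n_hab
            if hab in per_habitat.index:
                rows.append((cid, 0, float(per_habitat.loc[hab]), "habitat"))
            else:
                rows.append((cid, 0, global_median, "global"))
    table = pd.DataFrame(rows, columns=["class_id", "n", "median", "fallback"])
    return MedianTable(table=table, global_median=global_median)


def predict_stratified(class_map: ClassMap, medians: MedianTable) -> Grid:
    """Broadcast each class's median ACD onto all pixels of that class."""
    codes = np.asarray(class_map.grid.values)
    lut = medians.lookup()
    present = np.unique(codes[codes != NODATA_CLASS])
    missing = [int(c) for c in present if int(c) not in lut]
    if missing:
        raise ValueError(f"median table does not resolve class id(s) {missing[:5]}"
                         + ("..." if len(missing) > 5 else ""))
    # vectorized lookup: sorted class ids -> medians, searchsorted per pixel
    meds = np.array([lut[int(c)] for c in present], dtype=float)
    valid = codes != NODATA_CLASS
    idx = np.searchsorted(present, codes[valid])
    out = np.full(codes.shape, class_map.grid.nodata, dtype=float)
    out[valid] = meds[idx]
    g = class_map.grid
    return Grid(out, origin_x=g.origin_x, origin_y=g.origin_y, cell_size=g.cell_size,
                nodata=float(g.nodata))


# ---------------------------------------------------------------------------
# model-style wrapper
# ---------------------------------------------------------------------------

class StratifiedUpscaler:
    """Stratification upscaling model over a landscape.

    Parameters
    ----------
    landscape : Landscape
        Co-registered covariate stack with observed carbon (``acd_true``)
        along the LiDAR strips.
    scheme : StratScheme, optional
        Binning scheme; defaults to the shipped 20-interval scheme.
    sample_mask : ndarray of bool, optional
        Pixels whose observations may be used for fitting (e.g. LiDAR
        coverage restricted to calibration cells).  Defaults to the
        landscape's LiDAR mask.
    """

    def __init__(self, landscape: Landscape, scheme: StratScheme | None = None,
                 sample_mask: np.ndarray | None = None):
        self.landscape = landscape
        self.scheme = scheme if scheme is not None else default_scheme()
        if sample_mask is None:
            sample_mask = np.asarray(landscape.lidar_mask.values).astype(bool)
        self.sample_mask = np.asarray(sample_mask, dtype=bool)

    def fit(self) -> "StratifiedUpscalerResults":
        class_map = classify(self.landscape, self.scheme)
        mask_grid = self.landscape.lidar_mask.like(self.sample_mask)
        medians = fit_class_medians(class_map, self.landscape.acd_true, mask_grid)
        return StratifiedUpscalerResults(self, class_map, medians)


class StratifiedUpscalerResults:
    """Fitted stratification: class map + median table; ``predict`` broadcasts."""

    def __init__(self, model: StratifiedUpscaler, class_map: ClassMap, medians: MedianTable):
        self.model = model
        self.class_map = class_map
        self.median_table = medians
        self.n_classes = int(len(medians.table))

    def predict(self) -> Grid:
        return predict_stratified(self.class_map, self.median_table)

    def summary(self) -> str:
        t = self.median_table.table
        fb = t["fallback"].value_counts()
        lines = [
            "Stratified upscaler",
            f"  classes in map:        {self.n_classes}",
            f"  intervals in scheme:   {self.model.scheme.total_intervals}",
            f"  sampled classes:       {int(fb.get('class', 0))}",
            f"  habitat fallbacks:     {int(fb.get('habitat', 0))}",
            f"  global fallbacks:      {int(fb.get('global', 0))}",
            f"  global median ACD:     {self.median_table.global_median:.2f} Mg C ha-1",
        ]
        return "\n".join(lines)
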