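"""Random Forest upscaling, with and without explicit position features.

Two runs of a bagged regression-tree ensemble are compared: one using only
the wall-to-wall covariates (fractional cover, terrain, habitat class) and
one that additionally receives four "position" features — the pixel-center
easting/northing and their 45-degree clockwise rotations (diagx, diagy).
Axis-aligned tree splits on the rotated pair let the ensemble carve the map
along diagonal fronts as well as N-S/E-W ones, which is what allows it to
absorb purely spatial (covariate-free) carbon variation.

The ensemble itself is scikit-learn's RandomForestRegressor (bootstrap
aggregation with per-split random feature subsetting); out-of-bag variance
explained comes from its OOB machinery.  The habitat class is one-hot
expanded above a cardinality threshold because the trees have no native
unordered-categorical support.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .raster import Grid
from .synthetic import Landscape

__all__ = [
    "RFHyperparams",
    "FeatureMatrix",
    "RFRunResult",
    "position_features",
    "assemble_features",
    "sample_training",
    "fit_rf",
    "predict_rf",
    "RandomForestUpscaler",
    "RandomForestUpscalerResults",
]

BASE_FEATURES = ("frac_soil", "frac_pv", "frac_npv", "elevation", "slope", "aspect", "geoeco")
POSITION_FEATURES = ("easting", "northing", "diagx", "diagy")


@dataclass
class RFHyperparams:
    """Forest settings, exposed because none are dictated by the method itself.

    Defaults follow the regression conventions of the reference
    implementation of the algorithm: 500 trees, feature-subset size
    ceil(p/3) per split, leaves of at least 5 samples, unlimited depth.
    ``onehot_threshold`` controls when the habitat code is one-hot expanded
    (above this cardinality) rather than passed as a bare integer.
    """

    n_trees: int = 500
    max_features: str | int = "third"
    min_samples_leaf: int = 5
    max_depth: int | None = None
    onehot_threshold: int = 32


@dataclass
class FeatureMatrix:
    """Per-pixel predictor table with grid bookkeeping.

    ``frame`` holds one row per valid pixel with the named feature columns;
    ``rows``/``cols`` give each row's pixel indices in the source geometry.
    """

    frame: pd.DataFrame
    rows: np.ndarray
    cols: np.ndarray
    geometry: Grid
    n_habitat: int

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(self.frame.columns)

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class RFRunResult:
    """A fitted forest plus its provenance."""

    model: RandomForestRegressor
    oob_var_explained: float
    training_indices: np.ndarray
    feature_columns: tuple[str, ...]
    design_columns: tuple[str, ...]
    hyperparams: RFHyperparams
    seed: int
    degenerate_target: bool = False
    train_min: float = 0.0
    train_max: float = 0.0


def position_features(geometry: Grid) -> tuple[Grid, Grid, Grid, Grid]:
    """Pixel-center coordinates and their 45-degree clockwise rotation.

    Returns (easting, northing, diagx, diagy) grids in map units, with
    diagx = (x + y)/sqrt(2) and diagy = (x - y)/sqrt(2).  The rotation is an
    isometry, so pairwise distances are preserved; only the split axes the
    trees can use change.
    """
    x, y = geometry.pixel_centers()
    rt2 = math.sqrt(2.0)
    return (
        geometry.like(x),
        geometry.like(y),
        geometry.like((x + y) / rt2),
        geometry.like((x - y) / rt2),
    )


def assemble_features(
    landscape: Landscape,
    include_position: bool,
    include_soil: bool = True,
) -> FeatureMatrix:
    """One predictor row per pixel valid in every layer.

    Columns follow the fixed order of :data:`BASE_FEATURES` (optionally
    without ``frac_soil``) with the four :data:`POSITION_FEATURES` appended
    when requested.  The habitat class travels as an integer ``geoeco``
    code; its encoding for the trees is decided at fit time.
    """
    layers = {
        "frac_soil": landscape.frac_soil,
        "frac_pv": landscape.frac_pv,
        "frac_npv": landscape.frac_npv,
        "elevation": landscape.elevation,
        "slope": landscape.slope,
        "aspect": landscape.aspect,
        "geoeco": landscape.habitat,
    }
    if not include_soil:
        layers.pop("frac_soil")
    valid = np.ones(landscape.shape, dtype=bool)
    for g in layers.values():
        valid &= g.valid_mask()
    rows, cols = np.nonzero(valid)
    data = {name: np.asarray(g.values)[rows, cols] for name, g in layers.items()}
    if include_position:
        for name, g in zip(POSITION_FEATURES, position_features(landscape.elevation)):
            data[name] = np.asarray(g.values)[rows, cols]
    frame = pd.DataFrame(data)
    n_hab = int(np.asarray(landscape.habitat.values).max()) + 1
    return FeatureMatrix(frame=frame, rows=rows, cols=cols,
                         geometry=landscape.elevation, n_habitat=n_hab)


def sample_training(
    lidar_mask: np.ndarray,
    calibration_cells: np.ndarray,
    n: int,
    seed: int,
) -> tuple[np.ndarray, bool]:
    """Uniform sample (without replacement) of flat pixel indices for training.

    Eligible pixels are LiDAR-sampled AND inside calibration cells.  If
    fewer than ``n`` are available, all are returned with a truncation flag.
    Identical (masks, seed) give an identical index set, which both forest
    runs reuse verbatim.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    eligible = np.flatnonzero(np.asarray(lidar_mask).astype(bool).ravel()
                              & np.asarray(calibration_cells).astype(bool).ravel())
    if eligible.size == 0:
        raise ValueError("no pixels are both LiDAR-sampled and in calibration cells")
    truncated = eligible.size <= n
    if truncated:
        if eligible.size < n:
            warnings.warn(
                f"requested {n} training pixels but only {eligible.size} eligible; using all",
                stacklevel=2,
            )
        return np.sort(eligible), eligible.size < n
    rng = np.random.default_rng(seed)
    chosen = rng.choice(eligible, size=n, replace=False)
    return np.sort(chosen), False


def _design_matrix(frame: pd.DataFrame, n_habitat: int, threshold: int) -> pd.DataFrame:
    """Expand ``geoeco`` to one-hot columns when its cardinality exceeds the threshold."""
    if "geoeco" not in frame.columns or n_habitat <= threshold:
        return frame
    codes = frame["geoeco"].to_numpy(dtype=int)
    onehot = np.zeros((len(frame), n_habitat), dtype=np.float32)
    onehot[np.arange(len(frame)), codes] = 1.0
    hot = pd.DataFrame(onehot, columns=[f"geoeco_{k}" for k in range(n_habitat)],
                       index=frame.index)
    return pd.concat([frame.drop(columns=["geoeco"]), hot], axis=1)


def fit_rf(
    features: FeatureMatrix,
    targets: np.ndarray,
    hyperparams: RFHyperparams | None = None,
    seed: int = 0,
) -> RFRunResult:
    """Fit the bagged regression-tree ensemble and report OOB variance explained.

    ``oob_var_explained`` is 1 - MSE_oob / Var(targets), the internal
    "percent variation explained" of the algorithm's reference
    implementation.  A constant target is flagged degenerate (the fit still
    succeeds; the OOB statistic is meaningless there).
    """
    hp = hyperparams or RFHyperparams()
    y = np.asarray(targets, dtype=float)
    if len(features) != y.size:
        raise ValueError(f"feature rows ({len(features)}) != targets ({y.size})")
    if y.size < 10:
        raise ValueError(f"need >= 10 training rows, got {y.size}")
    if not np.isfinite(features.frame.to_numpy(dtype=float)).all() or not np.isfinite(y).all():
        raise ValueError("features and targets must be finite (no missing values)")
    design = _design_matrix(features.frame, features.n_habitat, hp.onehot_threshold)
    p = design.shape[1]
    max_features = math.ceil(p / 3) if hp.max_features == "third" else hp.max_features
    model = RandomForestRegressor(
        n_estimators=hp.n_trees,
        max_features=max_features,
        min_samples_leaf=hp.min_samples_leaf,
        max_depth=hp.max_depth,
        oob_score=True,
        bootstrap=True,
        n_jobs=1,
        random_state=int(seed) % (2**32),
    )
    degenerate = bool(np.var(y) == 0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # OOB warnings on tiny degenerate fits
        model.fit(design.to_numpy(dtype=np.float32), y)
        oob = float(model.oob_score_) if not degenerate else float("-inf")
    return RFRunResult(
        model=model,
        oob_var_explained=oob,
        training_indices=np.arange(y.size),
        feature_columns=features.columns,
        design_columns=tuple(design.columns),
        hyperparams=hp,
        seed=seed,
        degenerate_target=degenerate,
        train_min=float(y.min()),
        train_max=float(y.max()),
    )


def predict_rf(result: RFRunResult, features: FeatureMatrix) -> Grid:
    """Ensemble-mean prediction written back onto the grid geometry.

    Predictions are tree-leaf averages of training targets, so they lie in
    ``[min(train targets), max(train targets)]`` by construction.  Pixels
    absent from the feature matrix come back as nodata.
    """
    if features.columns != result.feature_columns:
        missing = set(result.feature_columns) - set(features.columns)
        extra = set(features.columns) - set(result.feature_columns)
        raise ValueError(
            f"feature columns do not match training columns; missing={sorted(missing)}, "
            f"unexpected={sorted(extra)}"
        )
    hp = result.hyperparams
    design = _design_matrix(features.frame, features.n_habitat, hp.onehot_threshold)
    if tuple(design.columns) != result.design_columns:
        raise ValueError("design-matrix expansion mismatch between fit and predict")
    pred = result.model.predict(design.to_numpy(dtype=np.float32))
    geom = features.geometry
    out = np.full(geom.shape, geom.nodata, dtype=float)
    out[features.rows, features.cols] = pred
    return geom.like(out)


# ---------------------------------------------------------------------------
# model-style wrapper
# ---------------------------------------------------------------------------

class RandomForestUpscaler:
    """Random Forest upscaling model over a landscape.

    Parameters
    ----------
    landscape : Landscape
    include_position : bool
        Whether to append the four position features.
    sample_mask : ndarray of bool, optional
        Pixels eligible for training (default: the LiDAR mask).
    n_train : int
        Training-sample cap; the eligible pool is subsampled to this size.
    hyperparams : RFHyperparams, optional
    include_soil : bool
        Whether ``frac_soil`` joins the covariate set.
    seed : int
        Drives both the training subsample and the forest.
    """

    def __init__(
        self,
        landscape: Landscape,
        include_position: bool,
        sample_mask: np.ndarray | None = None,
        n_train: int = 80_000,
        hyperparams: RFHyperparams | None = None,
        include_soil: bool = True,
        seed: int = 0,
        training_indices: np.ndarray | None = None,
    ):
        self.landscape = landscape
        self.include_position = include_position
        self.include_soil = include_soil
        if sample_mask is None:
            sample_mask = np.asarray(landscape.lidar_mask.values).astype(bool)
        self.sample_mask = np.asarray(sample_mask, dtype=bool)
        self.n_train = n_train
        self.hyperparams = hyperparams or RFHyperparams()
        self.seed = seed
        self.training_indices = training_indices

    def fit(self) -> "RandomForestUpscalerResults":
        ls = self.landscape
        features = assemble_features(ls, self.include_position, self.include_soil)
        feature_valid = np.zeros(ls.shape, dtype=bool)
        feature_valid[features.rows, features.cols] = True
        if self.training_indices is None:
            flat_idx, truncated = sample_training(
                self.sample_mask, feature_valid, self.n_train, self.seed
            )
        else:
            flat_idx, truncated = np.asarray(self.training_indices), False
        # map flat pixel indices into feature-matrix rows
        feat_flat = features.rows * ls.shape[1] + features.cols
        order = np.searchsorted(feat_flat, flat_idx)
        if not np.array_equal(feat_flat[order], flat_idx):
            raise ValueError("some training pixels are not valid feature rows")
        train = FeatureMatrix(
            frame=features.frame.iloc[order].reset_index(drop=True),
            rows=features.rows[order], cols=features.cols[order],
            geometry=features.geometry, n_habitat=features.n_habitat,
        )
        y = np.asarray(ls.acd_true.values, dtype=float)[train.rows, train.cols]
        run = fit_rf(train, y, self.hyperparams, seed=self.seed)
        return RandomForestUpscalerResults(self, run, features, flat_idx, truncated)


class RandomForestUpscalerResults:
    """Fitted forest with prediction over the full landscape."""

    def __init__(self, model: RandomForestUpscaler, run: RFRunResult,
                 features: FeatureMatrix, training_flat_indices: np.ndarray,
                 truncated: bool):
        self.model = model
        self.run = run
        self.features = features
        self.training_flat_indices = training_flat_indices
        self.truncated = truncated

    @property
    def oob_var_explained(self) -> float:
        return self.run.oob_var_explained

    def predict(self) -> Grid:
        return predict_rf(self.run, self.features)

    def summary(self) -> str:
        tag = "with position features" if self.model.include_position else "covariates only"
        lines = [
            f"Random Forest upscaler ({tag})",
            f"  trees:                 {self.run.hyperparams.n_trees}",
            f"  feature columns:       {len(self.run.feature_columns)}"
            f" ({len(self.run.design_columns)} after habitat encoding)",
            f"  training pixels:       {self.training_flat_indices.size}"
            + (" (pool smaller than requested)" if self.truncated else ""),
            f"  OOB variance explained:{self.run.oob_var_explained: .3f}",
        ]
        return "\n".join(lines)
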