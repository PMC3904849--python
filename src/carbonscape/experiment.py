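"""End-to-end upscaling experiment: three methods, one config, one report.

``UpscalingExperiment`` simulates a landscape, partitions it into a
checkerboard of calibration/validation cells, fits the three upscalers
(stratification, Random Forest, Random Forest with position features) on
LiDAR pixels inside calibration cells, predicts wall-to-wall, and evaluates
on LiDAR pixels inside validation cells — the only places where held-out
observations exist.  Residual diagnostics (Moran's I, semivariogram with a
Weibull fit) run on coordinate subsamples shared across methods, and the
two forest runs additionally report their out-of-bag versus hold-out
variance explained, the overfitting check.

Everything is deterministic given the master seed: each stage draws from
its own named sub-stream, so stages are independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import __version__
from .evaluation import (
    CheckerboardPartition,
    adjusted_r2,
    checkerboard_partition,
    net_bias_per_cell,
    performance_by_distance,
    rmse,
)
from .raster import Grid, distance_transform
from .rf import RFHyperparams, RandomForestUpscaler, sample_training
from .spatial import (
    MoranResult,
    Variogram,
    WeibullVariogramFit,
    empirical_variogram,
    fit_weibull_variogram,
    morans_i,
    subsample_indices,
)
from .stratification import StratifiedUpscaler, default_scheme
from .synthetic import Landscape, LandscapeConfig, layer_rng, make_landscape

__all__ = [
    "ExperimentConfig",
    "MethodEvaluation",
    "ExperimentResults",
    "UpscalingExperiment",
    "compare_oob_vs_holdout",
    "METHODS",
]

METHODS = ("stratification", "rf", "rf_position")


@dataclass
class ExperimentConfig:
    """Settings for one full three-method comparison.

    Defaults are desk-scale: a 300x300-pixel (1-ha cells) landscape with a
    3.75-km checkerboard (an 8x8 cell board), a training cap of 80,000
    pixels (auto-capped by availability), and diagnostic subsamples of
    15,000 residuals for the variogram and 5,000 for Moran's I.  The
    full-scale analysis this mirrors used 50-km cells over a 16-Mha region;
    ``full_scale_preset`` returns those settings.
    """

    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    checkerboard_cell_size: float = 3750.0
    strat_mode: str = "default"  # or "quantile"
    strat_bins: dict | None = None  # per-variable bin counts for quantile mode
    rf: RFHyperparams = field(default_factory=RFHyperparams)
    n_train: int = 80_000
    include_soil: bool = True
    n_variogram: int = 15_000
    n_moran: int = 5_000
    variogram_n_lags: int = 15
    n_distance_bins: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variogram < 2 or self.n_moran < 3:
            raise ValueError("diagnostic subsample sizes too small")

    @classmethod
    def full_scale_preset(cls, seed: int = 0) -> "ExperimentConfig":
        """Full-scale settings: 50-km cells, 80,000 training pixels.

        The landscape itself stays synthetic; only the protocol sizes scale.
        Expect hours of compute — this preset exists for provenance, not for
        tests.
        """
        ls = LandscapeConfig(n_rows=4000, n_cols=4000, seed=seed)
        return cls(landscape=ls, checkerboard_cell_size=50_000.0, n_train=80_000, seed=seed)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _seed_for(master: int, stage: str) -> int:
    """Deterministic 31-bit sub-seed for a named stage."""
    return int(layer_rng(master, stage).integers(0, 2**31 - 1))


@dataclass
class MethodEvaluation:
    """Hold-out accuracy and residual diagnostics for one upscaling method."""

    method: str
    rmse: float
    adjusted_r2: float
    bias_table: pd.DataFrame
    bias_kurtosis: float
    by_distance: pd.DataFrame
    moran: MoranResult
    variogram: Variogram
    variogram_fit: WeibullVariogramFit
    n_validation_pixels: int

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "rmse": self.rmse,
            "adjusted_r2": self.adjusted_r2,
            "bias_kurtosis": self.bias_kurtosis,
            "n_validation_pixels": self.n_validation_pixels,
            "n_validation_cells": int((self.bias_table["role"] == "validation").sum()),
            "moran_I": self.moran.I,
            "moran_expected": self.moran.expected,
            "moran_sd": self.moran.sd,
            "moran_p": self.moran.p_two_sided,
            "variogram_a": self.variogram_fit.a,
            "variogram_b": self.variogram_fit.b,
            "variogram_c": self.variogram_fit.c,
            "variogram_h90": self.variogram_fit.h90,
        }


class UpscalingExperiment:
    """Three-method upscaling comparison on a synthetic landscape.

    ``fit()`` runs the whole pipeline and returns an
    :class:`ExperimentResults`.  A pre-built landscape can be injected to
    reuse one simulation across method settings.
    """

    def __init__(self, config: ExperimentConfig, landscape: Landscape | None = None):
        self.config = config
        self._landscape = landscape

    def fit(self) -> "ExperimentResults":
        cfg = self.config
        warnings_log: list[str] = []

        landscape = self._landscape
        if landscape is None:
            ls_cfg = cfg.landscape
            if ls_cfg.seed != cfg.seed:
                ls_cfg = LandscapeConfig(**{**ls_cfg.to_dict(), "seed": cfg.seed})
            landscape = make_landscape(ls_cfg)

        geom = landscape.elevation
        partition = checkerboard_partition(geom, cfg.checkerboard_cell_size)
        calib_cells = partition.calibration_mask(geom)
        lidar = np.asarray(landscape.lidar_mask.values).astype(bool)
        train_mask = lidar & calib_cells
        valid_mask = lidar & ~calib_cells  # held-out LiDAR observations
        obs = landscape.acd_true

        # --- stratification -------------------------------------------------
        scheme = self._scheme(landscape, train_mask)
        strat = StratifiedUpscaler(landscape, scheme=scheme, sample_mask=train_mask).fit()
        if (strat.median_table.table["fallback"] != "class").any():
            n_fb = int((strat.median_table.table["fallback"] != "class").sum())
            warnings_log.append(f"stratification: {n_fb} class(es) resolved by fallback medians")

        # --- the two forest runs share one training-pixel set ---------------
        n_eligible = int(train_mask.sum())
        n_train = min(cfg.n_train, n_eligible)
        if n_train < cfg.n_train:
            warnings_log.append(
                f"rf: training sample capped at {n_train} eligible pixels (requested {cfg.n_train})"
            )
        train_idx, _ = sample_training(lidar, calib_cells, n_train, _seed_for(cfg.seed, "rf-sample"))
        rf_seed = _seed_for(cfg.seed, "rf-fit")
        rf_runs = {}
        for name, include_position in (("rf", False), ("rf_position", True)):
            rf_runs[name] = RandomForestUpscaler(
                landscape, include_position=include_position,
                sample_mask=train_mask, hyperparams=cfg.rf,
                include_soil=cfg.include_soil, seed=rf_seed,
                training_indices=train_idx,
            ).fit()

        predictions = {
            "stratification": strat.predict(),
            "rf": rf_runs["rf"].predict(),
            "rf_position": rf_runs["rf_position"].predict(),
        }

        # --- evaluation ------------------------------------------------------
        dist = distance_transform(geom.like(train_mask))
        max_d = float(np.asarray(dist.values)[valid_mask].max())
        dist_edges = np.linspace(0.0, max(max_d, geom.cell_size), cfg.n_distance_bins + 1)

        vario_idx = subsample_indices(valid_mask, min(cfg.n_variogram, int(valid_mask.sum())),
                                      _seed_for(cfg.seed, "variogram-subsample"))
        moran_idx = subsample_indices(valid_mask, min(cfg.n_moran, int(valid_mask.sum())),
                                      _seed_for(cfg.seed, "moran-subsample"))
        x, y = geom.pixel_centers()
        coords_v = np.column_stack([x.ravel()[vario_idx], y.ravel()[vario_idx]])
        coords_m = np.column_stack([x.ravel()[moran_idx], y.ravel()[moran_idx]])

        evaluations: dict[str, MethodEvaluation] = {}
        for name in METHODS:
            pred = predictions[name]
            resid_flat = (np.asarray(pred.values, dtype=float)
                          - np.asarray(obs.values, dtype=float)).ravel()
            bias_table, kurt = net_bias_per_cell(pred, obs, partition, mask=valid_mask)
            vario = empirical_variogram(resid_flat[vario_idx], coords_v,
                                        n_lags=cfg.variogram_n_lags)
            evaluations[name] = MethodEvaluation(
                method=name,
                rmse=rmse(pred, obs, mask=valid_mask),
                adjusted_r2=adjusted_r2(pred, obs, mask=valid_mask),
                bias_table=bias_table[bias_table["role"] == "validation"].reset_index(drop=True),
                bias_kurtosis=kurt,
                by_distance=performance_by_distance(pred, obs, dist, dist_edges, mask=valid_mask),
                moran=morans_i(resid_flat[moran_idx], coords_m),
                variogram=vario,
                variogram_fit=fit_weibull_variogram(vario),
                n_validation_pixels=int(valid_mask.sum()),
            )

        # --- OOB vs hold-out overfitting check -------------------------------
        oob_vs_holdout = {}
        for name in ("rf", "rf_position"):
            pred = predictions[name]
            p, o = (np.asarray(pred.values, dtype=float)[valid_mask],
                    np.asarray(obs.values, dtype=float)[valid_mask])
            holdout_ve = float(1.0 - np.mean((p - o) ** 2) / np.var(o))
            oob = rf_runs[name].oob_var_explained
            oob_vs_holdout[name] = {
                "oob_var_explained": oob,
                "holdout_var_explained": holdout_ve,
                "gap": oob - holdout_ve,
                "ratio": oob / holdout_ve if holdout_ve != 0 else float("inf"),
            }

        provenance = {
            "config_hash": hashlib.sha256(
                json.dumps(self.config.to_dict(), sort_keys=True, default=str).encode()
            ).hexdigest()[:16],
            "seed": cfg.seed,
            "version": __version__,
            "n_train_used": int(train_idx.size),
            "n_calibration_lidar_pixels": n_eligible,
            "n_validation_lidar_pixels": int(valid_mask.sum()),
        }
        return ExperimentResults(
            config=cfg, landscape=landscape, partition=partition,
            predictions=predictions, evaluations=evaluations,
            oob_vs_holdout=oob_vs_holdout, strat_results=strat,
            rf_results=rf_runs, provenance=provenance, warnings=warnings_log,
        )

    def _scheme(self, landscape: Landscape, train_mask: np.ndarray):
        cfg = self.config
        if cfg.strat_mode == "default":
            return default_scheme()
        if cfg.strat_mode != "quantile":
            raise ValueError(f"unknown strat_mode {cfg.strat_mode!r}")
        from .stratification import STRAT_VARIABLES, StratScheme, quantile_breaks
        from .stratification import _LAYER_OF  # noqa: PLC2701 — fixed layer mapping

        counts = cfg.strat_bins or {"soil": 2, "pv": 8, "npv": 3, "elevation": 4, "slope": 2, "aspect": 1}
        breaks = {}
        for var in STRAT_VARIABLES:
            vals = np.asarray(getattr(landscape, _LAYER_OF[var]).values, dtype=float)[train_mask]
            b, _collapsed = quantile_breaks(vals, counts.get(var, 1))
            breaks[var] = b
        return StratScheme(breaks=breaks)


@dataclass
class ExperimentResults:
    """Everything one experiment produced, regenerable from (config, seed)."""

    config: ExperimentConfig
    landscape: Landscape
    partition: CheckerboardPartition
    predictions: dict[str, Grid]
    evaluations: dict[str, MethodEvaluation]
    oob_vs_holdout: dict[str, dict[str, float]]
    strat_results: object
    rf_results: dict[str, object]
    provenance: dict
    warnings: list[str]

    def summary(self) -> str:
        lines = [
            "Upscaling experiment summary",
            "=" * 64,
            f"landscape: {self.landscape.shape[0]}x{self.landscape.shape[1]} px @ "
            f"{self.landscape.elevation.cell_size:.0f} m; "
            f"checkerboard cell {self.config.checkerboard_cell_size:.0f} m "
            f"({self.partition.n_cells_y}x{self.partition.n_cells_x} cells)",
            f"training pixels: {self.provenance['n_train_used']} of "
            f"{self.provenance['n_calibration_lidar_pixels']} calibration LiDAR px; "
            f"validation LiDAR px: {self.provenance['n_validation_lidar_pixels']}",
            "",
            f"{'method':<16}{'RMSE':>8}{'adj r2':>9}{'Moran I':>10}{'p':>11}{'h90 (m)':>10}",
            "-" * 64,
        ]
        for name in METHODS:
            ev = self.evaluations[name]
            lines.append(
                f"{name:<16}{ev.rmse:>8.2f}{ev.adjusted_r2:>9.3f}{ev.moran.I:>10.4f}"
                f"{ev.moran.p_two_sided:>11.2e}{ev.variogram_fit.h90:>10.0f}"
            )
        lines.append("")
        lines.append("out-of-bag vs hold-out variance explained (overfitting check):")
        for name, d in self.oob_vs_holdout.items():
            lines.append(
                f"  {name:<13} OOB {d['oob_var_explained']:.3f}  "
                f"hold-out {d['holdout_var_explained']:.3f}  gap {d['gap']:+.3f}"
            )
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "methods": {name: ev.to_dict() for name, ev in self.evaluations.items()},
            "oob_vs_holdout": self.oob_vs_holdout,
            "warnings": list(self.warnings),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def plot_variograms(self, ax=None):
        """Residual semivariograms with their fitted curves (optional extra)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for name in METHODS:
            ev = self.evaluations[name]
            ax.plot(ev.variogram.bin_centers, ev.variogram.gamma, "o", label=name, ms=4)
            fit = ev.variogram_fit
            if fit.converged:
                h = np.linspace(0, ev.variogram.max_lag, 200)
                ax.plot(h, fit(h), "-", lw=1)
        ax.set_xlabel("lag distance (m)")
        ax.set_ylabel("semivariance ((Mg C ha$^{-1}$)$^2$)")
        ax.legend()
        return ax


def compare_oob_vs_holdout(results: "ExperimentResults | list[ExperimentResults]") -> pd.DataFrame:
    """Summarize the OOB-vs-hold-out gap per forest run (and across seeds).

    For a list of results, adds a sign-test style count of how often OOB
    exceeded hold-out per run.
    """
    if isinstance(results, ExperimentResults):
        results = [results]
    rows = []
    for res in results:
        if set(res.oob_vs_holdout) != {"rf", "rf_position"}:
            raise ValueError("results are missing one of the forest runs")
        for name, d in res.oob_vs_holdout.items():
            rows.append({
                "seed": res.config.seed, "run": name,
                "oob": d["oob_var_explained"], "holdout": d["holdout_var_explained"],
                "gap": d["gap"], "ratio": d["ratio"],
            })
    df = pd.DataFrame(rows)
    df["oob_exceeds_holdout"] = df["gap"] > 0
    return df
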