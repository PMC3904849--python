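"""Synthetic landscape generator.

Produces co-registered raster stacks with the statistical structure the
upscaling comparison depends on: smooth terrain, fractional-cover fields
that sum to 100% per pixel, a many-class categorical habitat mosaic,
a canopy-height field driven partly by those covariates and partly by a
*purely spatial* autocorrelated residual, and partial LiDAR coverage laid
out as parallel flight strips.

The purely spatial residual is the load-bearing ingredient: it is carbon
variation that no wall-to-wall covariate explains, so a learner can only
capture it through position information.  Its share of the total variance
(``grf_sill_resid`` against the covariate effect sizes) is the dial that
makes position features valuable downstream.

All randomness is derived from a single integer seed, with independent
sub-streams per layer so that regenerating one layer never perturbs the
others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial import cKDTree

from .allometry import AllometryParams, acd_from_tch
from .raster import Grid, slope_aspect

__all__ = [
    "LandscapeConfig",
    "Landscape",
    "layer_rng",
    "gaussian_random_field",
    "simulate_habitat_map",
    "simulate_fractional_cover",
    "simulate_tch",
    "simulate_flightlines",
    "make_landscape",
]


def layer_rng(seed: int, layer: str) -> np.random.Generator:
    """Independent, reproducible random stream for one named layer.

    The stream is keyed by (seed, crc32(layer)), so adding or regenerating a
    layer never changes any other layer drawn from the same master seed.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(layer.encode())]))


@dataclass
class LandscapeConfig:
    """Parameters of a synthetic landscape.

    Defaults describe a 300x300-pixel landscape of 1-ha (100 m) pixels —
    9,000 ha, the desk-scale analogue of a regional carbon-mapping domain —
    with ~8.5% LiDAR strip coverage and a 134-class habitat mosaic.

    Canopy height (m) is assembled as
    ``b0 + beta_elev * z(elev) + beta_pv * pv + offset[habitat] + GRF + noise``
    clipped to ``[0, tch_max]``, where ``z(elev)`` is standardized elevation,
    ``pv`` is the photosynthetic-vegetation fraction in [0, 1], and ``GRF``
    is a zero-mean exponential-covariance Gaussian random field with range
    ``grf_range_resid`` (m) and variance ``grf_sill_resid`` (m^2) — the
    purely spatial residual.
    """

    n_rows: int = 300
    n_cols: int = 300
    cell_size: float = 100.0
    seed: int = 0
    # terrain
    elev_mean: float = 500.0
    elev_sd: float = 250.0
    grf_range_elev: float = 5000.0
    # purely spatial canopy-height residual
    grf_range_resid: float = 3000.0
    grf_sill_resid: float = 36.0
    # covariate-driven canopy height
    tch_b0: float = 22.0
    beta_elev: float = -4.0
    beta_pv: float = 10.0
    habitat_sd: float = 2.0
    n_habitat: int = 134
    noise_sd: float = 1.5
    tch_max: float = 50.0
    # LiDAR sampling
    coverage: float = 0.085
    strip_width_px: int = 2
    strip_orientation: str = "ns"
    # fractional cover smoothness
    grf_range_cover: float = 2000.0

    def __post_init__(self) -> None:
        if not (0 < self.coverage <= 1):
            raise ValueError(f"coverage must be in (0, 1], got {self.coverage}")
        if self.n_habitat < 1:
            raise ValueError("n_habitat must be >= 1")
        if not (self.tch_max > self.tch_b0 > 0):
            raise ValueError("need tch_max > tch_b0 > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "LandscapeConfig":
        return cls(**d)


@dataclass
class Landscape:
    """Bundle of co-registered layers on one grid geometry."""

    elevation: Grid
    slope: Grid
    aspect: Grid
    frac_soil: Grid
    frac_pv: Grid
    frac_npv: Grid
    habitat: Grid
    tch: Grid
    acd_true: Grid
    lidar_mask: Grid
    config: LandscapeConfig

    _CONTINUOUS = ("frac_soil", "frac_pv", "frac_npv", "elevation", "slope", "aspect")

    def layers(self) -> dict[str, Grid]:
        return {
            name: getattr(self, name)
            for name in (
                "elevation", "slope", "aspect", "frac_soil", "frac_pv",
                "frac_npv", "habitat", "tch", "acd_true", "lidar_mask",
            )
        }

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevation.shape


def gaussian_random_field(
    shape: tuple[int, int],
    correlation_range: float,
    sill: float,
    seed,
    cell_size: float = 1.0,
) -> Grid:
    """Stationary zero-mean Gaussian random field with exponential covariance.

    The covariance is ``C(h) = sill * exp(-h / correlation_range)`` with ``h``
    in map units.  Sampling uses circulant embedding on a doubled torus:
    the target covariance is laid out on the torus, its FFT gives the
    spectral weights, and filtering white noise through their square root
    yields a field with (up to clipping of tiny negative eigenvalues) the
    exact requested covariance.  Deterministic given the seed.
    """
    n_r, n_c = shape
    if sill <= 0:
        return Grid(np.zeros(shape), cell_size=cell_size)
    if correlation_range <= 0:
        raise ValueError("correlation_range must be positive when sill > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m_r, m_c = 2 * n_r, 2 * n_c
    ir = np.minimum(np.arange(m_r), m_r - np.arange(m_r))
    ic = np.minimum(np.arange(m_c), m_c - np.arange(m_c))
    h = np.hypot(ir[:, None], ic[None, :]) * cell_size
    cov = sill * np.exp(-h / correlation_range)
    lam = np.fft.fft2(cov).real
    lam = np.clip(lam, 0.0, None)
    eps = rng.standard_normal((m_r, m_c))
    z = np.fft.ifft2(np.sqrt(lam) * np.fft.fft2(eps)).real
    return Grid(z[:n_r, :n_c].copy(), cell_size=cell_size)


def simulate_habitat_map(shape: tuple[int, int], n_classes: int, seed) -> Grid:
    """Categorical habitat mosaic as a Voronoi tessellation of random centroids.

    Every pixel takes the code of its nearest centroid, so each class is a
    single convex (hence 4-connected) patch.  Codes lie in [0, n_classes).
    """
    n_r, n_c = shape
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    if n_classes > n_r * n_c:
        raise ValueError(f"n_classes={n_classes} exceeds pixel count {n_r * n_c}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_classes == 1:
        return Grid(np.zeros(shape, dtype=np.int64), nodata=-1)
    centroids = rng.uniform(low=(0, 0), high=(n_r, n_c), size=(n_classes, 2))
    rr, cc = np.mgrid[0:n_r, 0:n_c]
    pts = np.column_stack([rr.ravel() + 0.5, cc.ravel() + 0.5])
    _, codes = cKDTree(centroids).query(pts)
    return Grid(codes.reshape(shape).astype(np.int64), nodata=-1)


def simulate_fractional_cover(
    shape: tuple[int, int],
    seed,
    cell_size: float = 1.0,
    correlation_range: float = 20.0,
) -> tuple[Grid, Grid, Grid]:
    """Smooth soil / PV / NPV percent-cover fields summing to exactly 100.

    Three independent Gaussian random fields are shifted (forest-dominated
    landscape: PV high, bare soil low) and passed through a softmax, so the
    three fractions are smooth, lie in [0, 100] and sum to 100 per pixel.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    offsets = {"soil": -2.5, "pv": 2.0, "npv": -1.0}
    logits = []
    for name, off in offsets.items():
        f = gaussian_random_field(shape, correlation_range, 1.0, rng, cell_size=cell_size)
        logits.append(f.values + off)
    logits = np.stack(logits)
    logits -= logits.max(axis=0, keepdims=True)
    ex = np.exp(logits)
    frac = 100.0 * ex / ex.sum(axis=0, keepdims=True)
    soil, pv, npv = (Grid(frac[i].copy(), cell_size=cell_size) for i in range(3))
    return soil, pv, npv


def simulate_tch(
    elevation: Grid,
    frac_pv: Grid,
    habitat: Grid,
    config: LandscapeConfig,
    seed,
) -> Grid:
    """Canopy-height field: covariate signal + habitat offsets + spatial residual.

    ``tch = clip(b0 + beta_elev * z(elev) + beta_pv * pv + offset[h]
                 + GRF(range_resid, sill_resid) + N(0, noise_sd), 0, tch_max)``
    with habitat offsets drawn once per class from N(0, habitat_sd).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    elev = np.asarray(elevation.values, dtype=float)
    sd = elev.std()
    z = (elev - elev.mean()) / sd if sd > 0 else np.zeros_like(elev)
    pv = np.asarray(frac_pv.values, dtype=float) / 100.0
    offsets = rng.normal(0.0, config.habitat_sd, size=config.n_habitat) if config.habitat_sd > 0 else np.zeros(config.n_habitat)
    hab_term = offsets[np.asarray(habitat.values, dtype=int)]
    resid = gaussian_random_field(
        elevation.shape, config.grf_range_resid, config.grf_sill_resid, rng,
        cell_size=elevation.cell_size,
    ).values
    noise = rng.normal(0.0, config.noise_sd, size=elevation.shape) if config.noise_sd > 0 else 0.0
    tch = config.tch_b0 + config.beta_elev * z + config.beta_pv * pv + hab_term + resid + noise
    return elevation.like(np.clip(tch, 0.0, config.tch_max))


def simulate_flightlines(
    shape: tuple[int, int],
    coverage: float,
    strip_width_px: int = 2,
    orientation: str = "ns",
    seed=None,
) -> Grid:
    """Parallel LiDAR flight strips covering approximately ``coverage`` of the area.

    Strips of ``strip_width_px`` rows or columns are placed at random offsets
    (without replacement) until the covered fraction is within one percentage
    point of the target, or exceeds it on the last strip.  ``orientation``
    "ns" gives north-south (column) strips, "ew" east-west (row) strips.
    """
    if not coverage > 0:
        raise ValueError(f"coverage must be positive, got {coverage}")
    coverage = min(coverage, 1.0)
    n_r, n_c = shape
    mask = np.zeros(shape, dtype=bool)
    if coverage == 1.0:
        mask[:] = True
        return Grid(mask, nodata=-1)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_lines = n_c if orientation == "ns" else n_r
    if orientation not in ("ns", "ew"):
        raise ValueError(f"orientation must be 'ns' or 'ew', got {orientation!r}")
    starts = rng.permutation(max(1, n_lines - strip_width_px + 1))
    total = n_r * n_c
    for s in starts:
        if mask.sum() / total >= coverage - 0.01:
            break
        if orientation == "ns":
            mask[:, s : s + strip_width_px] = True
        else:
            mask[s : s + strip_width_px, :] = True
    return Grid(mask, nodata=-1)


def make_landscape(config: LandscapeConfig) -> Landscape:
    """Generate a full co-registered landscape from a config.

    Layer order and sub-seeding are fixed: elevation, fractional cover,
    habitat, canopy height, flightlines each consume their own named random
    stream derived from ``config.seed``, so the same config reproduces the
    landscape bit-for-bit.
    """
    shape = (config.n_rows, config.n_cols)
    cs = config.cell_size
    geo = dict(origin_x=0.0, origin_y=config.n_rows * cs, cell_size=cs)

    elev_field = gaussian_random_field(
        shape, config.grf_range_elev, config.elev_sd**2,
        layer_rng(config.seed, "elevation"), cell_size=cs,
    ).values
    elevation = Grid(np.clip(config.elev_mean + elev_field, 0.0, None), **geo)
    slope, aspect = slope_aspect(elevation)

    soil, pv, npv = simulate_fractional_cover(
        shape, layer_rng(config.seed, "cover"), cell_size=cs,
        correlation_range=config.grf_range_cover,
    )
    soil = Grid(soil.values, **geo)
    pv = Grid(pv.values, **geo)
    npv = Grid(npv.values, **geo)

    habitat_plain = simulate_habitat_map(shape, config.n_habitat, layer_rng(config.seed, "habitat"))
    habitat = Grid(habitat_plain.values, nodata=-1, **geo)

    tch = simulate_tch(elevation, pv, habitat, config, layer_rng(config.seed, "tch"))
    acd_true = acd_from_tch(tch)

    strips = simulate_flightlines(
        shape, config.coverage, config.strip_width_px,
        config.strip_orientation, layer_rng(config.seed, "flightlines"),
    )
    lidar_mask = Grid(strips.values, nodata=-1, **geo)

    return Landscape(
        elevation=elevation, slope=slope, aspect=aspect,
        frac_soil=soil, frac_pv=pv, frac_npv=npv,
        habitat=habitat, tch=tch, acd_true=acd_true,
        lidar_mask=lidar_mask, config=config,
    )
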