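"""Residual spatial-autocorrelation diagnostics.

Two complementary views of residual structure:

* **Moran's I** — a global cross-product index of spatial autocorrelation.
  With centered values ``z_i`` and spatial weights ``w_ij`` (zero diagonal),

      I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2,   S0 = sum_ij w_ij.

  Its expectation under spatial independence is ``-1/(n-1)``; the variance
  and two-sided p-value use the classical normality approximation.  The
  default weights are inverse Euclidean distance.

* **Omnidirectional empirical semivariogram** — half the mean squared
  difference between observation pairs as a function of their separation,
  with a saturating Weibull-shaped curve ``gamma(h) = a(1 - exp(-(h/b)^c))``
  fitted by count-weighted least squares.  ``h90 = b (ln 10)^(1/c)`` is the
  distance at which the fitted curve reaches 90% of its asymptote ``a`` —
  the reported effective range.

Both diagnostics run on random coordinate subsamples; the same subsample is
reused across methods being compared so their residual statistics are
spatially consistent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.spatial.distance import cdist

__all__ = [
    "MoranResult",
    "Variogram",
    "WeibullVariogramFit",
    "subsample_indices",
    "morans_i",
    "empirical_variogram",
    "fit_weibull_variogram",
]


def subsample_indices(valid_mask: np.ndarray, n: int, seed: int) -> np.ndarray:
    """Uniform without-replacement subsample of flat indices of True pixels.

    Fixing the seed fixes the subset, so all methods under comparison can be
    diagnosed on the same locations.  Requesting more than available returns
    every valid index with a warning.
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    idx = np.flatnonzero(np.asarray(valid_mask).astype(bool).ravel())
    if idx.size == 0:
        raise ValueError("no valid pixels to subsample")
    if n >= idx.size:
        if n > idx.size:
            warnings.warn(f"requested {n} indices but only {idx.size} valid; using all",
                          stacklevel=2)
        return np.sort(idx)
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(idx, size=n, replace=False))


@dataclass
class MoranResult:
    """Moran's I with its normality-approximation null distribution."""

    I: float
    expected: float
    sd: float
    z: float
    p_two_sided: float
    n: int
    weight_spec: str


def _inverse_distance_weights(coords: np.ndarray) -> np.ndarray:
    d = cdist(coords, coords)
    off = ~np.eye(len(coords), dtype=bool)
    if np.any(d[off] == 0):
        ii, jj = np.nonzero((d == 0) & off)
        raise ValueError(f"coincident points at indices {ii[0]} and {jj[0]}: "
                         "inverse-distance weights are undefined")
    w = np.zeros_like(d)
    w[off] = 1.0 / d[off]
    return w


def morans_i(
    values: np.ndarray,
    coords: np.ndarray,
    weights: np.ndarray | None = None,
    row_standardize: bool = False,
) -> MoranResult:
    """Moran's I with inverse-distance weights and a normal-approximation test.

    Parameters
    ----------
    values : array, shape (n,)
    coords : array, shape (n, 2)
        Planar coordinates (map units).
    weights : array, shape (n, n), optional
        Spatial weights with zero diagonal; default inverse Euclidean
        distance.
    row_standardize : bool
        Scale each row of the weight matrix to sum to 1 before computing.
    """
    x = np.asarray(values, dtype=float).ravel()
    coords = np.asarray(coords, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError(f"Moran's I needs n >= 3, got {n}")
    if coords.shape != (n, 2):
        raise ValueError(f"coords must be (n, 2), got {coords.shape}")
    if np.var(x) == 0:
        raise ValueError("Moran's I is undefined for zero-variance values")
    spec = "inverse_distance"
    if weights is None:
        w = _inverse_distance_weights(coords)
    else:
        w = np.asarray(weights, dtype=float).copy()
        np.fill_diagonal(w, 0.0)
        spec = "custom"
    if row_standardize:
        rs = w.sum(axis=1, keepdims=True)
        w = np.divide(w, rs, out=np.zeros_like(w), where=rs > 0)
        spec += "|row_standardized"

    z = x - x.mean()
    s0 = w.sum()
    num = z @ w @ z
    I = (n / s0) * num / (z @ z)

    # Cliff-Ord moments under the normality assumption
    e_i = -1.0 / (n - 1)
    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2 = ((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum()
    var = (n * n * s1 - n * s2 + 3.0 * s0 * s0) / ((n * n - 1.0) * s0 * s0) - e_i * e_i
    sd = float(np.sqrt(var))
    zscore = (I - e_i) / sd
    p = float(2.0 * stats.norm.sf(abs(zscore)))
    return MoranResult(I=float(I), expected=e_i, sd=sd, z=float(zscore),
                       p_two_sided=p, n=n, weight_spec=spec)


@dataclass
class Variogram:
    """Empirical omnidirectional semivariogram.

    ``gamma`` is NaN in lag bins with no pairs; ``counts`` gives the number
    of unordered pairs per bin.
    """

    bin_centers: np.ndarray
    gamma: np.ndarray
    counts: np.ndarray
    max_lag: float


def empirical_variogram(
    values: np.ndarray,
    coords: np.ndarray,
    n_lags: int = 15,
    max_lag: float | None = None,
    chunk: int = 2000,
) -> Variogram:
    """Semivariance over unordered pairs, in equal-width lag bins.

    ``gamma(h_k) = (1 / (2 |N_k|)) * sum_{(i,j) in N_k} (z_i - z_j)^2`` over
    pairs whose separation falls in bin k.  ``max_lag`` defaults to half the
    maximum pairwise distance.  Pairs are accumulated in blocks so large
    subsamples never materialize the full distance matrix.
    """
    z = np.asarray(values, dtype=float).ravel()
    coords = np.asarray(coords, dtype=float)
    n = z.size
    if n < 2:
        raise ValueError("variogram needs at least two points")
    if n_lags < 1:
        raise ValueError("n_lags must be >= 1")
    if max_lag is None:
        lo = coords.min(axis=0)
        hi = coords.max(axis=0)
        max_lag = 0.5 * float(np.hypot(*(hi - lo)))
    if not max_lag > 0:
        raise ValueError(f"max_lag must be positive, got {max_lag}")
    edges = np.linspace(0.0, max_lag, n_lags + 1)
    sq_sum = np.zeros(n_lags)
    counts = np.zeros(n_lags, dtype=np.int64)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d = cdist(coords[start:stop], coords)
        dz2 = (z[start:stop, None] - z[None, :]) ** 2
        # keep each unordered pair once: j > i
        jj = np.arange(n)[None, :]
        ii = np.arange(start, stop)[:, None]
        keep = (jj > ii) & (d <= max_lag)
        which = np.clip(np.digitize(d[keep], edges) - 1, 0, n_lags - 1)
        np.add.at(sq_sum, which, dz2[keep])
        np.add.at(counts, which, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(counts > 0, sq_sum / (2.0 * np.maximum(counts, 1)), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return Variogram(bin_centers=centers, gamma=gamma, counts=counts, max_lag=float(max_lag))


@dataclass
class WeibullVariogramFit:
    """Fitted saturating curve gamma(h) = a(1 - exp(-(h/b)^c)) and its h90."""

    a: float
    b: float
    c: float
    h90: float
    converged: bool

    def __call__(self, h) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        return self.a * (1.0 - np.exp(-np.power(h / self.b, self.c)))


def _weibull_gamma(h, a, b, c):
    return a * (1.0 - np.exp(-np.power(h / b, c)))


def fit_weibull_variogram(variogram: Variogram) -> WeibullVariogramFit:
    """Count-weighted least-squares fit of the Weibull-shaped variogram curve.

    Multi-start Levenberg-Marquardt over a grid of shape/scale starts, with
    pair counts as weights.  ``h90 = b (ln 10)^(1/c)`` satisfies
    ``gamma(h90) = 0.9 a`` exactly.  A flat variogram (no spatial structure)
    or a failed optimization returns ``converged=False`` with NaN h90.
    """
    occupied = variogram.counts > 0
    h = variogram.bin_centers[occupied]
    g = variogram.gamma[occupied]
    w = variogram.counts[occupied].astype(float)
    if occupied.sum() < 4:
        raise ValueError(f"need >= 4 occupied lag bins, got {int(occupied.sum())}")
    g_spread = g.max() - g.min()
    if g_spread <= 0 or g.max() <= 0:
        return WeibullVariogramFit(float(np.mean(g)), float("nan"), float("nan"),
                                   float("nan"), converged=False)
    # fit in normalized units (h / h_max, gamma / gamma_max) so the optimizer
    # sees O(1) parameters regardless of map scale
    h_scale = float(h.max())
    g_scale = float(g.max())
    hs = h / h_scale
    gs = g / g_scale
    sigma = 1.0 / np.sqrt(w)
    best = None
    for c0 in (0.8, 1.0, 1.5, 2.5):
        for b0 in (0.3, 0.7):
            try:
                popt, _ = optimize.curve_fit(
                    _weibull_gamma, hs, gs, p0=(1.0, b0, c0), sigma=sigma,
                    # the asymptote cannot stray far above the observed plateau,
                    # and the scale cannot exceed a few multiples of the lag span
                    bounds=([0.0, 1e-6, 0.05], [2.0, 10.0, 20.0]),
                    maxfev=5000,
                )
            except (RuntimeError, ValueError):
                continue
            resid = (_weibull_gamma(hs, *popt) - gs) / sigma
            sse = float(resid @ resid)
            if best is None or sse < best[0]:
                best = (sse, popt)
    if best is None:
        return WeibullVariogramFit(float("nan"), float("nan"), float("nan"),
                                   float("nan"), converged=False)
    a, b, c = (float(v) for v in best[1])
    a *= g_scale
    b *= h_scale
    h90 = b * np.log(10.0) ** (1.0 / c)
    return WeibullVariogramFit(a=a, b=b, c=c, h90=float(h90), converged=True)
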