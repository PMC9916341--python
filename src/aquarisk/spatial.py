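"""Spatial interpolation (IDW and ordinary kriging) and five-class
vulnerability classification of interpolated surfaces.

Ordinary kriging solves, for each query point, the augmented system

    [ Gamma  1 ] [ w  ]   [ gamma0 ]
    [ 1^T    0 ] [ mu ] = [ 1      ]

where Gamma is the matrix of pairwise semivariances between data points and
gamma0 the vector of semivariances to the query; the unbiasedness constraint
makes the weights sum to one.  The prediction variance is
w . gamma0 + mu.  Variograms are fitted to the method-of-moments empirical
semivariogram by least squares (spherical / exponential / gaussian).

Coordinates are treated as planar; lon/lat input is used as-is with a
logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist

log = logging.getLogger("aquarisk")

VULNERABILITY_CLASSES = ("lowest", "low", "medium", "potentially_high", "highest")


@dataclass(frozen=True)
class Variogram:
    """A bounded semivariogram model gamma(h)."""

    model: str  # spherical | exponential | gaussian
    nugget: float
    sill: float  # total sill (nugget + partial sill)
    range_: float

    def __post_init__(self) -> None:
        if self.model not in ("spherical", "exponential", "gaussian"):
            raise ValueError(f"unknown variogram model {self.model!r}")
        if not (self.sill >= self.nugget >= 0.0):
            raise ValueError("need sill >= nugget >= 0")
        if self.range_ <= 0:
            raise ValueError("range must be positive")

    def __call__(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        c = self.sill - self.nugget
        a = self.range_
        if self.model == "spherical":
            hr = np.minimum(h / a, 1.0)
            gamma = c * (1.5 * hr - 0.5 * hr**3)
        elif self.model == "exponential":
            gamma = c * (1.0 - np.exp(-3.0 * h / a))
        else:  # gaussian
            gamma = c * (1.0 - np.exp(-3.0 * (h / a) ** 2))
        return np.where(h > 0, self.nugget + gamma, 0.0)


def idw(
    points: np.ndarray,
    values: np.ndarray,
    query: np.ndarray,
    power: float = 2.0,
) -> np.ndarray:
    """Inverse-distance-weighted interpolation; exact at data points.

    Duplicate data points with conflicting values are averaged (warned).
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    query = np.atleast_2d(np.asarray(query, dtype=float))
    if power <= 0:
        raise ValueError("power must be positive")
    if len(points) == 0:
        raise ValueError("need at least one data point")
    d = cdist(query, points)
    out = np.empty(len(query))
    for i, row in enumerate(d):
        hit = row == 0.0
        if hit.any():
            vals = values[hit]
            if len(vals) > 1 and not np.allclose(vals, vals[0]):
                log.warning("IDW: duplicate points with conflicting values, averaging")
            out[i] = vals.mean()
        else:
            w = row**-power
            out[i] = np.dot(w, values) / w.sum()
    return out if out.size > 1 else out


def empirical_variogram(
    points: np.ndarray, values: np.ndarray, n_bins: int = 12
) -> tuple[np.ndarray, np.ndarray]:
    """Method-of-moments semivariogram: (bin centers, semivariances)."""
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    d = cdist(points, points)
    iu = np.triu_indices(len(points), k=1)
    h = d[iu]
    sv = 0.5 * (values[:, None] - values[None, :])[iu] ** 2
    edges = np.linspace(0.0, h.max(), n_bins + 1)
    centers, gammas = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (h > lo) & (h <= hi)
        if mask.sum() > 0:
            centers.append(0.5 * (lo + hi))
            gammas.append(sv[mask].mean())
    return np.asarray(centers), np.asarray(gammas)


def fit_variogram(
    points: np.ndarray,
    values: np.ndarray,
    model: str = "spherical",
    n_bins: int = 12,
) -> Variogram:
    """Least-squares fit of a variogram model to the empirical semivariogram."""
    h, gamma = empirical_variogram(points, values, n_bins=n_bins)
    sill0 = max(gamma.max(), 1e-12)
    range0 = max(h.max() * 0.5, 1e-9)

    def resid(theta):
        nugget, psill, rng = np.abs(theta)
        v = Variogram(model, nugget, nugget + psill, max(rng, 1e-12))
        return v(h) - gamma

    fit = least_squares(resid, x0=[0.0, sill0, range0], method="lm")
    nugget, psill, rng = np.abs(fit.x)
    return Variogram(model, float(nugget), float(nugget + psill), float(max(rng, 1e-12)))


def _ok_system(points: np.ndarray, variogram: Variogram) -> np.ndarray:
    n = len(points)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = variogram(cdist(points, points))
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    return A


def ordinary_krige(
    points: np.ndarray,
    values: np.ndarray,
    variogram: Variogram,
    query: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Ordinary-kriging predictions and variances at query points.

    Weights sum to one (unbiasedness); with zero nugget the predictor is
    exact at data points with zero variance.  A singular system from
    coincident points is jittered once and retried, then raised.
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    query = np.atleast_2d(np.asarray(query, dtype=float))
    n = len(points)
    if n < 3:
        raise ValueError("ordinary kriging needs at least 3 points")
    A = _ok_system(points, variogram)
    try:
        lu = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        log.warning("kriging system singular; jittering coincident points once")
        jitter = 1e-8 * (np.ptp(points, axis=0).max() or 1.0)
        rng = np.random.default_rng(0)
        points = points + rng.normal(scale=jitter, size=points.shape)
        A = _ok_system(points, variogram)
        lu = np.linalg.inv(A)  # raises if still singular
    preds = np.empty(len(query))
    variances = np.empty(len(query))
    for i, q in enumerate(query):
        b = np.empty(n + 1)
        b[:n] = variogram(cdist([q], points)[0])
        b[n] = 1.0
        sol = lu @ b
        w, mu = sol[:n], sol[n]
        preds[i] = float(w @ values)
        variances[i] = max(float(w @ b[:n] + mu), 0.0)
    return preds, variances


def krige_grid(
    points: np.ndarray,
    values: np.ndarray,
    variogram: Variogram | None = None,
    resolution: int = 100,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Krige onto the axis-aligned bounding-box grid of the data.

    Returns (grid_x, grid_y, predictions) with predictions shaped
    (resolution, resolution).
    """
    points = np.asarray(points, dtype=float)
    if variogram is None:
        variogram = fit_variogram(points, values)
    xs = np.linspace(points[:, 0].min(), points[:, 0].max(), resolution)
    ys = np.linspace(points[:, 1].min(), points[:, 1].max(), resolution)
    gx, gy = np.meshgrid(xs, ys)
    query = np.column_stack([gx.ravel(), gy.ravel()])
    preds, _ = ordinary_krige(points, values, variogram, query)
    return gx, gy, preds.reshape(gx.shape)


@dataclass
class RasterClassification:
    values: np.ndarray
    classes: np.ndarray  # integer class 0..4 per finite cell (-1 for NaN)
    breaks: np.ndarray  # interior break points (4 of them)
    labels: tuple[str, ...]
    constant: bool


def classify5(grid: np.ndarray) -> RasterClassification:
    """Equal-interval five-class classification between grid min and max."""
    grid = np.asarray(grid, dtype=float)
    finite = grid[np.isfinite(grid)]
    if finite.size == 0:
        raise ValueError("grid has no finite values")
    lo, hi = float(finite.min()), float(finite.max())
    if lo == hi:
        log.warning("constant grid: single-class output")
        classes = np.where(np.isfinite(grid), 0, -1)
        return RasterClassification(grid, classes, np.array([]), VULNERABILITY_CLASSES, True)
    breaks = lo + (hi - lo) / 5.0 * np.arange(1, 5)
    classes = np.full(grid.shape, -1, dtype=int)
    fin = np.isfinite(grid)
    classes[fin] = np.clip(np.searchsorted(breaks, grid[fin], side="right"), 0, 4)
    return RasterClassification(grid, classes, breaks, VULNERABILITY_CLASSES, False)
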