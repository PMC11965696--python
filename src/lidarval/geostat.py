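"""Geostatistical canopy-height mapping: empirical semivariograms,
weighted-least-squares variogram model fitting, ordinary/simple kriging,
and sequential Gaussian simulation (SGS).

Semivariogram estimator (method of moments):
    gamma_hat(h) = (1 / (2 N(h))) * sum_{pairs in bin} (v_i - v_j)^2.

Models (h >= 0; C0 nugget, C total sill, a range parameter):
    spherical:    C0 + (C - C0) * (1.5 h/a - 0.5 (h/a)^3), h < a; else C
    exponential:  C0 + (C - C0) * (1 - exp(-h / a))        (eff. range 3a)
    gaussian:     C0 + (C - C0) * (1 - exp(-(h / a)^2))

Kriging solves the usual system with a Lagrange multiplier (ordinary) or a
known mean (simple); with the covariance C(h) = sill - gamma(h) carrying
the nugget at h = 0, prediction at a data location returns the data value
exactly. SGS visits unconditioned cells along a random path, draws each
from its local kriging distribution given data plus previously simulated
cells, and back-transforms realizations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, spatial

__all__ = [
    "VariogramModel", "SimulationEnsemble",
    "transform_sqrt", "back_transform_sqrt",
    "empirical_semivariogram", "fit_variogram", "fit_best_variogram",
    "Kriging", "ordinary_kriging", "sequential_gaussian_simulation",
]

logger = logging.getLogger(__name__)

MODEL_NAMES = ("spherical", "exponential", "gaussian")


def _gamma(model: str, h, nugget: float, sill: float, rng_a: float):
    h = np.asarray(h, dtype=float)
    c = sill - nugget
    if model == "spherical":
        hr = np.minimum(h / rng_a, 1.0)
        g = nugget + c * (1.5 * hr - 0.5 * hr ** 3)
    elif model == "exponential":
        g = nugget + c * (1.0 - np.exp(-h / rng_a))
    elif model == "gaussian":
        g = nugget + c * (1.0 - np.exp(-((h / rng_a) ** 2)))
    else:
        raise ValueError(f"unknown variogram model {model!r}")
    return np.where(h == 0, nugget, g)


@dataclass
class VariogramModel:
    """A fitted (or constructed) variogram model."""

    model: str
    nugget: float
    sill: float
    range_: float
    r2: float = float("nan")
    rss: float = float("nan")

    def __post_init__(self) -> None:
        if self.model not in MODEL_NAMES:
            raise ValueError(f"unknown variogram model {self.model!r}")
        if self.nugget < 0 or self.sill < self.nugget or self.range_ <= 0:
            raise ValueError("require 0 <= nugget <= sill and range > 0")

    def gamma(self, h):
        return _gamma(self.model, h, self.nugget, self.sill, self.range_)

    def covariance(self, h):
        """C(h) = sill - gamma(h); C(0) = sill (nugget included)."""
        h = np.asarray(h, dtype=float)
        return np.where(h == 0, self.sill, self.sill - self.gamma(h))

    @property
    def nugget_to_sill_pct(self) -> float:
        """Nugget-to-sill ratio in percent (relative nugget effect)."""
        return 100.0 * self.nugget / self.sill if self.sill > 0 else 0.0


def transform_sqrt(values) -> np.ndarray:
    """Square-root transform (variance-stabilizing for height-like data)."""
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValueError("square-root transform requires nonnegative values")
    return np.sqrt(v)


def back_transform_sqrt(values) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    return v * v


def empirical_semivariogram(x, y, values, lag_width: float | None = None,
                            max_lag: float | None = None) -> pd.DataFrame:
    """Method-of-moments semivariogram binned by separation distance.

    Defaults: lag_width = mean nearest-neighbor distance; max_lag = half
    the domain diagonal. Empty bins keep their pair count of zero and a
    NaN gamma. Columns: lag (bin center), gamma, n_pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    v = np.asarray(values, dtype=float)
    if not (len(x) == len(y) == len(v)):
        raise ValueError("x, y, values must share length")
    if len(v) < 2:
        raise ValueError("need at least two samples")
    if len(v) < 30:
        logger.warning("semivariogram from only %d samples; bins may be "
                       "unstable", len(v))
    pts = np.column_stack([x, y])
    if max_lag is None:
        max_lag = 0.5 * math.hypot(x.max() - x.min(), y.max() - y.min())
    if lag_width is None:
        tree = spatial.cKDTree(pts)
        nn, _ = tree.query(pts, k=2)
        lag_width = float(np.mean(nn[:, 1]))
    d = spatial.distance.pdist(pts)
    g = 0.5 * spatial.distance.pdist(v[:, None], metric="sqeuclidean")
    nbins = max(int(math.ceil(max_lag / lag_width)), 1)
    idx = np.floor(d / lag_width).astype(int)
    keep = (d <= max_lag) & (idx < nbins)
    counts = np.bincount(idx[keep], minlength=nbins)
    sums = np.bincount(idx[keep], weights=g[keep], minlength=nbins)
    lag = (np.arange(nbins) + 0.5) * lag_width
    gamma = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame({"lag": lag, "gamma": gamma, "n_pairs": counts})


def fit_variogram(empirical: pd.DataFrame, model: str = "exponential") -> VariogramModel:
    """Weighted least squares fit of (nugget, sill, range) to the empirical
    semivariogram; weights are pair counts. Reports the unweighted RSS and
    the fit R^2 over nonempty bins. Raises on non-convergence."""
    emp = empirical[(empirical["n_pairs"] > 0)
                    & np.isfinite(empirical["gamma"])]
    if len(emp) < 4:
        raise ValueError("need at least 4 nonempty lag bins to fit")
    h = emp["lag"].to_numpy()
    g = emp["gamma"].to_numpy()
    w = emp["n_pairs"].to_numpy(float)
    sigma = 1.0 / np.sqrt(w)

    gmax = float(g.max())
    hmax = float(h.max())
    nugget0 = max(float(g[0]), 1e-9)
    best = None
    for a0 in (hmax / 6.0, hmax / 3.0, hmax):
        p0 = (min(nugget0, gmax), max(gmax, 1e-9), a0)
        try:
            popt, _ = optimize.curve_fit(
                lambda hh, c0, c, a: _gamma(model, hh, c0, max(c, c0), a),
                h, g, p0=p0, sigma=sigma,
                bounds=([0.0, 1e-12, 1e-6], [gmax * 2 + 1e-9,
                                             gmax * 10 + 1e-6, hmax * 10]),
                maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        c0, c, a = popt
        c = max(c, c0)
        resid = g - _gamma(model, h, c0, c, a)
        wsse = float(np.sum(w * resid ** 2))
        if best is None or wsse < best[0]:
            best = (wsse, (c0, c, a))
    if best is None:
        raise ValueError(f"variogram fit did not converge (model={model}, "
                         f"{len(emp)} bins, gamma range "
                         f"[{g.min():.4g}, {g.max():.4g}])")
    c0, c, a = best[1]
    resid = g - _gamma(model, h, c0, c, a)
    rss = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((g - g.mean()) ** 2))
    r2 = 1.0 - rss / ss_tot if ss_tot > 0 else float("nan")
    return VariogramModel(model=model, nugget=float(c0), sill=float(c),
                          range_=float(a), r2=r2, rss=rss)


def fit_best_variogram(empirical: pd.DataFrame,
                       models=MODEL_NAMES) -> tuple[VariogramModel, list[VariogramModel]]:
    """Fit all candidate models; return (lowest-RSS model, all fits)."""
    fits = []
    for m in models:
        try:
            fits.append(fit_variogram(empirical, m))
        except ValueError:
            continue
    if not fits:
        raise ValueError("no variogram model could be fitted")
    best = min(fits, key=lambda f: f.rss)
    return best, fits


class Kriging:
    """Ordinary or simple kriging interpolator (fit/predict style).

    Duplicate sample locations are averaged before solving. Prediction at a
    sample location reproduces the sample (the covariance keeps the nugget
    at zero separation), with zero kriging variance.
    """

    def __init__(self, model: VariogramModel, method: str = "ordinary",
                 mean: float | None = None):
        if method not in ("ordinary", "simple"):
            raise ValueError(f"unknown kriging method {method!r}")
        self.model = model
        self.method = method
        self.mean = mean

    def fit(self, x, y, values) -> "Kriging":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        v = np.asarray(values, dtype=float)
        if len(x) < 2:
            raise ValueError("kriging needs at least two samples")
        df = pd.DataFrame({"x": x, "y": y, "v": v}).groupby(
            ["x", "y"], as_index=False).mean()
        self.x_, self.y_, self.v_ = (df["x"].to_numpy(), df["y"].to_numpy(),
                                     df["v"].to_numpy())
        pts = np.column_stack([self.x_, self.y_])
        dmat = spatial.distance.squareform(spatial.distance.pdist(pts))
        cov = self.model.covariance(dmat)
        n = len(self.x_)
        if self.method == "ordinary":
            a = np.empty((n + 1, n + 1))
            a[:n, :n] = cov
            a[n, :n] = 1.0
            a[:n, n] = 1.0
            a[n, n] = 0.0
        else:
            a = cov
            if self.mean is None:
                self.mean = float(self.v_.mean())
        try:
            self._ainv = np.linalg.inv(a)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular kriging system even after "
                             "deduplication") from exc
        return self

    def predict(self, px, py) -> tuple[np.ndarray, np.ndarray]:
        """Estimate and kriging variance at prediction points."""
        px = np.atleast_1d(np.asarray(px, dtype=float))
        py = np.atleast_1d(np.asarray(py, dtype=float))
        d = np.hypot(px[:, None] - self.x_[None, :],
                     py[:, None] - self.y_[None, :])
        c0 = self.model.covariance(d)          # (m, n)
        n = len(self.x_)
        sill = self.model.sill
        if self.method == "ordinary":
            rhs = np.empty((len(px), n + 1))
            rhs[:, :n] = c0
            rhs[:, n] = 1.0
            sol = rhs @ self._ainv.T              # (m, n+1)
            w, mu = sol[:, :n], sol[:, n]
            est = w @ self.v_
            var = sill - np.sum(w * c0, axis=1) - mu
        else:
            w = c0 @ self._ainv.T
            est = self.mean + w @ (self.v_ - self.mean)
            var = sill - np.sum(w * c0, axis=1)
        return est, np.maximum(var, 0.0)

    def weights(self, px: float, py: float) -> np.ndarray:
        """Kriging weights at a single prediction point (diagnostics)."""
        d = np.hypot(px - self.x_, py - self.y_)
        c0 = self.model.covariance(d)
        if self.method == "ordinary":
            rhs = np.concatenate([c0, [1.0]])
            return (self._ainv @ rhs)[:-1]
        return self._ainv @ c0


def ordinary_kriging(x, y, values, model: VariogramModel, grid_x, grid_y,
                     method: str = "ordinary"):
    """Krige onto a grid; returns (estimate, variance) arrays of shape
    (len(grid_y), len(grid_x)), row 0 at grid_y[0]."""
    krig = Kriging(model, method=method).fit(x, y, values)
    gx, gy = np.meshgrid(np.asarray(grid_x, float), np.asarray(grid_y, float))
    est, var = krig.predict(gx.ravel(), gy.ravel())
    return est.reshape(gx.shape), var.reshape(gx.shape)


@dataclass
class SimulationEnsemble:
    """SGS output: conditional realizations plus ensemble summaries."""

    realizations: np.ndarray            # (n_real, ny, nx), back-transformed
    mean: np.ndarray
    sd: np.ndarray
    grid_x: np.ndarray
    grid_y: np.ndarray
    transform: str
    seed: int
    conditioning: pd.DataFrame = field(repr=False, default=None)

    @property
    def n_realizations(self) -> int:
        return self.realizations.shape[0]


def sequential_gaussian_simulation(x, y, values, model: VariogramModel,
                                   grid_x, grid_y, n_realizations: int = 50,
                                   seed: int = 0, transform: str = "sqrt",
                                   neighborhood: int = 16) -> SimulationEnsemble:
    """Conditional sequential Gaussian simulation on a regular grid.

    ``model`` must be fitted in the transformed space. Conditioning samples
    are migrated to their grid cells (averaged per cell) and held fixed in
    every realization; unconditioned cells are visited along a random path
    (reshuffled per realization) and drawn from the local simple-kriging
    distribution given the nearest ``neighborhood`` conditioned nodes.
    Transformed draws are floored at zero before back-transforming so the
    square-root back-transform stays monotone.
    """
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    if transform not in ("sqrt", "none"):
        raise ValueError(f"unknown transform {transform!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    v = np.asarray(values, dtype=float)
    tv = transform_sqrt(v) if transform == "sqrt" else v.copy()

    gx = np.asarray(grid_x, dtype=float)
    gy = np.asarray(grid_y, dtype=float)
    nx, ny = len(gx), len(gy)
    xx, yy = np.meshgrid(gx, gy)
    flat_x, flat_y = xx.ravel(), yy.ravel()
    ncell = nx * ny

    # migrate conditioning data to cells (nearest grid node)
    ci = np.argmin(np.abs(gx[None, :] - x[:, None]), axis=1)
    cj = np.argmin(np.abs(gy[None, :] - y[:, None]), axis=1)
    cond = pd.DataFrame({"cell": cj * nx + ci, "tv": tv}).groupby(
        "cell")["tv"].mean()
    cond_cells = cond.index.to_numpy()
    cond_vals = cond.to_numpy()
    free = np.setdiff1d(np.arange(ncell), cond_cells)
    gmean = float(tv.mean())

    reals = np.empty((n_realizations, ncell))
    for r in range(n_realizations):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), r]))
        sim = np.full(ncell, np.nan)
        sim[cond_cells] = cond_vals
        known = list(cond_cells)
        path = free.copy()
        rng.shuffle(path)
        for cell in path:
            kn = np.asarray(known)
            dx = flat_x[kn] - flat_x[cell]
            dy = flat_y[kn] - flat_y[cell]
            d = np.hypot(dx, dy)
            if len(kn) > neighborhood:
                sel = np.argpartition(d, neighborhood)[:neighborhood]
                kn, d = kn[sel], d[sel]
            if len(kn) == 0:
                mean_k, var_k = gmean, model.sill
            else:
                pts = np.column_stack([flat_x[kn], flat_y[kn]])
                cmat = model.covariance(
                    spatial.distance.squareform(spatial.distance.pdist(pts)))
                cvec = model.covariance(d)
                try:
                    w = np.linalg.solve(
                        cmat + 1e-10 * np.eye(len(kn)), cvec)
                except np.linalg.LinAlgError:
                    w = np.zeros(len(kn))
                mean_k = gmean + w @ (sim[kn] - gmean)
                var_k = max(model.sill - w @ cvec, 0.0)
            sim[cell] = mean_k + math.sqrt(var_k) * rng.standard_normal()
            known.append(cell)
        reals[r] = sim
    if transform == "sqrt":
        reals = back_transform_sqrt(np.maximum(reals, 0.0))
    reals = reals.reshape(n_realizations, ny, nx)
    conditioning = pd.DataFrame({"x": x, "y": y, "value": v})
    return SimulationEnsemble(realizations=reals,
                              mean=reals.mean(axis=0), sd=reals.std(axis=0),
                              grid_x=gx, grid_y=gy, transform=transform,
                              seed=int(seed), conditioning=conditioning)
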