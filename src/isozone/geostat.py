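"""Variography and ordinary kriging for per-plot tracer isoscapes.

The interpolation recipe: build empirical semivariograms of each tracer
under several lag segmentations, fit a set of parametric semivariance
models by weighted least squares (weights N_j / h_j**2), and pick the
(model, segmentation) pair with the smallest leave-one-out RMSE, ties
broken by the higher R-squared of the predicted-on-measured regression.
The winning model drives ordinary kriging onto the plot grid.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from scipy.spatial.distance import pdist, squareform

from .geodata import PlotExtent, PlotGrid, Raster

log = logging.getLogger(__name__)

MODEL_NAMES = ("nugget", "exponential", "spherical", "gaussian", "linear", "power")

#: segmentation catalogue used throughout: five uniform lag widths plus one
#: non-uniform set of boundaries (metres)
DEFAULT_LAG_WIDTHS = (1.0, 1.2, 2.0, 3.0, 4.0)
NONUNIFORM_BOUNDS = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 9.0, 12.0, 15.0, 18.0)


def default_cutoff(extent: PlotExtent) -> float:
    """One third of the plot's longest diagonal (m); 20 x 50 m -> 17.95 m."""
    return extent.diagonal / 3.0


@dataclass(frozen=True)
class LagSegmentation:
    """Ordered lag-bin boundaries up to a cutoff. Bin j is (b[j-1], b[j]],
    with the first bin starting at 0."""

    bounds: tuple[float, ...]
    name: str = ""

    def __post_init__(self) -> None:
        b = np.asarray(self.bounds, dtype=float)
        if b.size < 2:
            raise ValueError("need at least 2 bins")
        if not np.all(np.diff(b) > 0) or b[0] <= 0:
            raise ValueError("bin boundaries must be strictly increasing and positive")

    @classmethod
    def uniform(cls, width: float, cutoff: float) -> "LagSegmentation":
        n = max(2, int(math.ceil(cutoff / width - 1e-9)))
        bounds = tuple(min(width * (j + 1), cutoff) for j in range(n))
        # drop a duplicated last boundary if cutoff is an exact multiple
        bounds = tuple(dict.fromkeys(bounds))
        return cls(bounds, name=f"uniform_{width:g}m")

    @classmethod
    def nonuniform(cls, bounds=NONUNIFORM_BOUNDS, cutoff: float | None = None) -> "LagSegmentation":
        bs = tuple(b for b in bounds if cutoff is None or b <= cutoff + 1e-9)
        return cls(bs, name="nonuniform")


def default_segmentations(cutoff: float) -> list[LagSegmentation]:
    segs = [LagSegmentation.uniform(w, cutoff) for w in DEFAULT_LAG_WIDTHS]
    segs.append(LagSegmentation.nonuniform(cutoff=max(cutoff, NONUNIFORM_BOUNDS[-1])))
    return segs


@dataclass
class EmpiricalVariogram:
    """Binned semivariance estimates: mean lag, gamma-hat and pair count per bin."""

    lags: np.ndarray        # mean pair separation per retained bin (m)
    gammas: np.ndarray      # semivariance per bin (squared tracer units)
    counts: np.ndarray      # pair counts
    cutoff: float
    segmentation: LagSegmentation


def empirical_variogram(
    x: np.ndarray, y: np.ndarray, z: np.ndarray,
    seg: LagSegmentation, cutoff: float,
) -> EmpiricalVariogram:
    """Matheron estimator: gamma_j = (1 / 2 N_j) * sum (z_i - z_k)^2 over
    pairs whose separation falls in bin j; pairs beyond the cutoff are
    excluded; empty bins are dropped."""
    pts = np.column_stack([x, y])
    if len(pts) < 2:
        raise ValueError("need at least 2 samples")
    d = pdist(pts)
    dz2 = pdist(z.reshape(-1, 1), metric="sqeuclidean")
    keep = d <= cutoff + 1e-12
    if not keep.any():
        raise ValueError("no pairs within cutoff")
    d, dz2 = d[keep], dz2[keep]
    bounds = np.concatenate([[0.0], np.asarray(seg.bounds)])
    idx = np.searchsorted(bounds, d, side="left") - 1
    idx[d <= bounds[1]] = np.clip(idx[d <= bounds[1]], 0, None)
    in_range = (idx >= 0) & (idx < len(seg.bounds))
    d, dz2, idx = d[in_range], dz2[in_range], idx[in_range]
    nbins = len(seg.bounds)
    counts = np.bincount(idx, minlength=nbins)
    sums = np.bincount(idx, weights=dz2, minlength=nbins)
    dsum = np.bincount(idx, weights=d, minlength=nbins)
    retained = counts > 0
    return EmpiricalVariogram(
        lags=dsum[retained] / counts[retained],
        gammas=sums[retained] / (2.0 * counts[retained]),
        counts=counts[retained],
        cutoff=cutoff,
        segmentation=seg,
    )


# ---------------------------------------------------------------------------
# parametric models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariogramModel:
    """Named semivariance function with nugget c0, partial sill c and range a.

    ``power`` uses ``a`` as the scale and carries an exponent p in (0, 2);
    ``linear`` uses slope = c / a. gamma(0) = 0 for every model and the
    nugget contributes c0 for any h > 0.
    """

    name: str
    nugget: float = 0.0
    psill: float = 1.0
    range_: float = 1.0
    exponent: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}; choose from {MODEL_NAMES}")
        if self.nugget < 0 or self.psill < 0 or self.range_ <= 0:
            raise ValueError("require c0 >= 0, c >= 0, a > 0")
        if self.name == "power" and not (0 < self.exponent < 2):
            raise ValueError("power exponent must lie in (0, 2)")

    @property
    def sill(self) -> float:
        return self.nugget + self.psill

    @property
    def n_free(self) -> int:
        return {"nugget": 1, "linear": 2, "power": 3}.get(self.name, 3)

    def __call__(self, h) -> np.ndarray:
        return model_semivariance(self, h)


def model_semivariance(model: VariogramModel, h) -> np.ndarray:
    """Closed-form gamma(h); negative lags are an error."""
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("negative lag distance")
    c0, c, a = model.nugget, model.psill, model.range_
    name = model.name
    if name == "nugget":
        struct = np.zeros_like(h)
    elif name == "exponential":
        struct = c * (1.0 - np.exp(-h / a))
    elif name == "spherical":
        hr = np.minimum(h / a, 1.0)
        struct = c * (1.5 * hr - 0.5 * hr**3)
    elif name == "gaussian":
        struct = c * (1.0 - np.exp(-((h / a) ** 2)))
    elif name == "linear":
        struct = c * h / a
    elif name == "power":
        struct = c * (h / a) ** model.exponent
    out = struct + np.where(h > 0, c0, 0.0)
    return out if out.ndim else float(out)


def _pack(model_name: str, theta: np.ndarray) -> VariogramModel:
    if model_name == "nugget":
        return VariogramModel("nugget", nugget=theta[0], psill=0.0, range_=1.0)
    if model_name == "power":
        return VariogramModel("power", nugget=theta[0], psill=theta[1], range_=1.0,
                              exponent=theta[2])
    return VariogramModel(model_name, nugget=theta[0], psill=theta[1],
                          range_=max(theta[2], 1e-9))


def _profiled_wls(w: np.ndarray, g: np.ndarray, f: np.ndarray) -> tuple[float, float, float]:
    """Solve min_{c0,c >= 0} sum w*(g - c0 - c*f)^2 in closed form.

    The model is linear in (nugget, partial sill) once the structural shape
    ``f = gamma_unit(h; a)`` is fixed; the non-negativity constraints leave
    only three candidate solutions (interior, c0=0 edge, c=0 edge).
    """
    sw = w.sum()
    swf = (w * f).sum()
    swff = (w * f * f).sum()
    swg = (w * g).sum()
    swfg = (w * f * g).sum()
    swgg = (w * g * g).sum()

    def obj(c0, c):
        return swgg - 2 * c0 * swg - 2 * c * swfg + c0 * c0 * sw \
            + 2 * c0 * c * swf + c * c * swff

    cands = []
    det = sw * swff - swf * swf
    if det > 1e-14 * max(sw * swff, 1e-300):
        c0 = (swff * swg - swf * swfg) / det
        c = (sw * swfg - swf * swg) / det
        if c0 >= 0 and c >= 0:
            cands.append((c0, c))
    # pure-nugget edge before the zero-nugget edge: degenerate (flat) data
    # ties resolve to the structure-free model
    cands.append((max(swg / sw, 0.0), 0.0))
    c_edge = max(swfg / swff, 0.0) if swff > 0 else 0.0
    cands.append((0.0, c_edge))
    best = min(cands, key=lambda t: obj(*t))
    return best[0], best[1], max(obj(*best), 0.0)


def fit_variogram(
    emp: EmpiricalVariogram,
    model_name: str,
    n_restarts: int = 5,
    x0: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[VariogramModel, float, bool]:
    """Weighted least squares fit of a parametric model to binned semivariances.

    Minimizes ``sum_j w_j (gamma_hat_j - gamma(h_j))**2`` with
    ``w_j = N_j / h_j**2``, subject to c0 >= 0, c >= 0, a > 0. Nugget and
    partial sill enter linearly, so they are profiled out in closed form
    and only the range (or power exponent) is searched: a geometric
    candidate grid bracketed by the lag span, refined by bounded scalar
    minimization. Deterministic; ``x0`` injects an extra warm-start range
    into the grid (used by the leave-one-out refits), and ``n_restarts``
    only controls the grid density.

    Returns (model, wls_objective, converged).
    """
    if model_name not in MODEL_NAMES:
        raise ValueError(f"unknown model {model_name!r}")
    h, g, n = emp.lags, emp.gammas, emp.counts
    npar = {"nugget": 1, "linear": 2, "power": 3}.get(model_name, 3)
    if len(h) < npar:
        raise ValueError(f"{len(h)} bins < {npar} free parameters for {model_name!r}")
    w = n / h**2
    hmax = float(h.max())
    hmin = float(h.min())

    if model_name == "nugget":
        c0 = float((w * g).sum() / w.sum())
        obj = float((w * (g - c0) ** 2).sum())
        return _pack("nugget", np.array([c0])), obj, True

    if model_name == "linear":
        # slope = c / a with a fixed at the max lag (c, a are not separately
        # identifiable for an unbounded model)
        c0, c, obj = _profiled_wls(w, g, h / hmax)
        return VariogramModel("linear", nugget=c0, psill=c, range_=hmax), obj, True

    def unit_shape(a_or_p: float) -> np.ndarray:
        if model_name == "exponential":
            return 1.0 - np.exp(-h / a_or_p)
        if model_name == "spherical":
            hr = np.minimum(h / a_or_p, 1.0)
            return 1.5 * hr - 0.5 * hr**3
        if model_name == "gaussian":
            return 1.0 - np.exp(-((h / a_or_p) ** 2))
        return (h / hmax) ** a_or_p  # power: search the exponent

    if model_name == "power":
        lo, hi = 0.05, 1.95
    else:
        lo, hi = hmin / 4.0, 4.0 * hmax
    dense = max(20, 10 * int(n_restarts))
    grid = list(np.geomspace(lo, hi, dense))
    if x0 is not None and len(np.atleast_1d(x0)) >= 3:
        warm = float(np.atleast_1d(x0)[2])
        if lo < warm < hi:
            grid.append(warm)

    def objective(a):
        return _profiled_wls(w, g, unit_shape(a))[2]

    a_best = min(grid, key=objective)
    span = grid[1] / grid[0]
    res = optimize.minimize_scalar(
        objective, bounds=(max(lo, a_best / span**2), min(hi, a_best * span**2)),
        method="bounded", options={"xatol": 1e-10 * a_best})
    a_star = float(res.x) if res.fun <= objective(a_best) else a_best
    c0, c, obj = _profiled_wls(w, g, unit_shape(a_star))
    if model_name == "power":
        return VariogramModel("power", nugget=c0, psill=c, range_=hmax,
                              exponent=a_star), obj, True
    return VariogramModel(model_name, nugget=c0, psill=c, range_=a_star), obj, True


# ---------------------------------------------------------------------------
# ordinary kriging
# ---------------------------------------------------------------------------


@dataclass
class Isoscape:
    """Kriged tracer surface plus kriging variance and provenance."""

    tracer: str
    units: str
    prediction: Raster
    variance: Raster
    model: VariogramModel
    sample_fingerprint: str = ""


def _ok_weights(gamma_ss: np.ndarray, gamma_s0: np.ndarray) -> tuple[np.ndarray, float]:
    """Solve one ordinary-kriging system. Returns (weights, lagrange mu)."""
    n = gamma_ss.shape[0]
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = gamma_ss
    A[n, :] = 1.0
    A[:, n] = 1.0
    A[n, n] = 0.0
    b = np.concatenate([gamma_s0, [1.0]])
    sol = linalg.solve(A, b)
    return sol[:n], sol[n]


def ordinary_krige(
    x: np.ndarray, y: np.ndarray, z: np.ndarray,
    model: VariogramModel, grid: PlotGrid, cutoff: float,
    tracer: str = "", units: str = "",
    min_neighbors: int = 8,
) -> Isoscape:
    """Ordinary kriging of samples onto the grid.

    Per cell the semivariance system, augmented with the unbiasedness
    constraint through a Lagrange multiplier, is solved for weights that sum
    to one; prediction is the weighted sum of sample values, kriging
    variance is ``sum_i lambda_i gamma(h_i0) + mu``. The neighbourhood is
    every sample within ``cutoff`` of the target cell; if fewer than
    ``min_neighbors`` qualify, all samples are used. Cells with negative
    weights (screening) are counted and logged, never clamped.
    """
    pts = np.column_stack([x, y])
    n = len(pts)
    if n < 2:
        raise ValueError("need at least 2 samples to krige")
    if model.sill == 0 and model.name != "linear" and model.name != "power":
        # identically-zero semivariance (constant field): any weights summing
        # to 1 are optimal; use the sample mean with zero kriging variance
        mean = float(np.mean(z))
        return Isoscape(
            tracer=tracer, units=units,
            prediction=Raster(grid, np.full(grid.shape, mean), units=units),
            variance=Raster(grid, np.zeros(grid.shape), units=f"({units})^2"),
            model=model,
        )
    D = squareform(pdist(pts))
    G_full = model_semivariance(model, D)
    np.fill_diagonal(G_full, 0.0)

    X, Y = grid.cell_centers()
    cx, cy = X.ravel(), Y.ravel()
    ncell = cx.size
    pred = np.empty(ncell)
    var = np.empty(ncell)
    neg_cells = 0

    d0_all = np.sqrt((cx[:, None] - x[None, :]) ** 2 + (cy[:, None] - y[None, :]) ** 2)
    within = d0_all <= cutoff
    use_all = within.sum(axis=1) < min_neighbors

    # group cells by neighbourhood set so each system is factorised once
    keys: dict[bytes, list[int]] = {}
    for i in range(ncell):
        mask = np.ones(n, dtype=bool) if use_all[i] else within[i]
        keys.setdefault(mask.tobytes(), []).append(i)

    for key, cells in keys.items():
        mask = np.frombuffer(key, dtype=bool)
        idx = np.flatnonzero(mask)
        m = idx.size
        A = np.empty((m + 1, m + 1))
        A[:m, :m] = G_full[np.ix_(idx, idx)]
        A[m, :] = 1.0
        A[:, m] = 1.0
        A[m, m] = 0.0
        try:
            lu, piv = linalg.lu_factor(A)
        except linalg.LinAlgError as exc:  # pragma: no cover
            raise linalg.LinAlgError(
                f"singular kriging system for model {model.name!r} with {m} neighbours"
            ) from exc
        cells_arr = np.asarray(cells)
        g0 = model_semivariance(model, d0_all[np.ix_(cells_arr, idx)])
        B = np.empty((m + 1, len(cells)))
        B[:m, :] = g0.T
        B[m, :] = 1.0
        sol = linalg.lu_solve((lu, piv), B)
        lam, mu = sol[:m, :], sol[m, :]
        pred[cells_arr] = lam.T @ z[idx]
        var[cells_arr] = np.einsum("ic,ci->c", lam, g0) + mu
        neg_cells += int((lam.min(axis=0) < -1e-10).sum())

    if neg_cells:
        log.info("ordinary_krige: negative weights at %d/%d cells (screening effect)",
                 neg_cells, ncell)
    var = np.maximum(var, 0.0)
    return Isoscape(
        tracer=tracer, units=units,
        prediction=Raster(grid, pred.reshape(grid.shape), units=units),
        variance=Raster(grid, var.reshape(grid.shape), units=f"({units})^2"),
        model=model,
    )


def krige_points(
    x: np.ndarray, y: np.ndarray, z: np.ndarray,
    model: VariogramModel,
    x0: np.ndarray, y0: np.ndarray,
    cutoff: float, min_neighbors: int = 8,
) -> np.ndarray:
    """Ordinary-kriging predictions at arbitrary target points."""
    if model.sill == 0 and model.name not in ("linear", "power"):
        return np.full(len(x0), float(np.mean(z)))
    preds = np.empty(len(x0))
    pts = np.column_stack([x, y])
    D = squareform(pdist(pts))
    G = model_semivariance(model, D)
    np.fill_diagonal(G, 0.0)
    for j, (px, py) in enumerate(zip(x0, y0)):
        d0 = np.hypot(x - px, y - py)
        mask = d0 <= cutoff
        if mask.sum() < min_neighbors:
            mask = np.ones(len(x), dtype=bool)
        idx = np.flatnonzero(mask)
        lam, _ = _ok_weights(G[np.ix_(idx, idx)], model_semivariance(model, d0[idx]))
        preds[j] = lam @ z[idx]
    return preds


# ---------------------------------------------------------------------------
# leave-one-out cross-validation and model selection
# ---------------------------------------------------------------------------


@dataclass
class CVResult:
    model_name: str
    segmentation: LagSegmentation
    predictions: np.ndarray
    rmse: float
    r2: float | None
    converged: bool
    fitted: VariogramModel | None = None


def loo_cross_validate(
    x: np.ndarray, y: np.ndarray, z: np.ndarray,
    model_name: str, seg: LagSegmentation, cutoff: float,
) -> CVResult:
    """Leave-one-out CV of one (model, segmentation) candidate.

    Each sample is withheld in turn; the variogram is refit to the rest
    (warm-started from the full-data fit) and the withheld location kriged.
    RMSE over the held-out predictions; R-squared from an OLS regression of
    predicted on measured (reported missing when predictions are constant).
    """
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 samples for LOO cross-validation")
    try:
        emp_full = empirical_variogram(x, y, z, seg, cutoff)
        full_model, _, conv = fit_variogram(emp_full, model_name)
    except ValueError:
        return CVResult(model_name, seg, np.full(n, np.nan), np.inf, None, False)
    if not conv:
        return CVResult(model_name, seg, np.full(n, np.nan), np.inf, None, False)
    warm = None
    if model_name not in ("nugget",):
        warm = np.array([full_model.nugget, full_model.psill,
                         full_model.exponent if model_name == "power" else full_model.range_])
    preds = np.empty(n)
    ok = True
    for i in range(n):
        keep = np.arange(n) != i
        try:
            emp_i = empirical_variogram(x[keep], y[keep], z[keep], seg, cutoff)
            mdl_i, _, conv_i = fit_variogram(emp_i, model_name, n_restarts=1, x0=warm)
            if not conv_i:
                ok = False
                break
            preds[i] = krige_points(x[keep], y[keep], z[keep], mdl_i,
                                    x[i:i + 1], y[i:i + 1], cutoff)[0]
        except (ValueError, linalg.LinAlgError):
            ok = False
            break
    if not ok:
        return CVResult(model_name, seg, np.full(n, np.nan), np.inf, None, False,
                        fitted=full_model)
    rmse = float(np.sqrt(np.mean((preds - z) ** 2)))
    if np.ptp(preds) < 1e-12 or np.ptp(z) < 1e-12:
        r2 = None
    else:
        slope, icpt, r, p, se = stats.linregress(z, preds)
        r2 = float(r**2)
    return CVResult(model_name, seg, preds, rmse, r2, True, fitted=full_model)


def select_interpolation_model(
    x: np.ndarray, y: np.ndarray, z: np.ndarray,
    cutoff: float,
    model_names=("nugget", "exponential", "spherical", "gaussian", "linear", "power"),
    segmentations: list[LagSegmentation] | None = None,
) -> tuple[VariogramModel, LagSegmentation, CVResult, pd.DataFrame]:
    """Pick the (model, segmentation) candidate with the smallest LOO RMSE.

    Ties within 1e-9 relative RMSE go to the higher R-squared, then to the
    model with fewer free parameters, then to candidate order. Returns the
    winning fitted model, segmentation, its CVResult and the full ranking
    table (one row per candidate, with a ``chosen`` marker).
    """
    segs = segmentations if segmentations is not None else default_segmentations(cutoff)
    results: list[CVResult] = []
    for seg, name in itertools.product(segs, model_names):
        results.append(loo_cross_validate(x, y, z, name, seg, cutoff))
    convergent = [r for r in results if r.converged]
    if not convergent:
        raise RuntimeError("no convergent variogram candidate")
    best = convergent[0]
    for r in convergent[1:]:
        if r.rmse < best.rmse * (1 - 1e-9):
            best = r
        elif abs(r.rmse - best.rmse) <= 1e-9 * max(best.rmse, 1e-300):
            r_r2 = -np.inf if r.r2 is None else r.r2
            b_r2 = -np.inf if best.r2 is None else best.r2
            if r_r2 > b_r2 or (r_r2 == b_r2 and
                               r.fitted.n_free < best.fitted.n_free):
                best = r
    report = pd.DataFrame(
        {
            "model": [r.model_name for r in results],
            "segmentation": [r.segmentation.name for r in results],
            "rmse": [r.rmse for r in results],
            "r2": [r.r2 for r in results],
            "converged": [r.converged for r in results],
            "chosen": [r is best for r in results],
        }
    )
    return best.fitted, best.segmentation, best, report
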