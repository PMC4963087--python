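"""Constrained-covariance Gaussian mixture models fitted by EM.

Each component covariance is decomposed as ``Sigma_k = lambda_k D_k A_k D_k^T``
with volume ``lambda_k`` (scalar), shape ``A_k`` (diagonal, det 1) and
orientation ``D_k`` (rotation). A three-letter code states which factors are
Equal across components, Variable, or the Identity:

=====  ==========================================
EII    spherical, equal volume
VII    spherical, unequal volume
EEI    diagonal, equal volume and shape
VEI    diagonal, varying volume, equal shape
EVI    diagonal, equal volume, varying shape
VVI    diagonal, varying volume and shape
EEE    ellipsoidal, equal volume, shape, orientation
EEV    ellipsoidal, equal volume and shape
VEV    ellipsoidal, equal shape
VVV    ellipsoidal, all varying
=====  ==========================================

M-steps use the closed forms where they exist and small fixed-point
iterations for the VEI/EVI/VEV couplings. Initialisation is deterministic:
Ward agglomeration of a (seeded) subsample cut at k provides hard initial
assignments, so repeated fits reproduce bit-identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, ward
from scipy.spatial.distance import cdist

log = logging.getLogger(__name__)

CODES = ("EII", "VII", "EEI", "VEI", "EVI", "VVI", "EEE", "EEV", "VEV", "VVV")

_LOG2PI = float(np.log(2.0 * np.pi))


def n_params(code: str, k: int, d: int) -> int:
    """Number of free parameters of a k-component, d-variate mixture.

    ``(k-1)`` mixing proportions + ``k*d`` means + covariance parameters
    determined by the constraint code (e.g. EII: 1; VVI: k*d;
    EEE: d(d+1)/2; VVV: k*d(d+1)/2).
    """
    if code not in CODES:
        raise ValueError(f"unknown parameterization {code!r}")
    if k < 1 or d < 1:
        raise ValueError("k >= 1 and d >= 1 required")
    orient = d * (d - 1) // 2
    cov = {
        "EII": 1,
        "VII": k,
        "EEI": d,
        "VEI": k + (d - 1),
        "EVI": 1 + k * (d - 1),
        "VVI": k * d,
        "EEE": d * (d + 1) // 2,
        "EEV": d + k * orient,
        "VEV": k + (d - 1) + k * orient,
        "VVV": k * d * (d + 1) // 2,
    }[code]
    return (k - 1) + k * d + cov


@dataclass
class MixtureFit:
    """Result of one EM fit: parameters, responsibilities and diagnostics."""

    code: str
    k: int
    weights: np.ndarray            # (k,)
    means: np.ndarray              # (k, d)
    covariances: np.ndarray        # (k, d, d)
    responsibilities: np.ndarray   # (n, k)
    loglik: float
    n: int
    d: int
    n_iter: int
    converged: bool
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def bic(self) -> float:
        return bic(self)


def bic(fit: MixtureFit) -> float:
    """BIC = 2 * loglik - m * log(n); larger is better. Missing (nan) for
    fits that did not converge."""
    if not fit.converged:
        return float("nan")
    m = n_params(fit.code, fit.k, fit.d)
    return 2.0 * fit.loglik - m * np.log(fit.n)


# ---------------------------------------------------------------------------
# covariance M-steps
# ---------------------------------------------------------------------------


def _scatter(X: np.ndarray, resp: np.ndarray, means: np.ndarray) -> np.ndarray:
    """Per-component scatter matrices W_k = sum_i z_ik (x_i-mu_k)(x_i-mu_k)^T."""
    n, d = X.shape
    k = means.shape[0]
    W = np.empty((k, d, d))
    for j in range(k):
        Xc = X - means[j]
        W[j] = (Xc * resp[:, j:j + 1]).T @ Xc
    return W


def _mstep_cov(code: str, W: np.ndarray, nk: np.ndarray, n: int, d: int,
               inner_tol: float = 1e-10, inner_max: int = 200) -> np.ndarray:
    """Maximum-likelihood covariances under the given constraint code."""
    k = W.shape[0]
    eye = np.eye(d)
    if code == "EII":
        s2 = W.trace(axis1=1, axis2=2).sum() / (n * d)
        return np.broadcast_to(s2 * eye, (k, d, d)).copy()
    if code == "VII":
        s2k = W.trace(axis1=1, axis2=2) / (nk * d)
        return s2k[:, None, None] * eye
    if code == "EEI":
        diag = np.einsum("kii->i", W) / n
        return np.broadcast_to(np.diag(diag), (k, d, d)).copy()
    if code == "VVI":
        return np.stack([np.diag(np.diagonal(W[j]) / nk[j]) for j in range(k)])
    if code == "EEE":
        S = W.sum(axis=0) / n
        return np.broadcast_to(S, (k, d, d)).copy()
    if code == "VVV":
        return W / nk[:, None, None]
    if code == "EVI":
        # Sigma_k = lambda * B_k, B_k diagonal with det 1 (closed form)
        dW = np.stack([np.diagonal(W[j]) for j in range(k)])
        dW = np.maximum(dW, 1e-300)
        dets = np.exp(np.log(dW).sum(axis=1) / d)
        B = dW / dets[:, None]
        lam = dets.sum() / n
        return np.stack([np.diag(lam * B[j]) for j in range(k)])
    if code == "VEI":
        # Sigma_k = lambda_k * B, B diagonal det 1 (fixed point)
        dW = np.maximum(np.stack([np.diagonal(W[j]) for j in range(k)]), 1e-300)
        B = np.ones(d)
        lam = dW.sum(axis=1) / (nk * d)
        for _ in range(inner_max):
            lam_new = (dW / B).sum(axis=1) / (nk * d)
            Bn = (dW / np.maximum(lam_new, 1e-300)[:, None]).sum(axis=0)
            Bn = np.maximum(Bn, 1e-300)
            Bn = Bn / np.exp(np.log(Bn).sum() / d)
            if np.max(np.abs(lam_new - lam)) < inner_tol * max(lam_new.max(), 1e-300) \
               and np.max(np.abs(Bn - B)) < inner_tol:
                lam, B = lam_new, Bn
                break
            lam, B = lam_new, Bn
        return np.stack([np.diag(lam[j] * B) for j in range(k)])
    # rotating families: eigendecompose each scatter, eigenvalues descending
    Ls, Oms = [], []
    for j in range(k):
        vals, vecs = np.linalg.eigh(W[j])
        order = np.argsort(vals)[::-1]
        Ls.append(vecs[:, order])
        Oms.append(np.maximum(vals[order], 0.0))
    Om = np.stack(Oms)            # (k, d) descending
    if code == "EEV":
        Lam = Om.sum(axis=0) / n  # shared lambda*A eigenvalues
        return np.stack([Ls[j] @ np.diag(Lam) @ Ls[j].T for j in range(k)])
    if code == "VEV":
        # Sigma_k = lambda_k D_k A D_k^T, |A| = 1 (fixed point)
        Om_safe = np.maximum(Om, 1e-300)
        A = np.ones(d)
        lam = Om_safe.sum(axis=1) / (nk * d)
        for _ in range(inner_max):
            lam_new = (Om_safe / A).sum(axis=1) / (nk * d)
            An = (Om_safe / np.maximum(lam_new, 1e-300)[:, None]).sum(axis=0)
            An = np.maximum(An, 1e-300)
            An = An / np.exp(np.log(An).sum() / d)
            if np.max(np.abs(lam_new - lam)) < inner_tol * max(lam_new.max(), 1e-300) \
               and np.max(np.abs(An - A)) < inner_tol:
                lam, A = lam_new, An
                break
            lam, A = lam_new, An
        return np.stack([Ls[j] @ np.diag(lam[j] * A) @ Ls[j].T for j in range(k)])
    raise ValueError(f"unknown parameterization {code!r}")


def _regularize(cov: np.ndarray, floor: float) -> tuple[np.ndarray, bool]:
    """Lift covariance eigenvalues to at least ``floor``; report if touched."""
    k, d, _ = cov.shape
    touched = False
    out = cov.copy()
    for j in range(k):
        vals, vecs = np.linalg.eigh(out[j])
        if vals.min() < floor:
            touched = True
            vals = np.maximum(vals, floor)
            out[j] = vecs @ np.diag(vals) @ vecs.T
    return out, touched


def _log_gaussian(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = X.shape[1]
    L = np.linalg.cholesky(cov)
    sol = np.linalg.solve(L, (X - mean).T)
    maha = np.sum(sol**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diagonal(L)))
    return -0.5 * (d * _LOG2PI + logdet + maha)


# ---------------------------------------------------------------------------
# initialisation and EM
# ---------------------------------------------------------------------------


def ward_init_labels(X: np.ndarray, k: int, max_rows: int = 2000,
                     seed: int = 0) -> np.ndarray:
    """Hard initial labels from Ward agglomeration of a seeded subsample.

    Rows outside the subsample are attached to the nearest subsample row, so
    the initial partition covers every observation and is reproducible.
    """
    n = X.shape[0]
    if n <= max_rows:
        sub_idx = np.arange(n)
    else:
        rng = np.random.default_rng(seed)
        sub_idx = np.sort(rng.choice(n, size=max_rows, replace=False))
    Z = ward(X[sub_idx])
    sub_labels = fcluster(Z, t=k, criterion="maxclust") - 1
    if n == len(sub_idx):
        return sub_labels
    nearest = np.argmin(cdist(X, X[sub_idx]), axis=1)
    return sub_labels[nearest]


def em_fit(
    X: np.ndarray,
    k: int,
    code: str,
    init_labels: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
    seed: int = 0,
) -> MixtureFit:
    """Fit one (code, k) mixture by EM.

    E-step: responsibilities ``z_ik proportional to pi_k phi(x_i; mu_k,
    Sigma_k)``. M-step: weights, means and the constrained covariance
    update. Stops when the relative log-likelihood change drops below
    ``tol``. Components whose covariance collapses below the eigenvalue
    floor (1e-8 x mean pooled variance) are regularized with a warning.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if code not in CODES:
        raise ValueError(f"unknown parameterization {code!r}")
    if n <= k:
        raise ValueError(f"n={n} must exceed k={k}")
    pooled = np.cov(X.T) if n > 1 else np.atleast_2d(1.0)
    floor = 1e-8 * max(np.atleast_2d(pooled).trace() / d, 1e-300)

    if init_labels is None:
        init_labels = ward_init_labels(X, k, seed=seed)
    resp = np.zeros((n, k))
    resp[np.arange(n), np.asarray(init_labels) % k] = 1.0
    # guard: every component needs mass
    empty = resp.sum(axis=0) == 0
    if empty.any():
        rng = np.random.default_rng(seed)
        for j in np.flatnonzero(empty):
            resp[rng.integers(0, n)] = 0.0
            resp[rng.integers(0, n), j] = 1.0

    loglik = -np.inf
    trace = []
    converged = False
    regularized = False
    it = 0
    for it in range(1, max_iter + 1):
        # M-step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        weights = nk / n
        means = (resp.T @ X) / nk[:, None]
        W = _scatter(X, resp, means)
        cov = _mstep_cov(code, W, nk, n, d)
        cov, touched = _regularize(cov, floor)
        regularized |= touched
        # E-step
        logp = np.empty((n, k))
        for j in range(k):
            logp[:, j] = np.log(max(weights[j], 1e-300)) + _log_gaussian(X, means[j], cov[j])
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        new_loglik = float(lse.sum())
        resp = np.exp(logp - lse[:, None])
        trace.append(new_loglik)
        if np.isfinite(loglik):
            denom = max(abs(new_loglik), 1e-300)
            if (new_loglik - loglik) / denom < tol and new_loglik >= loglik - 1e-9 * denom:
                loglik = new_loglik
                converged = True
                break
        loglik = new_loglik
    if regularized:
        log.warning("em_fit(%s, k=%d): covariance eigenvalue floor applied", code, k)
    return MixtureFit(
        code=code, k=k, weights=weights, means=means, covariances=cov,
        responsibilities=resp, loglik=loglik, n=n, d=d, n_iter=it,
        converged=converged, loglik_trace=np.asarray(trace),
    )


def classify(fit: MixtureFit) -> np.ndarray:
    """MAP component labels (0-based); ties go to the lowest component index."""
    return np.argmax(fit.responsibilities, axis=1)


# ---------------------------------------------------------------------------
# family fitting and plateau selection
# ---------------------------------------------------------------------------


@dataclass
class BICSurface:
    """BIC over the (parameterization, k) family; nan marks failed fits."""

    values: pd.DataFrame           # index k, columns code
    fits: dict[tuple[str, int], MixtureFit]
    n: int
    d: int

    def best(self) -> tuple[str, int]:
        """(code, k) of the global BIC maximum."""
        v = self.values
        if not np.isfinite(v.to_numpy(dtype=float)).any():
            raise ValueError("no finite BIC values")
        stacked = v.stack()
        code_k = stacked.idxmax()
        return str(code_k[1]), int(code_k[0])


def fit_family(
    X: np.ndarray,
    k_range=range(1, 21),
    codes=CODES,
    tol: float = 1e-8,
    max_iter: int = 1000,
    seed: int = 0,
) -> BICSurface:
    """Fit every (code, k) with the deterministic Ward initialisation and
    collect the BIC surface. Failed (non-convergent or degenerate) cells are
    missing; if every cell fails, an error is raised."""
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    ks = [int(k) for k in k_range]
    if not ks:
        raise ValueError("k_range is empty")
    surface = pd.DataFrame(np.nan, index=ks, columns=list(codes))
    fits: dict[tuple[str, int], MixtureFit] = {}
    labels_cache: dict[int, np.ndarray] = {}
    for k in ks:
        if k >= n:
            continue
        if k not in labels_cache:
            labels_cache[k] = ward_init_labels(X, k, seed=seed)
        for code in codes:
            try:
                fit = em_fit(X, k, code, init_labels=labels_cache[k],
                             tol=tol, max_iter=max_iter, seed=seed)
            except (np.linalg.LinAlgError, ValueError) as exc:
                log.warning("fit_family: (%s, k=%d) failed: %s", code, k, exc)
                continue
            fits[(code, k)] = fit
            if fit.converged:
                surface.loc[k, code] = bic(fit)
    if not np.isfinite(surface.to_numpy(dtype=float)).any():
        raise RuntimeError("every (code, k) fit failed")
    return BICSurface(values=surface, fits=fits, n=n, d=d)


def select_model_plateau(surface: BICSurface, tau: float = 0.01) -> tuple[str, int]:
    """Parsimonious model choice: best code by global BIC, then the lowest k
    at the beginning of the BIC plateau along that code's curve.

    Operationally: with gains ``g(k) = BIC(k) - BIC(k-1)``, pick the
    smallest k whose NEXT gain is at most ``tau`` times the total BIC rise
    of the curve. A strictly steeply rising curve falls back to the argmax
    with a warning.
    """
    code, _ = surface.best()
    curve = surface.values[code].dropna()
    if len(curve) < 2:
        raise ValueError("need BIC at >= 2 cluster counts for plateau selection")
    ks = curve.index.to_numpy()
    vals = curve.to_numpy(dtype=float)
    span = vals.max() - vals[0]
    if span <= 0:
        return code, int(ks[np.argmax(vals)])
    thresh = tau * span
    for i in range(len(ks) - 1):
        gain_next = vals[i + 1] - vals[i]
        if gain_next <= thresh:
            return code, int(ks[i])
    log.warning("select_model_plateau: no plateau found; falling back to BIC argmax")
    return code, int(ks[np.argmax(vals)])
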