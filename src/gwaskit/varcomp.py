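"""REML and Haseman-Elston estimation of variance components.

Model: y = X beta + g + e with Var(g) = sigma_g^2 K and Var(e) = sigma_e^2 I.
Writing the total variance sigma^2 = sigma_g^2 + sigma_e^2 and heritability
h^2 = sigma_g^2 / sigma^2 gives V = sigma^2 (h^2 K + (1 - h^2) I); sigma^2
is profiled out of the restricted likelihood analytically, leaving a 1-D
objective in h^2 that all likelihood routes share:

* ``reml_brent`` — bounded Brent search on h^2 directly (the default),
  evaluated in the GRM's eigenbasis so each likelihood evaluation is O(n k).
* ``reml_emmax`` — EMMA-style coarse grid over delta = sigma_e^2/sigma_g^2
  followed by Brent refinement of the best bracket; same objective, so the
  two routes agree to optimizer tolerance.
* ``reml_fastlmm`` — spectrum taken from the genotype matrix itself (thin
  SVD when m < n, eigendecomposition of the marker kinship otherwise) and
  the identical objective evaluated through the nonzero components plus the
  identity complement; efficient when markers are scarce.
* ``he_regression`` — moment estimator regressing pairwise phenotype
  products on GRM entries; cheap, no likelihood, wider error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.linalg
from scipy.optimize import minimize_scalar

from .genotype_io import GenotypeStore
from .popstruct import GRM, EigenDecomposition

__all__ = [
    "VarianceComponents",
    "reml_brent",
    "reml_emmax",
    "reml_fastlmm",
    "he_regression",
]

H2_BOUNDS = (1e-6, 1.0 - 1e-6)
H2_TOL = 1e-6  # absolute tolerance on heritability (the 1-D parameter)
_FLAT_TOL = 1e-8


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    h2: float
    method: str
    loglik: Optional[float] = None
    flat_likelihood: bool = False

    def __post_init__(self):
        tot = self.sigma_g2 + self.sigma_e2
        if tot > 0:
            assert abs(self.h2 - self.sigma_g2 / tot) < 1e-10


def _check_design(y: np.ndarray, X: np.ndarray):
    y = np.asarray(y, dtype=np.float64).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[0] != y.shape[0]:
        raise ValueError("covariate rows do not match phenotype length")
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in phenotype or covariates")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    return y, X


def _reml_rotated(h2: float, yr: np.ndarray, Xr: np.ndarray, lam: np.ndarray,
                  logdet_xtx: float):
    """Profiled REML log-likelihood in the eigenbasis; returns (ll, sigma2)."""
    n, q = Xr.shape
    D = h2 * lam + (1.0 - h2)
    Dinv = 1.0 / D
    XtDX = Xr.T @ (Xr * Dinv[:, None])
    XtDy = Xr.T @ (yr * Dinv)
    beta = scipy.linalg.solve(XtDX, XtDy, assume_a="pos")
    R = float(yr @ (yr * Dinv) - XtDy @ beta)
    R = max(R, np.finfo(float).tiny)
    sigma2 = R / (n - q)
    ll = -0.5 * (
        (n - q) * (np.log(2 * np.pi * sigma2) + 1.0)
        + float(np.sum(np.log(D)))
        + float(np.linalg.slogdet(XtDX)[1])
        - logdet_xtx
    )
    return ll, sigma2


def _finish(h2: float, sigma2: float, ll: float, method: str,
            flat: bool = False) -> VarianceComponents:
    return VarianceComponents(
        sigma_g2=h2 * sigma2, sigma_e2=(1.0 - h2) * sigma2, h2=h2,
        method=method, loglik=ll, flat_likelihood=flat,
    )


def _is_flat(ll_fun) -> bool:
    probes = [ll_fun(h)[0] for h in (0.01, 0.25, 0.5, 0.75, 0.99)]
    return max(probes) - min(probes) < _FLAT_TOL


def reml_brent(y, X_cov, eig: EigenDecomposition, tol: float = H2_TOL,
               bounds=H2_BOUNDS) -> VarianceComponents:
    """REML via bounded Brent search on h^2 in the GRM eigenbasis.

    Convergence is judged on the absolute tolerance of heritability (the
    single free parameter) rather than on the individual variance
    components. A flat likelihood (e.g. K proportional to I) returns h^2=0
    with ``flat_likelihood=True`` instead of an arbitrary interior point.
    """
    y, X = _check_design(y, X_cov)
    if eig.n != len(y):
        raise ValueError("eigendecomposition size does not match phenotype length")
    U, lam = eig.vectors, eig.values
    yr, Xr = U.T @ y, U.T @ X
    logdet_xtx = float(np.linalg.slogdet(X.T @ X)[1])

    def f(h2):
        return _reml_rotated(h2, yr, Xr, lam, logdet_xtx)

    if _is_flat(f):
        ll, sigma2 = f(1e-12)
        return _finish(0.0, sigma2, ll, "brent", flat=True)
    res = minimize_scalar(lambda h: -f(h)[0], bounds=bounds, method="bounded",
                          options={"xatol": tol})
    h2 = float(res.x)
    ll, sigma2 = f(h2)
    return _finish(h2, sigma2, ll, "brent")


def reml_emmax(y, X_cov, eig: EigenDecomposition,
               grid_size: int = 100, delta_range=(1e-5, 1e5),
               tol: float = H2_TOL) -> VarianceComponents:
    """REML via EMMA-style grid on delta = sigma_e^2/sigma_g^2 + refinement.

    Evaluates the shared profiled objective on ``grid_size`` log-spaced
    delta values, then runs bounded Brent inside the bracket around the
    best grid point. Agrees with :func:`reml_brent` to optimizer tolerance.
    """
    y, X = _check_design(y, X_cov)
    if eig.n != len(y):
        raise ValueError("eigendecomposition size does not match phenotype length")
    U, lam = eig.vectors, eig.values
    yr, Xr = U.T @ y, U.T @ X
    logdet_xtx = float(np.linalg.slogdet(X.T @ X)[1])

    def f(h2):
        return _reml_rotated(h2, yr, Xr, lam, logdet_xtx)

    if _is_flat(f):
        ll, sigma2 = f(1e-12)
        return _finish(0.0, sigma2, ll, "emmax", flat=True)
    deltas = np.geomspace(delta_range[0], delta_range[1], grid_size)
    h2_grid = np.sort(1.0 / (1.0 + deltas))
    h2_grid = np.clip(h2_grid, H2_BOUNDS[0], H2_BOUNDS[1])
    lls = np.array([f(h)[0] for h in h2_grid])
    best = int(np.argmax(lls))
    lo = h2_grid[max(best - 1, 0)]
    hi = h2_grid[min(best + 1, len(h2_grid) - 1)]
    if hi - lo < tol:
        h2 = float(h2_grid[best])
    else:
        res = minimize_scalar(lambda h: -f(h)[0], bounds=(lo, hi),
                              method="bounded", options={"xatol": tol})
        h2 = float(res.x)
    ll, sigma2 = f(h2)
    return _finish(h2, sigma2, ll, "emmax")


def _scaled_markers(store, sample_index=None):
    """Centered (by 2p) marker matrix scaled so K = Zs' Zs is the VanRaden GRM."""
    if isinstance(store, GenotypeStore):
        X = store.dosage_block(0, store.n_markers, sample_index)
    else:
        X = np.atleast_2d(np.asarray(store, dtype=np.float64))
        if sample_index is not None:
            X = X[:, sample_index]
    from .genotype_io import _impute_block
    X, p = _impute_block(X.copy())
    poly = np.isfinite(p) & (X.var(axis=1) > 0)
    if not poly.any():
        raise ValueError("all markers are monomorphic; no genetic spectrum")
    Z = X[poly] - 2.0 * p[poly, None]
    denom = 2.0 * float(np.sum(p[poly] * (1 - p[poly])))
    return Z / np.sqrt(denom)


def reml_fastlmm(y, X_cov, store=None, sample_index=None, Z=None,
                 tol: float = H2_TOL) -> VarianceComponents:
    """REML through the genotype matrix's own spectrum (FaST-LMM style).

    ``store`` (or a raw m x n dosage matrix ``Z``) provides the markers; the
    kinship is the VanRaden normalization of these markers, so the estimate
    matches :func:`reml_brent` on the corresponding GRM. For m < n the
    nonzero spectrum comes from a thin SVD of the scaled marker matrix and
    the likelihood is evaluated through those components plus the identity
    complement, without ever forming the n x n kinship.
    """
    y, X = _check_design(y, X_cov)
    src = Z if Z is not None else store
    if src is None:
        raise ValueError("reml_fastlmm needs a store or marker matrix")
    Zs = _scaled_markers(src, sample_index)
    m_eff, n = Zs.shape
    if n != len(y):
        raise ValueError("marker matrix sample count does not match phenotype")
    if m_eff >= n:
        K = Zs.T @ Zs
        vals, vecs = scipy.linalg.eigh(K)
        vals = np.clip(vals, 0.0, None)[::-1]
        vecs = vecs[:, ::-1]
        eig = EigenDecomposition(vals, vecs)
        vc = reml_brent(y, X, eig, tol=tol)
        return _finish(vc.h2, vc.sigma_g2 + vc.sigma_e2, vc.loglik, "fastlmm",
                       vc.flat_likelihood)
    # thin SVD: K = V diag(s^2) V' with rank r = m_eff
    _, s, Vt = scipy.linalg.svd(Zs, full_matrices=False)
    Ur = Vt.T                      # n x r
    lam_r = s ** 2
    r = len(lam_r)
    q = X.shape[1]
    Ay, AX = Ur.T @ y, Ur.T @ X
    yty, XtX, Xty = float(y @ y), X.T @ X, X.T @ y
    logdet_xtx = float(np.linalg.slogdet(XtX)[1])

    def f(h2):
        Dr = h2 * lam_r + (1.0 - h2)
        d0 = 1.0 - h2
        w = 1.0 / Dr - 1.0 / d0
        XtDX = XtX / d0 + AX.T @ (AX * w[:, None])
        XtDy = Xty / d0 + AX.T @ (Ay * w)
        ytDy = yty / d0 + float(Ay @ (Ay * w))
        beta = scipy.linalg.solve(XtDX, XtDy, assume_a="pos")
        R = max(float(ytDy - XtDy @ beta), np.finfo(float).tiny)
        sigma2 = R / (n - q)
        ll = -0.5 * (
            (n - q) * (np.log(2 * np.pi * sigma2) + 1.0)
            + float(np.sum(np.log(Dr))) + (n - r) * np.log(d0)
            + float(np.linalg.slogdet(XtDX)[1])
            - logdet_xtx
        )
        return ll, sigma2

    if _is_flat(f):
        ll, sigma2 = f(1e-12)
        return _finish(0.0, sigma2, ll, "fastlmm", flat=True)
    res = minimize_scalar(lambda h: -f(h)[0], bounds=H2_BOUNDS, method="bounded",
                          options={"xatol": tol})
    h2 = float(res.x)
    ll, sigma2 = f(h2)
    return _finish(h2, sigma2, ll, "fastlmm")


def he_regression(y, grm: GRM, X_cov=None) -> VarianceComponents:
    """Haseman-Elston regression of pairwise phenotype products on kinship.

    The phenotype is residualized on the covariates and standardized; the
    products y_i y_j over sample pairs i < j are regressed (with intercept)
    on G_ij, and the slope estimates h^2 (clipped to [0, 1]). Diagonal pairs
    are excluded. No likelihood is reported.
    """
    G = grm.matrix if isinstance(grm, GRM) else np.asarray(grm)
    n = G.shape[0]
    if n < 3:
        raise ValueError("HE regression needs at least 3 samples")
    y = np.asarray(y, dtype=np.float64).ravel()
    if len(y) != n:
        raise ValueError("phenotype length does not match GRM")
    if X_cov is None:
        X = np.ones((n, 1))
    else:
        _, X = _check_design(y, X_cov)
    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    var_y = float(resid.var())
    sd = np.sqrt(var_y)
    if sd == 0:
        raise ValueError("phenotype has zero residual variance")
    yt = resid / sd
    iu = np.triu_indices(n, 1)
    g = G[iu]
    if np.ptp(g) == 0:
        raise ValueError("GRM off-diagonals are constant; HE regressor degenerate")
    prod = yt[iu[0]] * yt[iu[1]]
    slope = float(np.cov(g, prod, bias=True)[0, 1] / g.var())
    h2 = float(np.clip(slope, 0.0, 1.0))
    return VarianceComponents(
        sigma_g2=h2 * var_y, sigma_e2=(1 - h2) * var_y, h2=h2,
        method="he", loglik=None,
    )
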