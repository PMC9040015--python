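"""Shared fixtures and independent oracles for the test suite.

The oracles deliberately take the naive route (full per-marker design
rebuilds, explicit dense covariance inverses) so they stay independent of
the blockwise/eigen code paths they are used to check.
"""

import numpy as np
import pandas as pd
import pytest
import scipy.linalg
from scipy import stats

from gwaskit.simulate import SimConfig, simulate_genotypes, simulate_phenotype


# ---------------------------------------------------------------------------
# oracles


def naive_ols(y, W, x):
    """Per-marker OLS refit: rebuild the full design and invert X'X directly."""
    X = np.column_stack([W, x])
    n, k1 = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    df = n - k1
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(XtX_inv[-1, -1] * sigma2)
    t = beta[-1] / se
    p = 2 * stats.t.sf(abs(t), df)
    return float(beta[-1]), float(se), float(p)


def dense_gls(y, W, x, V):
    """Dense GLS oracle: whiten with an explicit Cholesky of V per marker."""
    L = np.linalg.cholesky(V)
    yw = scipy.linalg.solve_triangular(L, y, lower=True)
    Xw = scipy.linalg.solve_triangular(L, np.column_stack([W, x]), lower=True)
    n, k1 = Xw.shape
    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    beta = XtX_inv @ Xw.T @ yw
    resid = yw - Xw @ beta
    df = n - k1
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(XtX_inv[-1, -1] * sigma2)
    t = beta[-1] / se
    p = 2 * stats.t.sf(abs(t), df)
    return float(beta[-1]), float(se), float(p)


def dense_reml(y, X, K, h2):
    """Profiled REML log-likelihood with an explicit dense V inverse."""
    n, q = X.shape
    V = h2 * K + (1 - h2) * np.eye(n)
    Vinv = np.linalg.inv(V)
    XtVX = X.T @ Vinv @ X
    beta = np.linalg.solve(XtVX, X.T @ Vinv @ y)
    r = y - X @ beta
    R = float(r @ Vinv @ r)
    sigma2 = R / (n - q)
    return -0.5 * (
        (n - q) * (np.log(2 * np.pi * sigma2) + 1)
        + np.linalg.slogdet(V)[1]
        + np.linalg.slogdet(XtVX)[1]
        - np.linalg.slogdet(X.T @ X)[1]
    )


def dense_vanraden(dosages):
    """Single-shot VanRaden GRM on an in-memory matrix (m x n)."""
    X = np.asarray(dosages, dtype=float)
    p = X.mean(axis=1) / 2
    poly = X.var(axis=1) > 0
    Z = X[poly] - 2 * p[poly, None]
    den = 2 * np.sum(p[poly] * (1 - p[poly]))
    return Z.T @ Z / den


@pytest.fixture(scope="session")
def oracles():
    return {
        "ols": naive_ols,
        "gls": dense_gls,
        "reml": dense_reml,
        "vanraden": dense_vanraden,
    }


# ---------------------------------------------------------------------------
# simulated stores (session-scoped: read-only, shared across tests)


@pytest.fixture(scope="session")
def small_store(tmp_path_factory):
    """Unstructured cohort: 120 samples x 600 markers, 5 QTNs at h2=0.5."""
    cfg = SimConfig(n_samples=120, n_markers=600, seed=11, n_qtn=5, h2=0.5)
    store = simulate_genotypes(cfg, tmp_path_factory.mktemp("small") / "store")
    pheno, truth = simulate_phenotype(store, cfg)
    return store, pheno, truth, cfg


@pytest.fixture(scope="session")
def structured_store(tmp_path_factory):
    """Two diverged subpopulations: 200 samples x 1000 markers, Fst 0.1."""
    cfg = SimConfig(n_samples=200, n_markers=1000, seed=7, n_subpop=2, fst=0.1)
    store = simulate_genotypes(cfg, tmp_path_factory.mktemp("struct") / "store")
    return store, cfg
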