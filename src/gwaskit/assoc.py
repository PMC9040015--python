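"""Per-marker association scans: GLM, MLM (P3D), and FarmCPU.

All three scans share one kernel: for the model y = w a + x c + e with a
fixed covariate block w (intercept + covariates) and a per-marker column x,
the inverse of the full cross-product

    M = [[w'w, w'x],
         [x'w, x'x]]

is assembled blockwise from the once-computed (w'w)^-1 via the Schur
complement s = x'x - x'w (w'w)^-1 w'x:

    M22 = 1/s
    M12 = -(w'w)^-1 w'x / s        (M21 = M12')
    M11 = (w'w)^-1 + (w'w)^-1 w'x x'w (w'w)^-1 / s

so the per-marker cost is a handful of length-n dot products instead of a
(k+1)x(k+1) inversion. The MLM scan rotates the system into the GRM
eigenbasis, rescales rows by 1/sqrt(h^2 lambda_i + 1 - h^2) using variance
components estimated once under the null (P3D), and then runs the identical
machinery — generalized least squares as a weighted ordinary regression.

Markers are partitioned into contiguous, block-aligned chunks for parallel
workers that read the shared memory-mapped store without copying it;
results land in preallocated arrays indexed by marker, so output is
independent of worker count.
"""

from __future__ import annotations

import warnings
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats

from .genotype_io import GenotypeStore, _impute_block
from .popstruct import EigenDecomposition
from .varcomp import VarianceComponents, reml_brent

__all__ = [
    "BlockInverse",
    "block_inverse",
    "glm_scan",
    "mlm_scan",
    "farmcpu_scan",
    "genomic_inflation",
    "write_results",
]

RESULT_COLUMNS = ["SNP", "CHROM", "POS", "EFFECT", "SE", "PVALUE", "N"]

_SCHUR_TOL = 1e-12
_TINY = np.finfo(np.float64).tiny


@dataclass
class BlockInverse:
    """The four blocks of M^-1 for one marker, or a degeneracy flag."""

    M11: np.ndarray
    M12: np.ndarray
    M21: np.ndarray
    M22: float
    degenerate: bool = False


def block_inverse(wtw_inv: np.ndarray, wtx: np.ndarray, xtx: float,
                  tol: float = _SCHUR_TOL) -> BlockInverse:
    """Assemble M^-1 from the cached covariate-block inverse.

    A Schur complement at or below ``tol`` means the marker is (numerically)
    collinear with the covariates; the result is flagged degenerate.
    """
    wtw_inv = np.asarray(wtw_inv, dtype=np.float64)
    wtx = np.asarray(wtx, dtype=np.float64).reshape(-1)
    t = wtw_inv @ wtx
    schur = float(xtx - wtx @ t)
    if schur <= tol:
        k = wtw_inv.shape[0]
        return BlockInverse(np.full((k, k), np.nan), np.full(k, np.nan),
                            np.full(k, np.nan), np.nan, degenerate=True)
    m22 = 1.0 / schur
    m12 = -t * m22
    m11 = wtw_inv + np.outer(t, t) * m22
    return BlockInverse(m11, m12, m12.copy(), m22)


# ---------------------------------------------------------------------------
# scan core


def _prepare_covariates(n: int, covariates) -> np.ndarray:
    """Intercept-first covariate block; prepends 1s if no constant column."""
    if covariates is None:
        return np.ones((n, 1))
    C = np.atleast_2d(np.asarray(covariates, dtype=np.float64))
    if C.shape[0] != n:
        C = C.T
    if C.shape[0] != n:
        raise ValueError("covariate rows do not match phenotype length")
    has_const = np.any(np.ptp(C, axis=0) == 0)
    W = C if has_const else np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(W) < W.shape[1]:
        raise ValueError("covariate matrix (with intercept) is rank deficient")
    return W


def _scan_block(X: np.ndarray, y: np.ndarray, W: np.ndarray,
                wtw_inv: np.ndarray, a: np.ndarray, yty: float, df: int):
    """Blockwise-inverse regression statistics for a block of marker columns.

    ``X`` is (b, n) with rows already transformed/imputed; ``a`` is the
    cached (w'w)^-1 w'y. Returns (effect, se, pvalue) with NaN for
    degenerate (monomorphic or covariate-collinear) markers.
    """
    wtx = W.T @ X.T                      # k x b
    xtx = np.einsum("ij,ij->i", X, X)    # b
    xty = X @ y
    t1 = wtw_inv @ wtx                   # k x b
    schur = xtx - np.einsum("ij,ij->j", wtx, t1)
    scale = np.maximum(xtx, 1.0)
    ok = schur > _SCHUR_TOL * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        m22 = np.where(ok, 1.0 / schur, np.nan)
        c = m22 * (xty - wtx.T @ a)          # marker effect
        bw = a[:, None] + t1 * (m22 * (wtx.T @ a - xty))[None, :]
        fitted = np.einsum("kj,k->j", bw, W.T @ y) + c * xty
        rss = np.maximum(yty - fitted, 0.0)
        sigma2 = rss / df
        se = np.sqrt(m22 * np.maximum(sigma2, _TINY))
        tstat = c / se
        p = 2.0 * stats.t.sf(np.abs(tstat), df)
    perfect = ok & (rss <= 1e-12 * max(yty, _TINY))
    p = np.maximum(p, _TINY)             # p in (0, 1], never exactly 0
    p[perfect] = _TINY
    bad = ~ok
    c[bad] = np.nan
    se[bad] = np.nan
    p[bad] = np.nan
    return c, se, p


def _chunk_ranges(m: int, block_size: int, n_workers: int):
    """Contiguous chunks aligned to absolute block boundaries.

    Alignment guarantees each marker is processed in a block of identical
    shape regardless of worker count, making results bitwise reproducible.
    """
    n_blocks = -(-m // block_size)
    per = -(-n_blocks // max(n_workers, 1))
    out = []
    for w in range(n_workers):
        lo = w * per * block_size
        hi = min((w + 1) * per * block_size, m)
        if lo < hi:
            out.append((lo, hi))
    return out


def _glm_chunk(source, rng: tuple, y, W, wtw_inv, a, yty, df,
               sample_index, block_size, transform=None):
    lo, hi = rng
    eff = np.empty(hi - lo)
    se = np.empty(hi - lo)
    p = np.empty(hi - lo)
    if isinstance(source, str):
        source = GenotypeStore(source)
    for start in range(lo, hi, block_size):
        stop = min(start + block_size, hi)
        if isinstance(source, GenotypeStore):
            X, _ = source.imputed_block(start, stop, sample_index)
        else:
            Xb = source[start:stop]
            if sample_index is not None:
                Xb = Xb[:, sample_index]
            X, _ = _impute_block(np.asarray(Xb, dtype=np.float64).copy())
        if transform is not None:
            U, wgt = transform
            X = (X @ U) * wgt[None, :]
        e, s, pv = _scan_block(X, y, W, wtw_inv, a, yty, df)
        eff[start - lo:stop - lo] = e
        se[start - lo:stop - lo] = s
        p[start - lo:stop - lo] = pv
    return eff, se, p


def _run_scan(source, markers: Optional[pd.DataFrame], y, W,
              sample_index, block_size, n_workers, transform=None,
              model: str = "glm") -> pd.DataFrame:
    y = np.asarray(y, dtype=np.float64).ravel()
    n = len(y)
    k = W.shape[1]
    df = n - k - 1
    if df <= 0:
        raise ValueError("not enough samples for the requested design")
    if transform is not None:
        U, wgt = transform
        ys = (U.T @ y) * wgt
        Ws = (U.T @ W) * wgt[:, None]
        trans = (U, wgt)
    else:
        ys, Ws, trans = y, W, None
    wtw = Ws.T @ Ws
    wtw_inv = scipy.linalg.inv(wtw)
    a = wtw_inv @ (Ws.T @ ys)
    yty = float(ys @ ys)

    if isinstance(source, GenotypeStore):
        m = source.n_markers
        src_for_worker = str(source.path)
        src_local = source
    else:
        src_local = np.atleast_2d(np.asarray(source, dtype=np.float64))
        m = src_local.shape[0]
        src_for_worker = src_local

    ranges = _chunk_ranges(m, block_size, n_workers)
    eff = np.empty(m)
    se = np.empty(m)
    p = np.empty(m)
    if n_workers > 1 and len(ranges) > 1:
        with ProcessPoolExecutor(max_workers=n_workers) as ex:
            futs = [
                ex.submit(_glm_chunk, src_for_worker, r, ys, Ws, wtw_inv, a,
                          yty, df, sample_index, block_size, trans)
                for r in ranges
            ]
            for r, fut in zip(ranges, futs):
                e, s, pv = fut.result()
                eff[r[0]:r[1]], se[r[0]:r[1]], p[r[0]:r[1]] = e, s, pv
    else:
        for r in ranges:
            e, s, pv = _glm_chunk(src_local, r, ys, Ws, wtw_inv, a, yty, df,
                                  sample_index, block_size, trans)
            eff[r[0]:r[1]], se[r[0]:r[1]], p[r[0]:r[1]] = e, s, pv

    if np.all(np.isnan(p)):
        raise ValueError("no polymorphic markers to test")
    if markers is None:
        markers = pd.DataFrame({
            "snp_id": [f"m{i}" for i in range(m)],
            "chrom": "1", "pos": np.arange(1, m + 1),
        })
    out = pd.DataFrame({
        "SNP": markers["snp_id"].to_numpy(),
        "CHROM": markers["chrom"].astype(str).to_numpy(),
        "POS": markers["pos"].to_numpy(),
        "EFFECT": eff, "SE": se, "PVALUE": p, "N": n,
    })
    out.attrs["model"] = model
    return out


def glm_scan(y, store, covariates=None, sample_index=None,
             block_size: int = 1024, n_workers: int = 1,
             markers: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Fixed-effects scan: y ~ intercept + covariates + marker, per marker.

    Missing dosages are mean-imputed per marker. Effects come from the
    blockwise inverse with the covariate-block inverse computed once;
    SE(c) = sqrt(M22 * RSS/(n-k-1)) and a two-sided t test with n-k-1
    degrees of freedom gives the p-value. Monomorphic or covariate-collinear
    markers yield missing effect/SE/p; exact fits report the smallest
    positive p rather than 0.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    W = _prepare_covariates(len(y), covariates)
    if markers is None and isinstance(store, GenotypeStore):
        markers = store.markers
    return _run_scan(store, markers, y, W, sample_index, block_size,
                     n_workers, model="glm")


def mlm_scan(y, store, covariates, eig: EigenDecomposition,
             vc: VarianceComponents, sample_index=None,
             block_size: int = 1024, n_workers: int = 1,
             markers: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Mixed-model scan under P3D: variance components fixed from the null.

    Rotating by U' and rescaling row i by 1/sqrt(h^2 lambda_i + 1 - h^2)
    whitens V, after which the blockwise GLM machinery applies unchanged.
    With h^2 = 0 the transform is orthonormal and p-values reduce to GLM's.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    if eig.n != len(y):
        raise ValueError("eigendecomposition size does not match phenotype length")
    W = _prepare_covariates(len(y), covariates)
    wgt = 1.0 / np.sqrt(vc.h2 * eig.values + (1.0 - vc.h2))
    if markers is None and isinstance(store, GenotypeStore):
        markers = store.markers
    return _run_scan(store, markers, y, W, sample_index, block_size,
                     n_workers, transform=(eig.vectors, wgt), model="mlm")


def genomic_inflation(pvalues) -> float:
    """Genomic inflation factor: median observed chi^2(1) over its null median."""
    p = np.asarray(pd.Series(pvalues).dropna(), dtype=np.float64)
    if len(p) < 100:
        raise ValueError("genomic inflation needs >= 100 non-missing p-values")
    chi = stats.chi2.isf(np.median(p), df=1)
    return float(chi / stats.chi2.ppf(0.5, df=1))


def write_results(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# FarmCPU


def _get_rows(source, idx, sample_index):
    if isinstance(source, GenotypeStore):
        rows = [source.dosage_row(int(i), sample_index) for i in idx]
        X = np.array(rows)
    else:
        X = np.asarray(source, dtype=np.float64)[np.asarray(idx, dtype=int)]
        if sample_index is not None:
            X = X[:, sample_index]
    X, _ = _impute_block(X.copy())
    return X


def _dedupe_columns(X: np.ndarray, r_max: float = 0.99) -> np.ndarray:
    """Indices of columns to keep, dropping later near-duplicates (|r|>r_max)."""
    keep = []
    for j in range(X.shape[1]):
        xj = X[:, j]
        if xj.std() == 0:
            continue
        dup = False
        for i in keep:
            xi = X[:, i]
            r = np.corrcoef(xi, xj)[0, 1]
            if abs(r) > r_max:
                dup = True
                break
        if not dup:
            keep.append(j)
    return np.array(keep, dtype=int)


def _rem_loglik(y, W, qtn_dosages: np.ndarray) -> float:
    """Restricted likelihood of the random-effect model with a pseudo-QTN kinship.

    The kinship is the VanRaden normalization of the pseudo-QTN dosages
    alone; with q << n markers the spectrum is low-rank, so the REML
    optimum is found through the FaST-LMM-style route.
    """
    from .varcomp import reml_fastlmm
    vc = reml_fastlmm(y, W, Z=qtn_dosages)
    return float(vc.loglik)


def _select_pseudo_qtns(res: pd.DataFrame, y, W, source, sample_index,
                        bin_sizes, qtn_counts, p_threshold) -> list[int]:
    """Bin-and-count model selection for the pseudo-QTN set.

    For every bin size, markers are ranked by p and thinned to the best
    marker per (chrom, pos // bin) bin (ties: smaller p, then lower
    position); for every candidate count t the first t survivors below the
    entry threshold form a candidate set, scored by the REM restricted
    likelihood. The best-scoring set wins.
    """
    p = res["PVALUE"].to_numpy()
    valid = np.isfinite(p) & (p < p_threshold)
    if not valid.any():
        return []
    idx_all = np.flatnonzero(valid)
    order = idx_all[np.lexsort((res["POS"].to_numpy()[idx_all], p[idx_all]))]
    chroms = res["CHROM"].to_numpy()
    poss = res["POS"].to_numpy()
    best_ll, best_set = -np.inf, []
    scored: dict[frozenset, float] = {}
    for bin_size in bin_sizes:
        seen_bins = set()
        survivors = []
        for i in order:
            b = (chroms[i], int(poss[i]) // int(bin_size))
            if b in seen_bins:
                continue
            seen_bins.add(b)
            survivors.append(int(i))
        for t in qtn_counts:
            cand = survivors[:t]
            if not cand:
                continue
            key = frozenset(cand)
            if key in scored:
                ll = scored[key]
            else:
                X = _get_rows(source, cand, sample_index)
                try:
                    ll = _rem_loglik(y, W, X)
                except ValueError:
                    continue
                scored[key] = ll
            if ll > best_ll:
                best_ll, best_set = ll, cand
    return best_set


def farmcpu_scan(y, store, covariates=None, sample_index=None,
                 markers: Optional[pd.DataFrame] = None,
                 max_loop: int = 10,
                 bin_sizes: Sequence[float] = (5e5, 5e6, 5e7),
                 qtn_counts: Optional[Sequence[int]] = None,
                 p_threshold: Optional[float] = None,
                 block_size: int = 1024, n_workers: int = 1):
    """Iterative fixed/random-model scan (FarmCPU).

    Alternates (i) a fixed-effect scan with the current pseudo-QTN dosages
    appended as covariates — a pseudo-QTN is dropped from the covariate
    block when it is itself the tested marker — and (ii) pseudo-QTN
    reselection by binning the genome at several bin sizes and choosing the
    (bin size, count) combination maximizing the restricted likelihood of a
    random-effect model whose kinship is built from the candidate dosages
    alone. Stops when the set repeats or ``max_loop`` is reached; reports
    the final fixed-effect scan.

    Returns ``(results, info)`` where ``info`` carries the final pseudo-QTN
    row indices, their SNP IDs and the iteration count.
    """
    if max_loop < 1:
        raise ValueError("max_loop must be >= 1")
    y = np.asarray(y, dtype=np.float64).ravel()
    n = len(y)
    if markers is None and isinstance(store, GenotypeStore):
        markers = store.markers
    if markers is None:
        raise ValueError("FarmCPU needs a marker map with genomic positions")
    if markers["pos"].isna().any():
        raise ValueError("marker map has missing positions")
    W0 = _prepare_covariates(n, covariates)
    m = len(markers)
    if p_threshold is None:
        p_threshold = 0.05 / m  # Bonferroni-informed entry threshold
    if qtn_counts is None:
        qtn_counts = [t for t in range(10, 101, 10) if t <= max(n // 10, 10)]

    qtns: list[int] = []
    res = None
    loops = 0
    for loop in range(1, max_loop + 1):
        loops = loop
        res = _fem_scan(y, store, W0, qtns, sample_index, markers,
                        block_size, n_workers)
        new = _select_pseudo_qtns(res, y, W0, store, sample_index,
                                  bin_sizes, qtn_counts, p_threshold)
        if set(new) == set(qtns):
            break
        qtns = new
    info = {
        "pseudo_qtns": list(qtns),
        "pseudo_qtn_snps": markers["snp_id"].to_numpy()[qtns].tolist() if qtns else [],
        "n_iterations": loops,
    }
    res.attrs["model"] = "farmcpu"
    return res, info


def _fem_scan(y, store, W0, qtns, sample_index, markers, block_size,
              n_workers) -> pd.DataFrame:
    """One fixed-effect pass: GLM with pseudo-QTN dosages as extra covariates."""
    if not qtns:
        return _run_scan(store, markers, y, W0, sample_index, block_size,
                         n_workers, model="farmcpu")
    Q = _get_rows(store, qtns, sample_index).T       # n x q
    keep = _dedupe_columns(Q)
    used = [qtns[i] for i in keep]
    W = np.column_stack([W0, Q[:, keep]]) if len(keep) else W0
    if np.linalg.matrix_rank(W) < W.shape[1]:
        # drop QTN columns until full rank (rare: exact collinearity)
        cols = list(range(W0.shape[1]))
        used2 = []
        for j, qi in enumerate(used):
            trial = W[:, cols + [W0.shape[1] + j]]
            if np.linalg.matrix_rank(trial) == trial.shape[1]:
                cols.append(W0.shape[1] + j)
                used2.append(qi)
        W = W[:, cols]
        used = used2
    res = _run_scan(store, markers, y, W, sample_index, block_size,
                    n_workers, model="farmcpu")
    # re-test each pseudo-QTN with itself removed from the covariate block
    k0 = W0.shape[1]
    for j, qi in enumerate(used):
        Wm = np.delete(W, k0 + j, axis=1)
        x = _get_rows(store, [qi], sample_index)[0]
        e, s, pv = _single_marker(y, Wm, x)
        res.loc[qi, ["EFFECT", "SE", "PVALUE"]] = e, s, pv
    return res


def _single_marker(y, W, x):
    n = len(y)
    df = n - W.shape[1] - 1
    wtw_inv = scipy.linalg.inv(W.T @ W)
    a = wtw_inv @ (W.T @ y)
    e, s, p = _scan_block(x[None, :], y, W, wtw_inv, a, float(y @ y), df)
    return float(e[0]), float(s[0]), float(p[0])
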