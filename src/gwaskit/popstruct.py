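"""VanRaden genomic relationship matrix and principal components.

The GRM is G = Z'Z / (2 Σ_j p_j(1-p_j)), where Z is the marker-by-sample
dosage matrix centered per marker by twice the counted-allele frequency and
the sum runs over polymorphic markers (VanRaden 2008). A single symmetric
eigendecomposition of G supplies the PCs and is reused downstream for REML
variance-component estimation and the mixed-model scan, so the whole
pipeline pays for exactly one decomposition.

Construction streams marker blocks off the file-backed store: peak memory
is O(n^2) for the accumulator plus one block of rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy.linalg

from .genotype_io import GenotypeStore, _impute_block

__all__ = [
    "GRM",
    "EigenDecomposition",
    "compute_grm",
    "eigen_grm",
    "compute_pcs",
    "write_grm",
    "read_grm",
    "eigen_decomposition_count",
    "reset_eigen_count",
]

# instrumented counter: the pipeline asserts the decomposition happens once
_EIGEN_CALLS = 0


def eigen_decomposition_count() -> int:
    return _EIGEN_CALLS


def reset_eigen_count() -> None:
    global _EIGEN_CALLS
    _EIGEN_CALLS = 0


@dataclass
class GRM:
    """n x n genomic relationship matrix with its scaling denominator."""

    matrix: np.ndarray
    sample_ids: Optional[list] = None
    denominator: float = 0.0
    n_markers_used: int = 0
    max_block_rows: int = 0  # instrumented row-buffer accounting

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class EigenDecomposition:
    """Eigenvalues (descending) and orthonormal eigenvectors of a GRM."""

    values: np.ndarray
    vectors: np.ndarray

    @property
    def n(self) -> int:
        return len(self.values)


def _block_source(store_or_array, sample_index):
    """Uniform block iterator over a GenotypeStore or an in-memory matrix."""
    if isinstance(store_or_array, GenotypeStore):
        def blocks(block_size):
            yield from (
                (X, p) for _, X, p in
                store_or_array.iter_blocks(block_size, sample_index, imputed=True)
            )
        n = store_or_array.n_samples if sample_index is None else len(np.asarray(sample_index))
        return store_or_array.n_markers, n, blocks
    arr = np.asarray(store_or_array, dtype=np.float64)
    if sample_index is not None:
        arr = arr[:, sample_index]

    def blocks(block_size):
        for start in range(0, arr.shape[0], block_size):
            yield _impute_block(arr[start:start + block_size].copy())

    return arr.shape[0], arr.shape[1], blocks


def compute_grm(store, sample_index=None, block_size: int = 2048,
                denominator: str = "vanraden2") -> GRM:
    """Streamed VanRaden GRM over the analyzed sample subset.

    Missing dosages are mean-imputed per marker; monomorphic markers
    contribute to neither numerator nor denominator. ``denominator``
    selects the standard VanRaden scaling ``2*sum(p(1-p))`` ("vanraden2")
    or the unscaled ``sum(p(1-p))`` variant ("paper").
    """
    if denominator not in ("vanraden2", "paper"):
        raise ValueError(f"unknown GRM denominator {denominator!r}")
    m, n, blocks = _block_source(store, sample_index)
    if n < 2:
        raise ValueError("GRM needs at least 2 samples")
    G = np.zeros((n, n))
    denom_sum = 0.0
    used = 0
    max_rows = 0
    for X, p in blocks(block_size):
        max_rows = max(max_rows, X.shape[0])
        poly = np.isfinite(p) & (X.var(axis=1) > 0)
        if not poly.any():
            continue
        Z = X[poly] - 2.0 * p[poly, None]
        G += Z.T @ Z
        denom_sum += float(np.sum(p[poly] * (1 - p[poly])))
        used += int(poly.sum())
    if used == 0 or denom_sum <= 0:
        raise ValueError("all markers are monomorphic; GRM denominator is zero")
    den = 2.0 * denom_sum if denominator == "vanraden2" else denom_sum
    G /= den
    G = (G + G.T) / 2.0
    ids = list(store.samples) if isinstance(store, GenotypeStore) and sample_index is None else None
    if isinstance(store, GenotypeStore) and sample_index is not None:
        ids = [store.samples[i] for i in np.asarray(sample_index)]
    return GRM(G, ids, den, used, max_rows)


def eigen_grm(grm: GRM, neg_tol: float = -1e-8) -> EigenDecomposition:
    """Full symmetric eigendecomposition of the GRM, eigenvalues descending.

    Eigenvalues in [neg_tol, 0) are clipped to 0; anything below ``neg_tol``
    signals a malformed (non-PSD) GRM and raises. Eigenvector signs are
    fixed so each vector's largest-magnitude loading is positive.
    """
    global _EIGEN_CALLS
    G = grm.matrix if isinstance(grm, GRM) else np.asarray(grm)
    if not np.all(np.isfinite(G)):
        raise ValueError("GRM contains non-finite entries")
    vals, vecs = scipy.linalg.eigh(G)
    _EIGEN_CALLS += 1
    if vals.min() < neg_tol:
        raise ValueError(f"GRM has eigenvalue {vals.min():.3g} < {neg_tol}; not PSD")
    vals = np.clip(vals, 0.0, None)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    flip = vecs[np.abs(vecs).argmax(axis=0), np.arange(vecs.shape[1])] < 0
    vecs[:, flip] *= -1
    return EigenDecomposition(vals, vecs)


def compute_pcs(eig: EigenDecomposition, k: int) -> np.ndarray:
    """Top-k principal-component scores: column j is U_j * sqrt(lambda_j)."""
    n = eig.n
    if not 1 <= k < n:
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    return eig.vectors[:, :k] * np.sqrt(eig.values[:k])


def write_grm(grm: GRM, path) -> None:
    """Whitespace-delimited full matrix with a sample-ID header row."""
    ids = grm.sample_ids or [f"s{i}" for i in range(grm.n)]
    with open(path, "w") as fh:
        fh.write(" ".join(map(str, ids)) + "\n")
        np.savetxt(fh, grm.matrix, fmt="%.10g")


def read_grm(path) -> GRM:
    with open(path) as fh:
        ids = fh.readline().split()
        mat = np.loadtxt(fh)
    if mat.shape != (len(ids), len(ids)):
        raise ValueError("GRM file shape does not match header sample count")
    return GRM(mat, ids)
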