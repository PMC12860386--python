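"""Genomic relatedness matrix (GRM) and its eigendecomposition.

``K = (1/p) X Xᵀ`` over the standardized *penalized* feature columns only —
fixed-effect covariates such as sex or site do not enter relatedness.  With
mean-square-1 standardization ``trace(K) = n`` exactly, a useful analytic
check.  The accumulation is chunked over column blocks so filebacked designs
never need the whole matrix in memory; the result is independent of chunk
size.

The full dense symmetric eigendecomposition ``K = U diag(S) Uᵀ`` is the basis
for every preconditioning step downstream.  Small negative eigenvalues from
round-off (within −1e-10) are clipped to zero.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.linalg

from .design import Design
from .exceptions import ConfigurationError, IntegrityError

_SYMMETRY_TOL = 1e-8
_NEGATIVE_CLIP = -1e-10


@dataclass
class EigenRelatedness:
    """Eigenvectors ``U`` (n x n, orthonormal) and eigenvalues ``S`` (descending)."""

    U: np.ndarray
    S: np.ndarray
    n: int
    p: int

    def reconstruct(self) -> np.ndarray:
        return (self.U * self.S) @ self.U.T


def compute_grm(d: Design, chunk_features: int | None = None) -> np.ndarray:
    """K = (1/p) X Xᵀ over penalized columns, accumulated in column chunks."""
    p = d.n_penalized
    if p == 0:
        raise ConfigurationError("design has no penalized features; K is undefined")
    n = d.n_samples
    q = d.n_unpenalized
    if chunk_features is None:
        chunk_features = p if d.storage_mode == "in_memory" else 4096
    chunk_features = max(int(chunk_features), 1)
    K = np.zeros((n, n))
    for j0 in range(q, q + p, chunk_features):
        j1 = min(j0 + chunk_features, q + p)
        block = np.array(d.X_std[:, j0:j1])
        K += block @ block.T
    K /= p
    return (K + K.T) / 2.0


def eigendecompose(K: np.ndarray, p: int | None = None) -> EigenRelatedness:
    """Full symmetric eigendecomposition, eigenvalues sorted descending.

    Raises :class:`IntegrityError` if ``K`` is asymmetric beyond 1e-8.
    """
    K = np.asarray(K, dtype=np.float64)
    asym = float(np.max(np.abs(K - K.T))) if K.size else 0.0
    if asym > _SYMMETRY_TOL:
        raise IntegrityError(f"K asymmetric: max |K - Kᵀ| = {asym:.3e}")
    S, U = scipy.linalg.eigh((K + K.T) / 2.0)
    order = np.argsort(S)[::-1]
    S = S[order]
    U = U[:, order]
    S[(S < 0) & (S >= _NEGATIVE_CLIP)] = 0.0
    return EigenRelatedness(U=np.ascontiguousarray(U), S=S, n=K.shape[0], p=p or 0)


def _design_digest(d: Design) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(d.y).tobytes())
    h.update(np.int64(d.n_unpenalized).tobytes())
    for j0 in range(0, d.X_std.shape[1], 8192):
        h.update(np.ascontiguousarray(d.X_std[:, j0 : j0 + 8192]).tobytes())
    return h.hexdigest()


def grm_eigen(
    d: Design,
    chunk_features: int | None = None,
    cache_dir: str | Path | None = None,
) -> EigenRelatedness:
    """GRM + eigendecomposition, optionally cached on disk by design content hash."""
    if cache_dir is not None:
        cache_dir = Path(cache_dir)
        cache_dir.mkdir(parents=True, exist_ok=True)
        key = _design_digest(d)
        cache_file = cache_dir / f"eig-{key}.npz"
        if cache_file.exists():
            z = np.load(cache_file)
            return EigenRelatedness(U=z["U"], S=z["S"], n=int(z["n"]), p=int(z["p"]))
    eig = eigendecompose(compute_grm(d, chunk_features), p=d.n_penalized)
    if cache_dir is not None:
        np.savez(cache_file, U=eig.U, S=eig.S, n=eig.n, p=eig.p)
    return eig
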