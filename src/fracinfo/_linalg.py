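"""Half-vectorization helpers and small matrix utilities.

The package-wide convention for ``vech`` is lower-triangular,
column-major, diagonal included:

    vech(S) = (S[0,0], S[1,0], ..., S[p-1,0], S[1,1], S[2,1], ...)

Every module that stacks moment vectors (mu, vech(Sigma)) relies on this
ordering; it is defined here once.
"""

from __future__ import annotations

import numpy as np


def vech_indices(p: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column index arrays of the vech ordering for a p x p matrix."""
    rows, cols = [], []
    for j in range(p):
        for i in range(j, p):
            rows.append(i)
            cols.append(j)
    return np.asarray(rows, dtype=np.intp), np.asarray(cols, dtype=np.intp)


def vech(mat: np.ndarray) -> np.ndarray:
    """Stack the lower triangle (incl. diagonal) column-by-column."""
    p = mat.shape[0]
    r, c = vech_indices(p)
    return np.asarray(mat)[r, c]


def unvech(v: np.ndarray, p: int) -> np.ndarray:
    """Inverse of :func:`vech`, returning a symmetric p x p matrix."""
    v = np.asarray(v, dtype=float)
    if v.size != p * (p + 1) // 2:
        raise ValueError(f"vech vector of length {v.size} does not match p={p}")
    out = np.zeros((p, p))
    r, c = vech_indices(p)
    out[r, c] = v
    out[c, r] = v
    return out


def duplication_matrix(p: int) -> np.ndarray:
    """Duplication matrix D_p with vec(S) = D_p @ vech(S) for symmetric S.

    Shape (p^2, p(p+1)/2), consistent with the package vech ordering.
    """
    r, c = vech_indices(p)
    nvech = r.size
    D = np.zeros((p * p, nvech))
    for k in range(nvech):
        i, j = r[k], c[k]
        D[j * p + i, k] = 1.0  # vec is column-major: entry (i,j) at j*p+i
        if i != j:
            D[i * p + j, k] = 1.0
    return D


def is_symmetric(mat: np.ndarray, tol: float = 1e-10) -> bool:
    return bool(np.all(np.abs(mat - mat.T) <= tol * max(1.0, np.abs(mat).max())))


def min_eigval(mat: np.ndarray) -> float:
    return float(np.linalg.eigvalsh((mat + mat.T) / 2.0)[0])


def is_pd(mat: np.ndarray, tol: float = 0.0) -> bool:
    """Positive definiteness via Cholesky of the symmetrized matrix."""
    sym = (mat + mat.T) / 2.0
    if tol > 0.0:
        sym = sym - tol * np.eye(sym.shape[0])
    try:
        np.linalg.cholesky(sym)
        return True
    except np.linalg.LinAlgError:
        return False
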