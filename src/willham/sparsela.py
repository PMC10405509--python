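"""Sparse symmetric factorization with log-determinant and selected inverse.

REML for animal models needs three things from the mixed-model coefficient
matrix ``C`` beyond solving systems: ``log|C|`` for the restricted
likelihood, multi-right-hand-side solves for average-information terms, and
*selected* entries of ``C``:sup:`-1` (on the sparsity pattern of the
Cholesky factor) for the trace terms of EM updates and likelihood
gradients.  SuperLU in symmetric mode (diagonal pivoting, symmetric
permutation) yields an ``L D L'`` factorization, and the Takahashi
recurrences then deliver every inverse entry on the factor pattern at
roughly the cost of the factorization itself.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from numba import njit
from scipy.sparse.linalg import splu

__all__ = ["SymFactor", "NotPositiveDefiniteError"]


class NotPositiveDefiniteError(np.linalg.LinAlgError):
    pass


class SymFactor:
    """LDL' factorization of a sparse symmetric positive-definite matrix."""

    def __init__(self, C: sp.spmatrix):
        C = sp.csc_matrix(C)
        n = C.shape[0]
        try:
            self._lu = splu(
                C,
                permc_spec="MMD_AT_PLUS_A",
                diag_pivot_thresh=0.0,
                options=dict(SymmetricMode=True),
            )
        except RuntimeError as exc:  # singular factor
            raise NotPositiveDefiniteError(str(exc)) from None
        if not np.array_equal(self._lu.perm_r, self._lu.perm_c):
            # SuperLU abandoned the symmetric permutation; the matrix is
            # far from positive definite
            raise NotPositiveDefiniteError("symmetric factorization failed")
        self.n = n
        self._d = self._lu.U.diagonal()
        if np.any(self._d <= 0):
            raise NotPositiveDefiniteError("non-positive pivot encountered")
        self._perm = self._lu.perm_c
        self._iperm = np.empty(n, dtype=np.int64)
        self._iperm[self._perm] = np.arange(n)
        self._Z = None
        self._L = None

    @property
    def logdet(self) -> float:
        return float(np.sum(np.log(self._d)))

    def solve(self, b: np.ndarray) -> np.ndarray:
        b = np.asarray(b, dtype=float)
        if b.ndim == 1:
            return self._lu.solve(b)
        return self._lu.solve(b)

    # -- selected inverse ---------------------------------------------------

    def _ensure_selected(self):
        if self._Z is not None:
            return
        L = self._lu.L.tocsc()
        L.sort_indices()
        self._L = L
        self._Z = _takahashi(L.indptr, L.indices, L.data, self._d)

    def inverse_entries(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Entries ``inv(C)[rows, cols]`` for positions inside the factor
        pattern (which covers the pattern of ``C`` itself)."""
        self._ensure_selected()
        # the factorization is of C[ip][:, ip] with ip = inverse of perm_c,
        # so original (i, j) sits at permuted (perm[i], perm[j])
        r = self._perm[np.asarray(rows, dtype=np.int64)]
        c = self._perm[np.asarray(cols, dtype=np.int64)]
        L = self._L
        return _lookup(L.indptr, L.indices, self._Z, r, c)


class LDLSolver:
    """Reusable LDL' machinery for a fixed sparsity pattern.

    REML iterates re-factorize a coefficient matrix whose pattern never
    changes; SuperLU redoes ordering and symbolic analysis on every call,
    which dominates runtime for pedigree-sparse systems with little
    fill-in.  This class performs the fill-reducing ordering (borrowed
    from one SuperLU call) and the symbolic analysis once, then runs a
    numba up-looking numeric factorization per iteration.
    """

    def __init__(self, C: sp.spmatrix, perm: np.ndarray | None = None):
        C = sp.csc_matrix(C)
        self.n = C.shape[0]
        if perm is None:
            lu = splu(
                C, permc_spec="MMD_AT_PLUS_A", diag_pivot_thresh=0.0,
                options=dict(SymmetricMode=True),
            )
            # splu factors C[ip][:, ip] with ip = inverse of perm_c
            perm = np.empty(self.n, dtype=np.int64)
            perm[lu.perm_c] = np.arange(self.n)
        self.perm = np.asarray(perm, dtype=np.int64)
        self._iperm = np.empty(self.n, dtype=np.int64)
        self._iperm[self.perm] = np.arange(self.n)
        U = self._permuted_upper(C)
        self._Up, self._Ui = U.indptr, U.indices
        self._nnz_upper = U.nnz
        self._parent, self._Lp = _ldl_symbolic(self.n, self._Up, self._Ui)

    def _permuted_upper(self, C: sp.spmatrix) -> sp.csc_matrix:
        Cp = C[self.perm][:, self.perm].tocsc()
        U = sp.triu(Cp, format="csc")
        U.sort_indices()
        return U

    def factor(self, C: sp.spmatrix) -> "LDLFactor":
        U = self._permuted_upper(C)
        if U.nnz != self._nnz_upper or not np.array_equal(U.indices, self._Ui):
            # pattern changed: redo the symbolic analysis
            self.__init__(C, self.perm)
            U = self._permuted_upper(C)
        Li, Lx, D, ok = _ldl_numeric(
            self.n, U.indptr, U.indices, U.data, self._parent, self._Lp
        )
        if not ok:
            raise NotPositiveDefiniteError("non-positive pivot in LDL'")
        return LDLFactor(self.n, self.perm, self._iperm, self._Lp, Li, Lx, D)


class LDLFactor:
    """Numeric LDL' factor with solve, log-determinant and selected inverse."""

    def __init__(self, n, perm, iperm, Lp, Li, Lx, D):
        self.n = n
        self._perm = perm
        self._iperm = iperm
        self._Lp, self._Li, self._Lx, self._d = Lp, Li, Lx, D
        self._Zoff = None
        self._Zdiag = None

    @property
    def logdet(self) -> float:
        return float(np.sum(np.log(self._d)))

    def solve(self, b: np.ndarray) -> np.ndarray:
        b = np.asarray(b, dtype=float)
        squeeze = b.ndim == 1
        B = b[:, None] if squeeze else b
        X = _ldl_solve(self._Lp, self._Li, self._Lx, self._d,
                       np.ascontiguousarray(B[self._perm]))
        out = np.empty_like(X)
        out[self._perm] = X
        return out[:, 0] if squeeze else out

    def inverse_entries(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        if self._Zoff is None:
            self._Zoff, self._Zdiag = _takahashi_ldl(
                self._Lp, self._Li, self._Lx, self._d
            )
        # the factorization is of C[perm][:, perm]: original (i, j) sits at
        # permuted (iperm[i], iperm[j])
        r = self._iperm[np.asarray(rows, dtype=np.int64)]
        c = self._iperm[np.asarray(cols, dtype=np.int64)]
        return _lookup_ldl(self._Lp, self._Li, self._Zoff, self._Zdiag, r, c)


@njit(cache=True)
def _ldl_symbolic(n, Ap, Ai):  # pragma: no cover - numba kernel
    # elimination tree and column counts from the upper-triangular pattern
    parent = np.full(n, -1, dtype=np.int64)
    flag = np.full(n, -1, dtype=np.int64)
    Lnz = np.zeros(n, dtype=np.int64)
    for j in range(n):
        flag[j] = j
        for p in range(Ap[j], Ap[j + 1]):
            i = Ai[p]
            while i != j and flag[i] != j:
                if parent[i] == -1:
                    parent[i] = j
                Lnz[i] += 1
                flag[i] = j
                i = parent[i]
    Lp = np.zeros(n + 1, dtype=np.int64)
    for j in range(n):
        Lp[j + 1] = Lp[j] + Lnz[j]
    return parent, Lp


@njit(cache=True)
def _ldl_numeric(n, Ap, Ai, Ax, parent, Lp):  # pragma: no cover - numba kernel
    Li = np.empty(Lp[n], dtype=np.int64)
    Lx = np.empty(Lp[n])
    D = np.empty(n)
    Y = np.zeros(n)
    pattern = np.empty(n, dtype=np.int64)
    flag = np.full(n, -1, dtype=np.int64)
    lnz = np.zeros(n, dtype=np.int64)
    for j in range(n):
        top = n
        flag[j] = j
        for p in range(Ap[j], Ap[j + 1]):
            i = Ai[p]
            Y[i] += Ax[p]
            length = 0
            while flag[i] != j:
                pattern[length] = i
                length += 1
                flag[i] = j
                i = parent[i]
            while length > 0:
                length -= 1
                top -= 1
                pattern[top] = pattern[length]
        D[j] = Y[j]
        Y[j] = 0.0
        for t in range(top, n):
            k = pattern[t]
            yk = Y[k]
            Y[k] = 0.0
            for p in range(Lp[k], Lp[k] + lnz[k]):
                Y[Li[p]] -= Lx[p] * yk
            ljk = yk / D[k]
            D[j] -= ljk * yk
            Li[Lp[k] + lnz[k]] = j
            Lx[Lp[k] + lnz[k]] = ljk
            lnz[k] += 1
        if D[j] <= 0.0:
            return Li, Lx, D, False
    return Li, Lx, D, True


@njit(cache=True)
def _ldl_solve(Lp, Li, Lx, D, B):  # pragma: no cover - numba kernel
    n, m = B.shape
    X = B.copy()
    for col in range(m):
        for j in range(n):
            xj = X[j, col]
            if xj != 0.0:
                for p in range(Lp[j], Lp[j + 1]):
                    X[Li[p], col] -= Lx[p] * xj
        for j in range(n):
            X[j, col] /= D[j]
        for j in range(n - 1, -1, -1):
            acc = X[j, col]
            for p in range(Lp[j], Lp[j + 1]):
                acc -= Lx[p] * X[Li[p], col]
            X[j, col] = acc
    return X


@njit(cache=True, inline="always")
def _get_ldl(Lp, Li, Zoff, Zdiag, i, j):  # pragma: no cover - numba kernel
    # Z entry at (i, j) with i >= j; unit diagonal is implicit in L
    if i == j:
        return Zdiag[j]
    lo, hi = Lp[j], Lp[j + 1]
    while lo < hi:
        mid = (lo + hi) // 2
        v = Li[mid]
        if v == i:
            return Zoff[mid]
        if v < i:
            lo = mid + 1
        else:
            hi = mid
    return 0.0


@njit(cache=True)
def _takahashi_ldl(Lp, Li, Lx, D):  # pragma: no cover - numba kernel
    # selected inverse on the pattern of L (implicit unit diagonal)
    n = D.shape[0]
    Zoff = np.zeros_like(Lx)
    Zdiag = np.empty(n)
    for j in range(n - 1, -1, -1):
        lo, hi = Lp[j], Lp[j + 1]
        for t in range(hi - 1, lo - 1, -1):
            i = Li[t]
            acc = 0.0
            for u in range(lo, hi):
                k = Li[u]
                lkj = Lx[u]
                if lkj == 0.0:
                    continue
                if k == i:
                    z = Zdiag[i]
                elif k < i:
                    z = _get_ldl(Lp, Li, Zoff, Zdiag, i, k)
                else:
                    z = _get_ldl(Lp, Li, Zoff, Zdiag, k, i)
                acc -= lkj * z
            Zoff[t] = acc
        acc = 1.0 / D[j]
        for u in range(lo, hi):
            acc -= Lx[u] * Zoff[u]
        Zdiag[j] = acc
    return Zoff, Zdiag


@njit(cache=True)
def _lookup_ldl(Lp, Li, Zoff, Zdiag, rows, cols):  # pragma: no cover
    m = rows.shape[0]
    out = np.empty(m)
    for t in range(m):
        i, j = rows[t], cols[t]
        if i < j:
            i, j = j, i
        out[t] = _get_ldl(Lp, Li, Zoff, Zdiag, i, j)
    return out


@njit(cache=True)
def _takahashi(indptr, indices, data, d):  # pragma: no cover - numba kernel
    # Z holds inv(C) on the (lower-triangular) pattern of L, aligned with
    # L's storage.  Columns are processed last to first; within a column the
    # off-diagonal entries are filled top-down using already-finished
    # columns to the right.
    n = indptr.shape[0] - 1
    Z = np.zeros_like(data)
    for j in range(n - 1, -1, -1):
        lo, hi = indptr[j], indptr[j + 1]
        # locate the sub-diagonal entries of column j
        # (SuperLU stores the unit diagonal explicitly)
        for t in range(hi - 1, lo - 1, -1):
            i = indices[t]
            if i == j:
                continue
            acc = 0.0
            for u in range(lo, hi):
                k = indices[u]
                if k == j:
                    continue
                lkj = data[u]
                if lkj == 0.0:
                    continue
                # symmetric lookup of Z[max(i,k), min(i,k)]
                if k == i:
                    zik = _get(indptr, indices, Z, i, i)
                elif k < i:
                    zik = _get(indptr, indices, Z, i, k)
                else:
                    zik = _get(indptr, indices, Z, k, i)
                acc -= lkj * zik
            Z[t] = acc
        # diagonal entry
        acc = 1.0 / d[j]
        for u in range(lo, hi):
            k = indices[u]
            if k == j:
                continue
            acc -= data[u] * Z[u]
        for t in range(lo, hi):
            if indices[t] == j:
                Z[t] = acc
                break
    return Z


@njit(cache=True, inline="always")
def _get(indptr, indices, Z, i, j):  # pragma: no cover - numba kernel
    # binary search for row i in column j (i >= j); absent => 0
    lo, hi = indptr[j], indptr[j + 1]
    while lo < hi:
        mid = (lo + hi) // 2
        v = indices[mid]
        if v == i:
            return Z[mid]
        if v < i:
            lo = mid + 1
        else:
            hi = mid
    return 0.0


@njit(cache=True)
def _lookup(indptr, indices, Z, rows, cols):  # pragma: no cover - numba kernel
    m = rows.shape[0]
    out = np.empty(m)
    for t in range(m):
        i, j = rows[t], cols[t]
        if i < j:
            i, j = j, i
        out[t] = _get(indptr, indices, Z, i, j)
    return out
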