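"""Simplicial sparse LDL' factorization with Takahashi selected inverse.

A compact up-looking LDL' factorization (elimination-tree based, in the
style of Davis's LDL algorithm) for the symmetric positive-definite mixed
model equations, plus the Takahashi recurrences that compute every entry of
the matrix inverse lying on the (filled) factor pattern.  Those selected
inverse entries are exactly what EM/AI-REML needs for its trace terms.

All inner loops are numba-compiled.  The symbolic analysis is done once per
sparsity pattern and reused across numeric refactorizations.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy import sparse


@njit(cache=True)
def _ldl_symbolic(n, Ap, Ai):
    parent = np.full(n, -1, np.int64)
    lnz = np.zeros(n, np.int64)
    flag = np.full(n, -1, np.int64)
    for k in range(n):
        flag[k] = k
        for p in range(Ap[k], Ap[k + 1]):
            i = Ai[p]
            if i < k:
                while flag[i] != k:
                    if parent[i] == -1:
                        parent[i] = k
                    lnz[i] += 1
                    flag[i] = k
                    i = parent[i]
    Lp = np.zeros(n + 1, np.int64)
    for k in range(n):
        Lp[k + 1] = Lp[k] + lnz[k]
    return Lp, parent


@njit(cache=True)
def _ldl_numeric(n, Ap, Ai, Ax, Lp, parent, Li, Lx, D):
    """Numeric factorization; returns -1 on success, else the failing column."""
    Y = np.zeros(n)
    pattern = np.empty(n, np.int64)
    flag = np.full(n, -1, np.int64)
    lnz = np.zeros(n, np.int64)
    for k in range(n):
        Y[k] = 0.0
        top = n
        flag[k] = k
        for p in range(Ap[k], Ap[k + 1]):
            i = Ai[p]
            if i <= k:
                Y[i] += Ax[p]
                length = 0
                while flag[i] != k:
                    pattern[length] = i
                    length += 1
                    flag[i] = k
                    i = parent[i]
                while length > 0:
                    length -= 1
                    top -= 1
                    pattern[top] = pattern[length]
        D[k] = Y[k]
        Y[k] = 0.0
        while top < n:
            i = pattern[top]
            yi = Y[i]
            Y[i] = 0.0
            p2 = Lp[i] + lnz[i]
            for p in range(Lp[i], p2):
                Y[Li[p]] -= Lx[p] * yi
            l_ki = yi / D[i]
            D[k] -= l_ki * yi
            Li[p2] = k
            Lx[p2] = l_ki
            lnz[i] += 1
            top += 1
        if D[k] <= 0.0:
            return k
    return -1


@njit(cache=True)
def _ldl_solve_many(n, Lp, Li, Lx, D, B):
    """Solve LDL' X = B in place; B is (n, nrhs)."""
    nrhs = B.shape[1]
    for r in range(nrhs):
        for j in range(n):
            bj = B[j, r]
            if bj != 0.0:
                for p in range(Lp[j], Lp[j + 1]):
                    B[Li[p], r] -= Lx[p] * bj
        for j in range(n):
            B[j, r] /= D[j]
        for j in range(n - 1, -1, -1):
            s = B[j, r]
            for p in range(Lp[j], Lp[j + 1]):
                s -= Lx[p] * B[Li[p], r]
            B[j, r] = s
    return B


@njit(cache=True, inline="always")
def _zlookup(Lp, Li, Zx, Zd, r, c):
    """Inverse entry at (r, c) with r >= c from the Takahashi storage."""
    if r == c:
        return Zd[c]
    lo = Lp[c]
    hi = Lp[c + 1]
    while lo < hi:
        mid = (lo + hi) >> 1
        v = Li[mid]
        if v == r:
            return Zx[mid]
        elif v < r:
            lo = mid + 1
        else:
            hi = mid
    return 0.0


@njit(cache=True)
def _takahashi_pair_count(n, Lp):
    total = 0
    for j in range(n):
        s = Lp[j + 1] - Lp[j]
        total += s * s
    return total


@njit(cache=True)
def _takahashi_symbolic(n, Lp, Li, zidx):
    """Precompute the inverse-entry indices read by the recurrences.

    Enumeration order matches :func:`_takahashi_numeric`: columns from the
    last to the first, rows within a column from the bottom up, and for
    each target entry the full column pattern.  Index >= nnz(L) encodes a
    diagonal entry (idx - nnz)."""
    nz = Lp[n]
    t = 0
    for j in range(n - 1, -1, -1):
        p0 = Lp[j]
        p1 = Lp[j + 1]
        for pi in range(p1 - 1, p0 - 1, -1):
            i = Li[pi]
            for pk in range(p0, p1):
                k = Li[pk]
                if k == i:
                    zidx[t] = nz + i
                else:
                    if k > i:
                        r, c = k, i
                    else:
                        r, c = i, k
                    lo = Lp[c]
                    hi = Lp[c + 1]
                    found = np.int64(-1)
                    while lo < hi:
                        mid = (lo + hi) >> 1
                        v = Li[mid]
                        if v == r:
                            found = mid
                            break
                        elif v < r:
                            lo = mid + 1
                        else:
                            hi = mid
                    zidx[t] = found
                t += 1
    return t


@njit(cache=True)
def _takahashi_numeric(n, Lp, Li, Lx, D, zidx):
    nz = Lp[n]
    Zx = np.zeros(nz)
    Zd = np.zeros(n)
    t = 0
    for j in range(n - 1, -1, -1):
        p0 = Lp[j]
        p1 = Lp[j + 1]
        for pi in range(p1 - 1, p0 - 1, -1):
            s = 0.0
            for pk in range(p0, p1):
                idx = zidx[t]
                t += 1
                if idx >= nz:
                    z = Zd[idx - nz]
                elif idx >= 0:
                    z = Zx[idx]
                else:
                    z = 0.0
                s += Lx[pk] * z
            Zx[pi] = -s
        s = 1.0 / D[j]
        for pk in range(p0, p1):
            s -= Lx[pk] * Zx[pk]
        Zd[j] = s
    return Zx, Zd


@njit(cache=True)
def _takahashi(n, Lp, Li, Lx, D):
    Zx = np.zeros(Lp[n])
    Zd = np.zeros(n)
    for j in range(n - 1, -1, -1):
        p0 = Lp[j]
        p1 = Lp[j + 1]
        for pi in range(p1 - 1, p0 - 1, -1):
            i = Li[pi]
            s = 0.0
            for pk in range(p0, p1):
                k = Li[pk]
                if k >= i:
                    z = _zlookup(Lp, Li, Zx, Zd, k, i)
                else:
                    z = _zlookup(Lp, Li, Zx, Zd, i, k)
                s += Lx[pk] * z
            Zx[pi] = -s
        s = 1.0 / D[j]
        for pk in range(p0, p1):
            s -= Lx[pk] * Zx[pk]
        Zd[j] = s
    return Zx, Zd


@njit(cache=True)
def _entry_indices(Lp, Li, rows, cols):
    """Index of each (row >= col) entry in the [Zx | Zd] storage, -1 if absent."""
    nz = Lp[len(Lp) - 1]
    out = np.empty(len(rows), np.int64)
    for t in range(len(rows)):
        r = rows[t]
        c = cols[t]
        if r == c:
            out[t] = nz + r
            continue
        lo = Lp[c]
        hi = Lp[c + 1]
        out[t] = -1
        while lo < hi:
            mid = (lo + hi) >> 1
            v = Li[mid]
            if v == r:
                out[t] = mid
                break
            elif v < r:
                lo = mid + 1
            else:
                hi = mid
    return out


class SingularMatrixError(np.linalg.LinAlgError):
    pass


def fill_reducing_order(A: sparse.spmatrix) -> np.ndarray:
    """Minimum-degree ordering (new position -> old index) for an SPD matrix.

    Uses SuperLU's MMD_AT_PLUS_A column ordering in symmetric mode; falls
    back to the natural order if the one-off factorization fails."""
    from scipy.sparse.linalg import splu

    A = sparse.csc_matrix(A)
    try:
        lu = splu(
            A,
            permc_spec="MMD_AT_PLUS_A",
            diag_pivot_thresh=0.0,
            options=dict(SymmetricMode=True),
        )
    except Exception:
        return np.arange(A.shape[0])
    pinv = np.empty(A.shape[0], np.int64)
    pinv[lu.perm_c] = np.arange(A.shape[0])
    return pinv


class LDLFactor:
    """Reusable LDL' factorization of a sparse SPD matrix.

    ``perm`` is a fill-reducing permutation (new order -> old index).  The
    symbolic analysis is retained so that matrices with the same pattern can
    be refactored cheaply via :meth:`refactor`.
    """

    def __init__(self, A: sparse.spmatrix, perm: np.ndarray | None = None):
        A = sparse.csc_matrix(A)
        n = A.shape[0]
        self.n = n
        if perm is None:
            perm = np.arange(n)
        self.perm = np.asarray(perm, np.int64)
        self.pinv = np.empty(n, np.int64)
        self.pinv[self.perm] = np.arange(n)
        Ap = A[self.perm][:, self.perm].tocsc()
        Ap.sort_indices()
        self._Ap_pattern = (Ap.indptr.copy(), Ap.indices.copy())
        self.Lp, self._parent = _ldl_symbolic(n, Ap.indptr, Ap.indices)
        self.Li = np.empty(self.Lp[n], np.int64)
        self.Lx = np.empty(self.Lp[n], np.float64)
        self.D = np.empty(n, np.float64)
        self._Zx: np.ndarray | None = None
        self._Zd: np.ndarray | None = None
        self._tak_idx: np.ndarray | None = None
        self._tak_big = False
        self._numeric(Ap.data)

    def _numeric(self, Ax: np.ndarray) -> None:
        bad = _ldl_numeric(
            self.n,
            self._Ap_pattern[0],
            self._Ap_pattern[1],
            Ax,
            self.Lp,
            self._parent,
            self.Li,
            self.Lx,
            self.D,
        )
        if bad >= 0:
            raise SingularMatrixError(
                f"non-positive pivot at equation {self.perm[bad]} "
                "(rank-deficient or indefinite system)"
            )
        self._Zx = None
        self._Zd = None

    def refactor(self, A: sparse.spmatrix) -> "LDLFactor":
        """Refactorize a matrix with the identical sparsity pattern."""
        Ap = sparse.csc_matrix(A)[self.perm][:, self.perm].tocsc()
        Ap.sort_indices()
        if len(Ap.data) != len(self._Ap_pattern[1]):
            raise ValueError("sparsity pattern changed; build a new LDLFactor")
        self._numeric(Ap.data)
        return self

    def solve(self, b: np.ndarray) -> np.ndarray:
        b = np.asarray(b, float)
        squeeze = b.ndim == 1
        B = b.reshape(self.n, -1)[self.perm].copy()
        _ldl_solve_many(self.n, self.Lp, self.Li, self.Lx, self.D, B)
        out = np.empty_like(B)
        out[self.perm] = B
        return out[:, 0] if squeeze else out

    @property
    def logdet(self) -> float:
        return float(np.sum(np.log(self.D)))

    #: pair-index tables above this size fall back to on-the-fly lookups
    #: (int32 indices: 4 bytes per pair)
    SYMBOLIC_PAIR_LIMIT = 500_000_000

    # -- selected inverse -------------------------------------------------
    def compute_selected_inverse(self) -> None:
        """Takahashi recurrences for the inverse on the factor pattern.

        The entry indices visited by the recurrences depend only on the
        pattern, so they are resolved once and replayed on refactorized
        matrices; very large patterns fall back to on-the-fly lookups."""
        if self._tak_idx is None and self._tak_big is False:
            pairs = _takahashi_pair_count(self.n, self.Lp)
            if pairs <= self.SYMBOLIC_PAIR_LIMIT:
                self._tak_idx = np.empty(pairs, np.int32)
                _takahashi_symbolic(self.n, self.Lp, self.Li, self._tak_idx)
            else:
                self._tak_big = True
        if self._tak_idx is not None:
            self._Zx, self._Zd = _takahashi_numeric(
                self.n, self.Lp, self.Li, self.Lx, self.D, self._tak_idx
            )
        else:
            self._Zx, self._Zd = _takahashi(self.n, self.Lp, self.Li, self.Lx, self.D)

    def entry_indices(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Storage indices for inverse entries at (rows, cols).

        The returned indices stay valid across :meth:`refactor` calls and
        are resolved against the current selected inverse by
        :meth:`gather_inverse`.  Entries outside the factor pattern (which
        cannot happen for entries of the original matrix) come back as -1.
        """
        pr = self.pinv[np.asarray(rows, np.int64)]
        pc = self.pinv[np.asarray(cols, np.int64)]
        lo = np.minimum(pr, pc)
        hi = np.maximum(pr, pc)
        return _entry_indices(self.Lp, self.Li, hi, lo)

    def gather_inverse(self, idx: np.ndarray) -> np.ndarray:
        if self._Zx is None:
            self.compute_selected_inverse()
        store = np.concatenate([self._Zx, self._Zd])
        out = np.zeros(len(idx))
        ok = idx >= 0
        out[ok] = store[idx[ok]]
        return out

    @property
    def fill_nnz(self) -> int:
        return int(self.Lp[self.n])
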