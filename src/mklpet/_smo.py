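"""Sequential minimal optimization for the soft-margin SVM dual.

Solves

    max_a  sum_i a_i - 1/2 sum_ij a_i a_j y_i y_j K_ij
    s.t.   sum_i a_i y_i = 0,  0 <= a_i <= C

by maximal-violating-pair SMO with second-order working-set selection.
The stopping rule bounds the KKT violation directly: writing
f_i = sum_j a_j y_j K_ij, the solver stops when

    max_{i in I_up} (y_i - f_i) - min_{j in I_low} (y_j - f_j) < tol,

which is the width of the feasible interval for the bias; at tol the margin
residuals |y_i g(x_i) - 1| of free support vectors are below tol as well.

The kernel loop is JIT-compiled with numba when available; a pure-Python
twin (identical code path) is used otherwise.  Problem sizes here are tiny
(tens of samples), so the pure path is still usable.
"""

from __future__ import annotations

import numpy as np

DEFAULT_TOL = 1e-8


def _smo_kernel(K, y, C, tol, max_iter, alpha):
    n = y.shape[0]
    # G_i = y_i f_i - 1 with f_i = sum_j alpha_j y_j K_ij
    G = np.empty(n)
    for i in range(n):
        s = 0.0
        for j in range(n):
            if alpha[j] > 0.0:
                s += alpha[j] * y[j] * K[i, j]
        G[i] = y[i] * s - 1.0

    it = 0
    while it < max_iter:
        it += 1
        # working-set selection: i = argmax over I_up of (y_i - f_i) = -y_i G_i
        gmax = -1e300
        ii = -1
        for t in range(n):
            if (y[t] > 0.0 and alpha[t] < C) or (y[t] < 0.0 and alpha[t] > 0.0):
                v = -y[t] * G[t]
                if v > gmax:
                    gmax = v
                    ii = t
        gmax2 = -1e300
        jj = -1
        obj_min = 1e300
        for t in range(n):
            if (y[t] > 0.0 and alpha[t] > 0.0) or (y[t] < 0.0 and alpha[t] < C):
                v = y[t] * G[t]
                if v > gmax2:
                    gmax2 = v
                grad_diff = gmax + v
                if grad_diff > 0.0:
                    quad = K[ii, ii] + K[t, t] - 2.0 * K[ii, t]
                    if quad <= 0.0:
                        quad = 1e-12
                    obj = -(grad_diff * grad_diff) / quad
                    if obj < obj_min:
                        obj_min = obj
                        jj = t
        if ii == -1 or jj == -1 or gmax + gmax2 < tol:
            break

        quad = K[ii, ii] + K[jj, jj] - 2.0 * K[ii, jj]
        if quad <= 0.0:
            quad = 1e-12
        # unconstrained step along the feasible pair direction
        delta = (gmax + y[jj] * G[jj]) / quad
        # box limits: alpha_i moves by y_i*delta, alpha_j by -y_j*delta
        if y[ii] > 0.0:
            dmax = C - alpha[ii]
        else:
            dmax = alpha[ii]
        if y[jj] > 0.0:
            if alpha[jj] < dmax:
                dmax = alpha[jj]
        else:
            if C - alpha[jj] < dmax:
                dmax = C - alpha[jj]
        if delta > dmax:
            delta = dmax
        if delta <= 0.0:
            break

        alpha[ii] += y[ii] * delta
        alpha[jj] -= y[jj] * delta
        # snap to the box to keep index-set tests exact
        if alpha[ii] < 1e-14:
            alpha[ii] = 0.0
        if alpha[ii] > C - 1e-14 * C:
            alpha[ii] = C
        if alpha[jj] < 1e-14:
            alpha[jj] = 0.0
        if alpha[jj] > C - 1e-14 * C:
            alpha[jj] = C

        for t in range(n):
            G[t] += y[t] * delta * (K[t, ii] - K[t, jj])
    return it


def _bias_from_alpha(K, y, C, alpha):
    n = y.shape[0]
    nfree = 0
    s = 0.0
    for i in range(n):
        if alpha[i] > 1e-10 * C and alpha[i] < C * (1.0 - 1e-10):
            f = 0.0
            for j in range(n):
                f += K[i, j] * alpha[j] * y[j]
            s += y[i] - f
            nfree += 1
    if nfree > 0:
        return s / nfree
    hi = -1e300
    lo = 1e300
    for i in range(n):
        f = 0.0
        for j in range(n):
            f += K[i, j] * alpha[j] * y[j]
        r = y[i] - f
        if ((y[i] > 0.0 and alpha[i] < C) or (y[i] < 0.0 and alpha[i] > 0.0)) and r > hi:
            hi = r
        if ((y[i] > 0.0 and alpha[i] > 0.0) or (y[i] < 0.0 and alpha[i] < C)) and r < lo:
            lo = r
    return 0.5 * (hi + lo)


def _grid_fold_counts(Btr, Bval, ytr, yval, Q, Cs, tol, max_iter, counts):
    """Validation-correct counts for every (q candidate, C) pair on one fold.

    Btr: (n_kernels, n_tr, n_tr) per-block train kernels; Bval likewise
    (n_val, n_tr).  C values are visited in ascending order with a warm
    start, which is feasible because enlarging the box keeps the previous
    optimum feasible.  counts has shape (n_candidates, n_C) and is
    accumulated in place.
    """
    ncand = Q.shape[0]
    nk = Q.shape[1]
    nC = Cs.shape[0]
    ntr = ytr.shape[0]
    nva = yval.shape[0]
    K = np.empty((ntr, ntr))
    Kv = np.empty((nva, ntr))
    alpha = np.empty(ntr)
    for ci in range(ncand):
        for a in range(ntr):
            for b in range(ntr):
                s = 0.0
                for m in range(nk):
                    s += Q[ci, m] * Btr[m, a, b]
                K[a, b] = s
        for a in range(nva):
            for b in range(ntr):
                s = 0.0
                for m in range(nk):
                    s += Q[ci, m] * Bval[m, a, b]
                Kv[a, b] = s
        for t in range(ntr):
            alpha[t] = 0.0
        for cj in range(nC):
            C = Cs[cj]
            _smo_kernel(K, ytr, C, tol, max_iter, alpha)
            bias = _bias_from_alpha(K, ytr, C, alpha)
            correct = 0
            for a in range(nva):
                g = bias
                for b in range(ntr):
                    g += Kv[a, b] * alpha[b] * ytr[b]
                if (g >= 0.0 and yval[a] > 0.0) or (g < 0.0 and yval[a] < 0.0):
                    correct += 1
            counts[ci, cj] += correct


try:  # pragma: no cover - exercised implicitly
    import numba

    _smo_kernel = numba.njit(cache=True, fastmath=False)(_smo_kernel)
    _bias_from_alpha = numba.njit(cache=True, fastmath=False)(_bias_from_alpha)
    _grid_fold_counts = numba.njit(cache=True, fastmath=False)(_grid_fold_counts)
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False


def grid_fold_counts(Btr, Bval, ytr, yval, Q, Cs, tol, max_iter, counts) -> None:
    """Wrapper ensuring contiguous float64 inputs for the compiled kernel."""
    _grid_fold_counts(
        np.ascontiguousarray(Btr, dtype=np.float64),
        np.ascontiguousarray(Bval, dtype=np.float64),
        np.ascontiguousarray(ytr, dtype=np.float64),
        np.ascontiguousarray(yval, dtype=np.float64),
        np.ascontiguousarray(Q, dtype=np.float64),
        np.ascontiguousarray(Cs, dtype=np.float64),
        float(tol),
        int(max_iter),
        counts,
    )


def solve_dual(
    K: np.ndarray,
    y: np.ndarray,
    C: float,
    tol: float = DEFAULT_TOL,
    max_iter: int = 200_000,
    warm_alpha: np.ndarray | None = None,
) -> np.ndarray:
    """Solve the dual; returns alpha.  ``warm_alpha`` seeds the iteration.

    A warm start must itself be feasible (in the box and on the equality
    constraint); callers re-solving at a new C should clip and rebalance
    first or pass None.
    """
    n = y.shape[0]
    if warm_alpha is not None:
        alpha = np.clip(warm_alpha.astype(np.float64), 0.0, C)
        # repair the equality constraint if clipping broke it
        if abs(float(alpha @ y)) > 1e-12:
            alpha = np.zeros(n)
    else:
        alpha = np.zeros(n)
    _smo_kernel(
        np.ascontiguousarray(K, dtype=np.float64),
        np.ascontiguousarray(y, dtype=np.float64),
        float(C),
        float(tol),
        int(max_iter),
        alpha,
    )
    return alpha
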