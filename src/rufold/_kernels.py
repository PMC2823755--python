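"""Optional numba-jitted inner loops for the three solvers.

Each kernel implements exactly the same recurrences and evaluation order as
the pure-Python engine in :mod:`rufold.nussinov` / :mod:`rufold.four_russians`;
the test suite asserts cell-for-cell equality between engines.  Kernels take
the padded pair-score matrix B (see ``sequences.pair_score_matrix``) and
return the padded score table.

If numba is not importable the module degrades gracefully: ``available()``
returns False and callers fall back to the Python engines.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        return deco if not (args and callable(args[0])) else args[0]


def available() -> bool:
    return _HAVE_NUMBA


@njit(cache=False)
def _fold_diagonal(B, n):
    S = np.zeros((n + 2, n + 2), dtype=np.int32)
    for span in range(1, n):
        for i in range(1, n - span + 1):
            j = i + span
            best = S[i + 1, j - 1] + B[i, j]
            if S[i, j - 1] > best:
                best = S[i, j - 1]
            if S[i + 1, j] > best:
                best = S[i + 1, j]
            for k in range(i + 1, j):
                cand = S[i, k] + S[k + 1, j]
                if cand > best:
                    best = cand
            S[i, j] = best
    return S


@njit(cache=False)
def _fold_column(B, n):
    S = np.zeros((n + 2, n + 2), dtype=np.int32)
    for j in range(2, n + 1):
        for i in range(1, j):
            a = S[i + 1, j - 1] + B[i, j]
            b = S[i, j - 1]
            S[i, j] = a if a > b else b
        for i in range(j - 1, 0, -1):
            best = S[i, j]
            if S[i + 1, j] > best:
                best = S[i + 1, j]
            for k in range(j - 1, i, -1):
                cand = S[i, k - 1] + S[k, j]
                if cand > best:
                    best = cand
            S[i, j] = best
    return S


@njit(cache=False)
def _fold_four_russians(B, n, q, C):
    S = np.zeros((n + 2, n + 2), dtype=np.int32)
    width = 1
    for _ in range(q - 1):
        width *= C
    Gmax = n // q + 1
    # offset vectors V' for every packed difference vector (big-endian base C)
    Vp = np.zeros((width, q), dtype=np.int32)
    for v in range(width):
        rem = v
        acc = 0
        p = width
        for t in range(q - 1):
            p //= C
            dgt = rem // p
            rem -= dgt * p
            acc += dgt
            Vp[v, t + 1] = acc
    # R laid out [i, g*width + v]: the group loop for one cell walks a single
    # contiguous row slice instead of jumping across group-major blocks
    R = np.full((n + 1, Gmax * width), -1, dtype=np.int32)
    vkey = np.zeros(Gmax, dtype=np.int64)
    col = np.zeros(n + 2, dtype=np.int32)  # contiguous copy of column j
    for j in range(2, n + 1):
        # independent pass: rules a, b
        for i in range(1, j):
            a = S[i + 1, j - 1] + B[i, j]
            b = S[i, j - 1]
            col[i] = a if a > b else b
        col[j] = 0
        # dependent pass: rules c, d; cells finalized top-down, so col[k] is
        # final for every k > i when cell (i, j) is computed
        for i in range(j - 1, 0, -1):
            best = col[i]
            if col[i + 1] > best:
                best = col[i + 1]
            if j - 1 >= i + 1:
                # complete groups strictly inside (i, j): one lookup each
                gfull_lo = (i + q - 1) // q
                gfull_hi = (j - 1) // q - 1
                if gfull_hi >= gfull_lo:
                    for k in range(i + 1, gfull_lo * q + 1):  # i-side partial
                        cand = S[i, k - 1] + col[k]
                        if cand > best:
                            best = cand
                    Ri = R[i]
                    for g in range(gfull_hi, gfull_lo - 1, -1):
                        k = Ri[g * width + vkey[g]]
                        cand = S[i, k - 1] + col[k]
                        if cand > best:
                            best = cand
                    for k in range((gfull_hi + 1) * q + 1, j):  # j-side partial
                        cand = S[i, k - 1] + col[k]
                        if cand > best:
                            best = cand
                else:
                    for k in range(i + 1, j):
                        cand = S[i, k - 1] + col[k]
                        if cand > best:
                            best = cand
            col[i] = best
            S[i, j] = best
            if (i - 1) % q == 0:
                # lowest row of its Rgroup just finalized: encode v_g
                g = (i - 1) // q
                z = (g + 1) * q
                if z <= j - 1:
                    key = np.int64(0)
                    for t in range(q - 1):
                        dgt = col[z - t - 1] - col[z - t]
                        key = key * C + dgt
                    vkey[g] = key
        # interleaved preprocessing: Cgroup (j+1)//q - 1 just completed
        if (j + 1) % q == 0:
            g = (j + 1) // q - 1
            if g >= 1 and (g + 1) * q <= n:
                lo = g * q + 1
                hi = (g + 1) * q
                z = hi
                gw = g * width
                for i2 in range(1, g * q + 1):
                    Si = S[i2]
                    Ri = R[i2]
                    for v in range(width):
                        bestval = np.int64(-1)
                        bestk = -1
                        for k in range(lo, hi + 1):
                            val = Si[k - 1] + Vp[v, z - k]
                            if val > bestval:
                                bestval = val
                                bestk = k
                        Ri[gw + v] = bestk
    return S


def fold_diagonal(B: np.ndarray, n: int) -> np.ndarray:
    return _fold_diagonal(B, n)


def fold_column(B: np.ndarray, n: int) -> np.ndarray:
    return _fold_column(B, n)


def fold_four_russians(B: np.ndarray, n: int, q: int, C: int) -> np.ndarray:
    width = C ** (q - 1)
    nbytes = (n // q + 1) * (n + 1) * width * 4
    if nbytes > 4 << 30:
        raise MemoryError(
            f"eager R table would need {nbytes / 2**30:.1f} GiB "
            f"(n={n}, q={q}, C={C}); reduce q"
        )
    return _fold_four_russians(B, n, q, C)
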