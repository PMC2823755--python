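"""Reference cubic-time solvers for the basic RNA-folding problem.

S(i, j) is the maximum total score of a non-crossing matching of permitted
pairs inside the inclusive interval of sites i..j.  The recurrence is

    S(i, j) = max( S(i+1, j-1) + B(i, j),        # rule a: pair (i, j)
                   S(i, j-1),                    # rule b: j unmatched
                   S(i+1, j),                    # rule c: i unmatched
                   max_{i < k <= j-1} S(i, k-1) + S(k, j) )   # rule d

Rule d splits the interval into a head i..k-1 and a tail k..j (a bipartition).
The textbook form writes the split as S(i, k) + S(k+1, j) over i < k < j;
substituting k -> k+1 shows the two are the same family, and the column form
above is the one the Four-Russians speedup groups, so it is the internal
standard here.  Empty and inverted intervals score 0, which makes rule a
well-defined when i + 1 > j - 1.

Two evaluation orders are provided: :func:`fold_diagonal` fills by increasing
interval length (the classic order) and :func:`fold_column` fills column by
column (the order the Four-Russians speedup requires).  They compute the same
matrix cell for cell.  :func:`brute_force_score` is an independent exponential
oracle, and :func:`traceback` recovers an optimal matching from any filled
matrix by recomputing rule choices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequences import RnaSequence, ScoringScheme, pair_score_matrix

BRUTE_FORCE_CAP = 16


class ScoreMatrix:
    """Upper-triangular DP table S(i, j), 1 <= i <= j <= n, 1-based access.

    Backed by an (n+2) x (n+2) integer array whose row 0 / column 0 and
    trailing padding are always zero; cells below the diagonal are never
    written, so reads of empty intervals return 0 by construction.
    """

    def __init__(self, values: np.ndarray, n: int):
        self.values = values
        self.n = n

    def __getitem__(self, ij) -> int:
        i, j = ij
        return int(self.values[i, j])

    @property
    def score(self) -> int:
        """S(1, n): the optimal total score for the whole sequence."""
        return int(self.values[1, self.n]) if self.n >= 1 else 0

    def equals(self, other: "ScoreMatrix") -> bool:
        """Cell-for-cell equality on the stored triangle."""
        return self.n == other.n and bool(
            np.array_equal(self.values[1:, 1:], other.values[1:, 1:])
        )

    def triu_cells(self):
        """Iterate (i, j, S(i, j)) over 1 <= i <= j <= n."""
        for i in range(1, self.n + 1):
            for j in range(i, self.n + 1):
                yield i, j, int(self.values[i, j])


@dataclass(frozen=True)
class Matching:
    """A set of site pairs (i, j), i < j — a candidate secondary structure."""

    pairs: frozenset

    def __init__(self, pairs):
        object.__setattr__(
            self, "pairs", frozenset((min(i, j), max(i, j)) for i, j in pairs)
        )

    def __len__(self) -> int:
        return len(self.pairs)

    def total_score(self, seq: RnaSequence, scheme: ScoringScheme) -> int:
        from .sequences import pair_score

        return sum(pair_score(scheme, seq, i, j) for i, j in self.pairs)


def _new_table(n: int) -> np.ndarray:
    return np.zeros((n + 2, n + 2), dtype=np.int32)


def _resolve_engine(engine: str) -> str:
    if engine == "auto":
        from . import _kernels

        return "numba" if _kernels.available() else "python"
    if engine not in ("python", "numba"):
        raise ValueError(f"unknown engine {engine!r}")
    return engine


def fold_diagonal(seq: RnaSequence, scheme: ScoringScheme,
                  engine: str = "auto") -> ScoreMatrix:
    """Fill S in order of increasing interval length j - i (classic order)."""
    n = seq.n
    B = pair_score_matrix(seq, scheme)
    engine = _resolve_engine(engine)
    if engine == "numba":
        from . import _kernels

        return ScoreMatrix(_kernels.fold_diagonal(B, n), n)
    S = _new_table(n)
    for span in range(1, n):
        for i in range(1, n - span + 1):
            j = i + span
            best = max(S[i + 1, j - 1] + B[i, j], S[i, j - 1], S[i + 1, j])
            for k in range(i + 1, j):  # rule d, textbook split at k | k+1
                cand = S[i, k] + S[k + 1, j]
                if cand > best:
                    best = cand
            S[i, j] = best
    return ScoreMatrix(S, n)


def fold_column(seq: RnaSequence, scheme: ScoringScheme,
                engine: str = "auto") -> ScoreMatrix:
    """Fill S column by column: the evaluation order the speedup builds on.

    Per column j, an *independent* pass (rules a, b; ascending i) uses only
    earlier columns, then a *dependent* pass (rules c, d; descending i) uses
    cells of column j already finalized below.
    """
    n = seq.n
    B = pair_score_matrix(seq, scheme)
    engine = _resolve_engine(engine)
    if engine == "numba":
        from . import _kernels

        return ScoreMatrix(_kernels.fold_column(B, n), n)
    S = _new_table(n)
    for j in range(2, n + 1):
        for i in range(1, j):  # independent: rules a, b
            S[i, j] = max(S[i + 1, j - 1] + B[i, j], S[i, j - 1])
        for i in range(j - 1, 0, -1):  # dependent: rules c, d
            best = max(S[i, j], S[i + 1, j])
            for k in range(j - 1, i, -1):
                cand = S[i, k - 1] + S[k, j]
                if cand > best:
                    best = cand
            S[i, j] = best
    return ScoreMatrix(S, n)


def brute_force_score(seq: RnaSequence, scheme: ScoringScheme,
                      cap: int = BRUTE_FORCE_CAP) -> int:
    """Maximum score by exhaustive enumeration of non-crossing matchings.

    Independent oracle: recursion on "leave site i unmatched, or match it to
    each feasible partner j" generates every nested permitted matching exactly
    once; no memoization, no sharing with the DP solvers.  Exponential — the
    cap guards against blowup.
    """
    n = seq.n
    if n > cap:
        raise ValueError(
            f"brute force is exponential; n={n} exceeds the cap of {cap}"
        )
    res = seq.residues
    sc = scheme.score
    d = scheme.d

    def best(i: int, j: int) -> int:
        # max score of any nested permitted matching of sites i..j
        if j - i <= d:
            return 0
        top = best(i + 1, j)  # site i unmatched
        for jp in range(i + d + 1, j + 1):
            s = sc(res[i - 1], res[jp - 1])
            if s > 0:
                cand = s + best(i + 1, jp - 1) + best(jp + 1, j)
                if cand > top:
                    top = cand
        return top

    return best(1, n) if n >= 1 else 0


class TracebackError(RuntimeError):
    """The score matrix is internally inconsistent: no rule attains a cell."""


def traceback(S: ScoreMatrix, seq: RnaSequence, scheme: ScoringScheme) -> Matching:
    """Recover an optimal matching from a filled score matrix.

    Rule choices are recomputed per cell (no stored pointers); rules are tried
    in the fixed order a, b, c, d — and within d, smallest split k — so the
    output is deterministic.  The returned matching scores exactly S(1, n).
    Pairs with zero score are never emitted: they cannot change any cell.
    """
    n = seq.n
    V = S.values
    B = pair_score_matrix(seq, scheme)
    d = scheme.d
    pairs = []
    stack = [(1, n)] if n >= 1 else []
    while stack:
        i, j = stack.pop()
        if j - i <= d:
            if V[i, j] != 0:
                raise TracebackError(f"S({i},{j}) = {V[i, j]} on a base-case cell")
            continue
        target = V[i, j]
        if B[i, j] > 0 and V[i + 1, j - 1] + B[i, j] == target:  # rule a
            pairs.append((i, j))
            stack.append((i + 1, j - 1))
            continue
        if V[i, j - 1] == target:  # rule b
            stack.append((i, j - 1))
            continue
        if V[i + 1, j] == target:  # rule c
            stack.append((i + 1, j))
            continue
        for k in range(i + 1, j):  # rule d, smallest k first
            if V[i, k - 1] + V[k, j] == target:
                stack.append((i, k - 1))
                stack.append((k, j))
                break
        else:
            raise TracebackError(
                f"no rule attains S({i},{j}) = {target}; matrix inconsistent"
            )
    return Matching(pairs)
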