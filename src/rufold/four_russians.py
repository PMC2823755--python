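"""Four-Russians speedup of the column-order RNA-folding dynamic program.

The cubic cost of the folding DP is the rule-d loop: for each cell (i, j) it
scans every split point k in i+1..j-1 evaluating S(i, k-1) + S(k, j).  The
speedup partitions the rows of each column into *Rgroups* of q consecutive
rows, and replaces the scan over a group that lies entirely inside the
interval by a single table lookup.

The trick that makes a precomputed table possible is that within one column,
consecutive cells can only grow by a bounded amount as the interval extends
downward: S(z-1, j) - S(z, j) lies in {0, ..., C-1}, where C - 1 is the
maximum pair score (C = 2 for unit scoring).  The q values of a group in
column j are therefore determined, up to one additive constant, by a
difference vector v_g of q-1 small digits.  An additive constant never
changes an argmax (Fact 1), so the best split k* inside a group depends only
on (i, g, v_g) — not on j.  A table R(i, g, v) of best split points can thus
be filled for *every possible* difference vector once the columns that the
head scores S(i, k-1) live in (Cgroup g) are complete, and consulted for all
later columns.  Preprocessing is interleaved with the DP, which is what
distinguishes this use of the Four-Russians technique.

With q = floor(log_b n), b > C, the total time is O(n^3 / log n): the rule-d
loop does O(n/q) lookups per cell, the (at most two) groups cut by the
interval ends are scanned directly at O(q) per cell, and table construction
costs O(n^2 C^(q-1)) overall.

Group geometry (fixed, never re-aligned per column):

* Rgroup g covers rows g*q + 1 .. (g+1)*q; its top row is z = (g+1)*q.
* V_g is the group's column vector ordered from row z *down* to row z-q+1,
  so entry t corresponds to row z - t.
* Cgroup g covers columns g*q .. (g+1)*q - 1 (Cgroup 0: columns 1..q-1);
  those are exactly the columns k-1 ranges over for k in Rgroup g.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nussinov import ScoreMatrix, _new_table
from .sequences import RnaSequence, ScoringScheme, pair_score_matrix

#: Default cap on the group size; C^(q-1) table width grows fast with q.
DEFAULT_Q_MAX = 8

#: Refuse eager tables beyond this many bytes.
RTABLE_MEMORY_LIMIT = 4 << 30


def choose_q(n: int, C: int, q_max: int = DEFAULT_Q_MAX) -> int:
    """Group size q = floor(log_{C+1} n), clamped to [2, q_max].

    The log base must exceed C for the preprocessing term O(n^2 C^(q-1)) to
    stay within O(n^3 / log n); base C + 1 is the smallest integer choice
    (base 3 for unit scoring).  Computed with integer arithmetic to avoid
    float-log edge cases at exact powers.
    """
    if n < 2 or C < 2 or q_max < 2:
        raise ValueError(f"need n >= 2, C >= 2, q_max >= 2 (got {n}, {C}, {q_max})")
    b = C + 1
    q, p = 0, 1
    while p * b <= n:
        p *= b
        q += 1
    return max(2, min(q, q_max))


@dataclass(frozen=True)
class FourRussiansConfig:
    """Tuning knobs for the speedup; defaults preserve exactness for any q.

    q=None defers to :func:`choose_q` once the sequence length is known.
    ``lazy`` switches the R table from eager enumeration of all C^(q-1)
    difference vectors to memoization of only the keys actually queried.
    """

    q: int | None = None
    q_max: int = DEFAULT_Q_MAX
    lazy: bool = False

    def __post_init__(self) -> None:
        if self.q_max < 2:
            raise ValueError(f"q_max must be >= 2, got {self.q_max}")
        if self.q is not None and not 2 <= self.q <= self.q_max:
            raise ValueError(f"need 2 <= q <= q_max={self.q_max}, got q={self.q}")

    def resolve_q(self, n: int, C: int) -> int:
        if self.q is not None:
            return self.q
        if n < 2:
            return 2
        return choose_q(n, C, self.q_max)


@dataclass(frozen=True)
class DiffVector:
    """v_g: the q-1 consecutive differences of a group's column vector V_g.

    V_g lists S values from the group's top row z downward, so it is
    non-decreasing (a larger interval never scores less) and digit
    ``digits[t] = V_g[t+1] - V_g[t]`` lies in {0, ..., C-1}.  The packed
    ``key`` is the base-C integer with digits[0] most significant; pack and
    unpack round-trip exactly.
    """

    q: int
    C: int
    digits: tuple

    @property
    def key(self) -> int:
        k = 0
        for dgt in self.digits:
            k = k * self.C + dgt
        return k

    @classmethod
    def from_key(cls, key: int, q: int, C: int) -> "DiffVector":
        digits = []
        for _ in range(q - 1):
            digits.append(key % C)
            key //= C
        if key:
            raise ValueError("key out of range for given q, C")
        return cls(q=q, C=C, digits=tuple(reversed(digits)))


def encode_group(V, C: int) -> DiffVector:
    """Encode a group column vector (ordered row z down to z-q+1) as v_g."""
    q = len(V)
    digits = []
    for t in range(q - 1):
        dgt = V[t + 1] - V[t]
        if not 0 <= dgt < C:
            raise ValueError(
                f"consecutive difference {dgt} at offset {t} outside "
                f"{{0,...,{C - 1}}}; scheme violates the bounded-marginal premise"
            )
        digits.append(int(dgt))
    return DiffVector(q=q, C=C, digits=tuple(digits))


def decode_vector(v: DiffVector):
    """Offset vector V' with V'[0] = 0 and V'[t] the prefix sum of digits.

    V' equals the true V_g minus the constant V_g[0], so
    ``decode(encode(V)) + V[0] == V`` exactly, and by Fact 1 the argmax over a
    group computed from V' equals the one computed from V_g.
    """
    out = [0] * v.q
    for t in range(v.q - 1):
        out[t + 1] = out[t] + v.digits[t]
    return out


class RTableError(RuntimeError):
    """Sequencing bug: an R-table group was used before its Cgroup completed."""


class RTable:
    """The lookup R(i, g, v) -> k*: best split index within Rgroup g.

    Eager mode materializes, for every complete group g >= 1 and every row i
    below the group (1 <= i <= g*q), all C^(q-1) difference keys — exactly the
    set of lookups the dependent pass can ever issue.  Lazy mode memoizes only
    (i, g, key) triples actually queried, computing each on first use from the
    same columns.  Both modes require Cgroup g to be complete first;
    ``columns_filled`` tracks progress and guards the precondition.
    """

    def __init__(self, S: np.ndarray, n: int, q: int, C: int, lazy: bool = False):
        self.S = S
        self.n = n
        self.q = q
        self.C = C
        self.width = C ** (q - 1)
        self.lazy = lazy
        self.columns_filled = 0
        self.built_groups: set[int] = set()
        self._eager: dict[int, np.ndarray] = {}
        self._lazy: dict[tuple, int] = {}
        self._offsets = [decode_vector(DiffVector.from_key(v, q, C))
                         for v in range(self.width)]

    # -- geometry -----------------------------------------------------------
    def group_rows(self, g: int) -> range:
        """Rows of Rgroup g, ascending: g*q + 1 .. (g+1)*q."""
        return range(g * self.q + 1, (g + 1) * self.q + 1)

    def cgroup_last_column(self, g: int) -> int:
        return (g + 1) * self.q - 1

    def _check_complete(self, g: int) -> None:
        need = self.cgroup_last_column(g)
        if self.columns_filled < need:
            raise RTableError(
                f"Cgroup {g} incomplete: columns filled through "
                f"{self.columns_filled}, need {need}"
            )

    # -- construction -------------------------------------------------------
    def _kstar(self, i: int, g: int, offsets) -> int:
        """argmax over k in Rgroup g of S(i, k-1) + V'[z - k]; smallest-k ties."""
        z = (g + 1) * self.q
        bestval, bestk = -1, -1
        for k in self.group_rows(g):
            val = int(self.S[i, k - 1]) + offsets[z - k]
            if val > bestval:
                bestval, bestk = val, k
        return bestk

    def build_group(self, g: int) -> None:
        """Eagerly fill R(i, g, v) for all i <= g*q and all C^(q-1) keys.

        Legal only once every column of Cgroup g is filled (the head scores
        S(i, k-1) it reads live there).
        """
        if g < 1:
            return  # no row i >= 1 lies below Rgroup 0; nothing to store
        self._check_complete(g)
        if g in self.built_groups:
            return
        imax = g * self.q
        table = np.full((imax + 1, self.width), -1, dtype=np.int32)
        for v in range(self.width):
            offsets = self._offsets[v]
            for i in range(1, imax + 1):
                table[i, v] = self._kstar(i, g, offsets)
        self._eager[g] = table
        self.built_groups.add(g)

    @property
    def entries_stored(self) -> int:
        if self.lazy:
            return len(self._lazy)
        return sum(t.shape[0] - 1 for t in self._eager.values()) * self.width

    # -- lookup -------------------------------------------------------------
    def lookup(self, i: int, g: int, v) -> int:
        """k*(i, g, v) in O(1) (eager) or memoized on first use (lazy)."""
        key = v.key if isinstance(v, DiffVector) else int(v)
        if self.lazy:
            self._check_complete(g)
            if not 1 <= i <= g * self.q:
                raise RTableError(f"row i={i} is not below Rgroup {g}")
            tag = (i, g, key)
            k = self._lazy.get(tag, -1)
            if k < 0:
                k = self._kstar(i, g, self._offsets[key])
                self._lazy[tag] = k
            return k
        if g not in self.built_groups:
            raise RTableError(f"R table group {g} has not been built yet")
        table = self._eager[g]
        if not 1 <= i < table.shape[0]:
            raise RTableError(f"row i={i} is not below Rgroup {g}")
        return int(table[i, key])


def build_rtable_group(S: ScoreMatrix | np.ndarray, g: int,
                       cfg: FourRussiansConfig, scheme: ScoringScheme,
                       columns_filled: int | None = None) -> RTable:
    """Standalone construction of one R-table group from a partial S matrix.

    Convenience wrapper over :meth:`RTable.build_group` for tests and
    inspection; the fold loop uses the method directly.  ``columns_filled``
    defaults to the last column of Cgroup g (assume exactly complete).
    """
    values = S.values if isinstance(S, ScoreMatrix) else S
    n = values.shape[0] - 2
    q = cfg.resolve_q(n, scheme.C)
    rt = RTable(values, n, q, scheme.C, lazy=False)
    rt.columns_filled = (
        columns_filled if columns_filled is not None else rt.cgroup_last_column(g)
    )
    rt.build_group(g)
    return rt


def kstar_lookup(R: RTable, i: int, g: int, v) -> int:
    """Retrieve the stored best split k*(i, g, v) from the R table."""
    return R.lookup(i, g, v)


@dataclass
class FoldStats:
    """Instrumentation counters from the pure-Python speedup engine."""

    lookups: int = 0
    direct_evals: int = 0
    max_direct_per_cell: int = 0
    encodes: int = 0
    groups_built: int = 0
    table_entries: int = 0
    q: int = 0
    cells: int = 0
    per_cell_direct: dict = field(default_factory=dict, repr=False)


def fold_four_russians(seq: RnaSequence, scheme: ScoringScheme,
                       cfg: FourRussiansConfig | None = None,
                       engine: str = "auto",
                       stats: FoldStats | None = None) -> ScoreMatrix:
    """Column-order folding DP with the Four-Russians rule-d speedup.

    Produces a score matrix identical cell-for-cell to ``fold_column`` /
    ``fold_diagonal`` — the speedup changes the work, never the answers.
    Per column j: (1) independent pass, rules a-b, i ascending; (2) dependent
    pass, i descending: rule c, then groups from the one holding k = j-1 down
    to the one holding k = i+1 — complete groups strictly inside (i, j) cost
    one lookup each, the at-most-two groups cut by i or j-1 are scanned
    directly; (3) v_g is encoded as soon as a group's lowest cell in column j
    is finalized; (4) after the last column of each Cgroup, that group's R
    entries are built (interleaved preprocessing).

    ``stats`` (Python engine only) collects lookup/scan counters; passing it,
    or requesting a lazy table, selects the Python engine.
    """
    cfg = cfg or FourRussiansConfig()
    n = seq.n
    C = scheme.C
    q = cfg.resolve_q(n, C)
    if engine not in ("auto", "python", "numba"):
        raise ValueError(f"unknown engine {engine!r}")
    want_python = engine == "python" or stats is not None or cfg.lazy
    if not want_python:
        from . import _kernels

        if _kernels.available():
            B = pair_score_matrix(seq, scheme)
            return ScoreMatrix(_kernels.fold_four_russians(B, n, q, C), n)
        if engine == "numba":
            raise RuntimeError("numba engine requested but numba is unavailable")

    if not cfg.lazy:
        nbytes = (n // q + 1) * (n + 1) * (C ** (q - 1)) * 4
        if nbytes > RTABLE_MEMORY_LIMIT:
            raise MemoryError(
                f"eager R table would need {nbytes / 2**30:.1f} GiB "
                f"(n={n}, q={q}, C={C}); reduce q or use lazy mode"
            )

    B = pair_score_matrix(seq, scheme)
    S = _new_table(n)
    rt = RTable(S, n, q, C, lazy=cfg.lazy)
    st = stats if stats is not None else FoldStats()
    st.q = q
    vkeys: dict[int, int] = {}

    for j in range(2, n + 1):
        for i in range(1, j):  # independent: rules a, b
            a = S[i + 1, j - 1] + B[i, j]
            b = S[i, j - 1]
            S[i, j] = a if a > b else b
        for i in range(j - 1, 0, -1):  # dependent: rules c, d
            best = max(S[i, j], S[i + 1, j])
            direct_here = 0
            if j - 1 >= i + 1:
                ghi = (j - 2) // q  # group of k = j-1
                glo = i // q        # group of k = i+1
                for g in range(ghi, glo - 1, -1):
                    lo, hi = g * q + 1, (g + 1) * q
                    klo, khi = max(lo, i + 1), min(hi, j - 1)
                    if klo == lo and khi == hi:
                        k = rt.lookup(i, g, vkeys[g])
                        st.lookups += 1
                        cand = S[i, k - 1] + S[k, j]
                        if cand > best:
                            best = cand
                    else:
                        for k in range(klo, khi + 1):
                            direct_here += 1
                            cand = S[i, k - 1] + S[k, j]
                            if cand > best:
                                best = cand
            S[i, j] = best
            st.cells += 1
            st.direct_evals += direct_here
            if direct_here > st.max_direct_per_cell:
                st.max_direct_per_cell = direct_here
            st.per_cell_direct[(i, j)] = direct_here
            if (i - 1) % q == 0:
                g = (i - 1) // q
                z = (g + 1) * q
                if z <= j - 1:  # group complete in this column: encode v_g
                    V = [int(S[z - t, j]) for t in range(q)]
                    vkeys[g] = encode_group(V, C).key
                    st.encodes += 1
        rt.columns_filled = j
        if (j + 1) % q == 0:  # Cgroup (j+1)/q - 1 just completed
            g = (j + 1) // q - 1
            if g >= 1 and (g + 1) * q <= n and not cfg.lazy:
                before = rt.entries_stored
                rt.build_group(g)
                st.groups_built += 1
                st.table_entries += rt.entries_stored - before
    if cfg.lazy:
        st.table_entries = rt.entries_stored
    return ScoreMatrix(S, n)
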