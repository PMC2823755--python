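# Methods

## Problem and model

The basic RNA-folding problem: for a sequence K of length n over {A, C, G, U}
and integer minimum separation d ≥ 1, find a matching M of site pairs that is

* **site-disjoint** — no site appears in two pairs;
* **non-crossing (nested)** — no i < i′ < j < j′ with (i, j), (i′, j′) ∈ M;
* **permitted** — each pair's residues have positive score under the scheme
  and j − i > d (strict; the default d = 1 forbids adjacent pairs only);

maximizing the total pair score. This is a combinatorial abstraction: it
maximizes (weighted) base-pair count, not thermodynamic stability. Stacking,
loop energies, pseudoknots, dangles and ambiguity codes are all out of scope.

Scoring schemes are maps from unordered residue pairs to non-negative
integers: the unit scheme (A·U = C·G = 1) solves maximum-cardinality
matching; `pairwise` gives constant per-pair-type scores and can enable G·U
wobble pairs (off by default); arbitrary pair-type scores can be read from a
file. Scores are restricted to non-negative integers because the speedup
encodes *differences* of adjacent column cells into a finite alphabet
{0, …, C−1}, C = max score + 1. Position-specific score matrices are not
supported: the DP consumes the scheme only through B(i, j).

## The dynamic program and its two orders

S(i, j) is the optimum over the inclusive site interval i..j, with S = 0 on
empty and inverted intervals (this convention makes rule a well-defined when
i + 1 > j − 1; cells with j − i ≤ d are identically 0). The bipartition rule
is written in the "column" form max_k S(i, k−1) + S(k, j) over i < k < j; the
textbook form S(i, k) + S(k+1, j) is the same family under a shift of k, and
`fold_diagonal` uses the textbook form internally while `fold_column` and the
speedup use the column form — the matrices agree cell for cell, which the
tests assert rather than assume.

Column order matters because it splits each column j into an *independent*
pass (rules a–b, reading only earlier columns) and a *dependent* pass (rules
c–d, descending i, reading already-final cells of column j below i). Only
this order leaves, at the moment cell (i, j) is computed, the entire suffix
of column j finalized — which is what the group encoding needs.

## The Four-Russians speedup

Fixed geometry (never re-aligned per column): Rgroup g = rows g·q+1 … (g+1)·q
with top row z = (g+1)·q; Cgroup g = columns g·q … (g+1)·q − 1 (Cgroup 0 is
columns 1 … q−1). Cgroup g's columns are exactly where S(i, k−1) lives for
k ∈ Rgroup g.

* **Encoding.** For a group complete in column j, V_g lists S(z, j) down to
  S(z−q+1, j). Interval monotonicity bounds each step: the consecutive
  differences lie in {0, …, C−1}. We store the non-negative orientation
  digits[t] = V[t+1] − V[t] (entry t ↔ row z − t); encode/decode/build/lookup
  all use this one orientation, so the choice is invisible to results. The
  packed key is the base-C integer of the digit string.
* **Decoding.** decode(v) is the prefix-sum vector V′ with V′[0] = 0, so
  decode(encode(V)) = V − V[0] exactly.
* **Fact 1.** The best split within a group maximizes S(i, k−1) + S(k, j);
  replacing the column values by V′ shifts every candidate by the same
  constant V_g[0], so the argmax — with the same smallest-k tie rule on both
  sides — is unchanged. Hence k\*(i, g, j) depends only on (i, g, v_g).
* **R table, interleaved.** Once Cgroup g is complete the table entries
  R(i, g, v) = argmax_k S(i, k−1) + V′[z−k] are computed for every row
  i ≤ g·q below the group and all C^(q−1) digit vectors. Entries for group 0
  are never stored: no row i ≥ 1 lies below it, so no lookup can reach them.
  Preprocessing and use are necessarily interleaved — group g's entries
  require Cgroup g's columns, which the DP itself fills.
* **Dependent pass.** For each (i, j), complete groups strictly inside
  (i, j) cost one lookup each; the at most two groups cut by i or by j−1 are
  scanned directly (≤ 2q split evaluations per cell — the instrumentation
  counters assert this). v_g for column j is encoded the moment the group's
  lowest cell is finalized, i.e. when the descending pass leaves row g·q+1.

**Choice of q.** q = ⌊log_{C+1} n⌋, clamped to [2, q_max] with q_max = 8,
computed by integer arithmetic (float logs misround at exact powers). The
log base must exceed C or the O(n² C^(q−1)) preprocessing term swallows the
savings; base C+1 is the smallest integer that satisfies this (base 3 for
unit scoring). The clamp exists because eager-table memory is
Θ(n² C^(q−1)/q), which grows super-quadratically at the asymptotic q; any
constant q preserves exactness — only the speedup factor changes — so
capping is safe. Degenerate sizes (n < 2q) simply have no complete groups
and fall through to direct scans, still cell-exact.

**Eager vs lazy table.** Eager (default) enumerates all C^(q−1) keys per
built group. Lazy memoizes only (i, g, key) triples actually queried — an
optimization flag, off by default, with an equivalence test between modes.
Both refuse to serve a group before its Cgroup completes (a sequencing-bug
guard, raising rather than returning stale data).

## Engines

Every solver has a pure-Python reference engine; `fold_diagonal`,
`fold_column` and `fold_four_russians` also have numba-jitted kernels used by
default when numba imports (pass `engine="python"` to force the reference).
The jit Four-Russians kernel stores R as a 2-D array indexed [i, g·width+v]
and keeps a contiguous copy of the current column, purely for cache locality;
its group bounds, tie rules and interleaving are the same as the Python
engine's, and tests assert cell-exact equality between engines and with both
cubic solvers. Instrumentation (lookup/direct-scan/table counters) lives in
the Python engine, which requesting `stats` selects automatically.

## Oracle and traceback

`brute_force_score` enumerates every nested permitted matching by recursion
("site i unmatched, or matched to each feasible partner"), shares no code or
tables with the DP solvers, and is capped at n = 16.

`traceback` recovers an optimal matching by recomputing, per cell, which rule
attains the stored value — tried in the fixed order a, b, c, d (smallest
split k within d) so output is deterministic; any optimum would be valid.
Recomputation is O(n²) worst case versus O(n) with stored pointers, but it is
memory-free and negligible beside the O(n³/log n) fill, which is why it was
preferred. A complementary pair whose scheme score is 0 is never emitted
(it cannot change any cell) and is rejected by `validate_matching`; schemes
with *all* scores 0 are rejected at construction. An inconsistent matrix (no
rule attains a cell) raises rather than silently producing a structure.

## Random sequences and what the tests show

`random_rna` draws residues i.i.d. uniform over the four letters,
deterministically in (n, seed). Uniform composition is a modeling choice for
fixtures and benchmarks — real RNAs have skewed composition and correlated
structure — but every correctness claim here (solver equivalence, oracle
agreement, traceback validity) is *exact and per-instance*, not statistical,
so passing on random inputs plus hand-built edge cases is evidence about the
algorithms, not about biology. Benchmark runtime is sequence-independent
(the DP does identical work for any input of a given n).

## Problem sizes used in the checks

The equivalence sweep uses 200 instances spanning n = 1…300 with
q ∈ {2,3,4,5}, d ∈ {1,2,3} and both the unit (C = 2) and AU=2/CG=3 (C = 4)
schemes; oracle agreement uses 500 instances with n ≤ 14; work accounting is
instrumented at n = 500; timing ratios are measured at n = 1000–4000 with
best-of-2 repetitions after a jit warmup. Timing numbers are
hardware-dependent and reported as indicative only; they gate nothing.

## Known limitations

* No energy model, pseudoknots, suboptimal enumeration, or partition
  function; scores must be non-negative integers with n-independent maximum.
* The reported speedup ratio at small n (~1000) can dip near 1 on machines
  where the cubic inner loop vectorizes well; the ratio grows with n as the
  theory predicts.
* CT output is the common 6-column dialect only; foreign CT dialects are not
  parsed.
* The O(n²) parallel/vectorized variant of the dependent pass is not
  implemented.
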