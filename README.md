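# rufold

Exact solvers for the **basic RNA-folding problem**: given an RNA sequence
*K* of length *n* over {A, C, G, U}, find a maximum-score *non-crossing*
matching of complementary sites (A·U, C·G, optionally G·U), where every match
(i, j) must satisfy j − i > d for a minimum separation d (default 1). This
maximum-base-pairing problem sits in the inner loop of many richer
secondary-structure methods and is routinely solved for long viral RNA
genomes, so its cubic cost matters.

`rufold` provides three interchangeable exact solvers plus an exponential
brute-force oracle, with machine-checkable cell-by-cell agreement:

| solver | order of evaluation | time |
|---|---|---|
| `fold_diagonal` | increasing interval length (the textbook order) | O(n³) |
| `fold_column` | column-major (independent pass then dependent pass) | O(n³) |
| `fold_four_russians` | column-major with grouped rule-d lookups | **O(n³ / log n)** |

All three fill the same table

```
S(i, j) = max( S(i+1, j-1) + B(i, j),              # pair (i, j)
               S(i, j-1),                           # j unmatched
               S(i+1, j),                           # i unmatched
               max_{i < k < j} S(i, k-1) + S(k, j) )  # bipartition
```

where B(i, j) is the pair score (0 unless the residues are complementary and
j − i > d). The Four-Russians variant groups the rows of each column into
blocks of q: within one column, consecutive cells differ by at most the
maximum pair score, so a block's q values are captured — up to an additive
constant that can never change an argmax — by q−1 bounded digits. A table
R(i, g, v) of best split points per (row, block, digit vector) is precomputed
*interleaved* with the DP and turns the rule-d scan over a complete block
into one O(1) lookup. With q = ⌊log₍C+1₎ n⌋ (C−1 = maximum pair score) the
total time is O(n³/log n), and the answers are identical cell for cell.

Hot loops are jit-compiled with numba when available; every solver also has a
pure-Python engine (the instrumented reference), and the test suite asserts
engine equality.

## Worked example

```
$ rufold fold GGGAAACCC GAAAUC
>arg1 score=3
GGGAAACCC
(((...)))
>arg2 score=2
GAAAUC
((..))
```

`score=3` is S(1, 9): three nested pairs (1,9), (2,8), (3,7) — a hairpin, as
the dot-bracket line shows ('(' opens a pair at the 5′ site, ')' closes it at
the 3′ partner, '.' is unpaired). For `GAAAUC` the optimum is (1,6) G·C and
(2,5) A·U. Richer constant scores per pair type change the optimum's value:

```
$ rufold fold GAAAUC --scheme pairwise --au 2 --cg 3
>arg1 score=5
GAAAUC
((..))
```

CT-format output (`--format ct`), minimum separation (`--d`), fixed group
size (`--q`), and pair-score files (`--scheme file --scores FILE`) are
supported; `rufold gen` writes reproducible random FASTA fixtures, and
`rufold bench` emits an indicative timing CSV (cubic vs Four-Russians).

The exactness harness, which exits non-zero and prints the reproducing
(seed, n, q, scheme) tuple on any disagreement:

```
$ rufold compare --sizes 10,40 --reps 3 --seed 7 --q-list 2,3
compare: 30 checks, 0 failures (sizes=10,40, reps=3, seed=7)
```

Library use mirrors the CLI:

```python
from rufold import random_rna, unit_scheme, fold_four_russians, FoldStats

seq = random_rna(300, seed=7)
stats = FoldStats()
S = fold_four_russians(seq, unit_scheme(), stats=stats)
print(stats.q, S.score, stats.lookups, stats.max_direct_per_cell)
# 5 120 855500 8
```

855,500 rule-d group lookups replace ~4.4M direct split evaluations, and no
cell ever scans more than 2q = 10 split points directly (the two partial
blocks at the interval ends).

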