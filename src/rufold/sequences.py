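"""Sequence handling and scoring schemes for the basic RNA-folding problem.

The folding problem takes a nucleotide string over {A, C, G, U} and asks for a
maximum-score set of non-crossing matches between complementary sites.  This
module provides the validated sequence container, FASTA input, a seeded random
sequence generator for benchmarks and tests, and the integer pair-scoring
schemes the dynamic programs consume through :func:`pair_score`.

Positions are 1-based throughout, matching the standard presentation of the
folding recurrences.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

ALPHABET = frozenset("ACGU")

#: Watson-Crick complementary pairs; G.U wobble is opt-in via pairwise/file schemes.
_CANONICAL = (("A", "U"), ("C", "G"))
_WOBBLE = ("G", "U")


class SequenceError(ValueError):
    """Raised for malformed FASTA input or illegal residues."""


@dataclass(frozen=True)
class RnaSequence:
    """A validated RNA sequence.

    Residues are normalized on construction: lowercase is uppercased and
    ``T`` becomes ``U``.  Any other character is rejected with its 1-based
    position.  Site ``i`` (1 <= i <= n) refers to the i-th residue.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        norm = self.residues.upper().replace("T", "U")
        for pos, ch in enumerate(norm, start=1):
            if ch not in ALPHABET:
                raise SequenceError(
                    f"illegal character {ch!r} at position {pos} in sequence "
                    f"{self.id!r} (alphabet is A, C, G, U; T is accepted and "
                    f"normalized to U)"
                )
        object.__setattr__(self, "residues", norm)

    @property
    def n(self) -> int:
        return len(self.residues)

    def site(self, i: int) -> str:
        """Residue at 1-based site ``i``."""
        if not 1 <= i <= self.n:
            raise IndexError(f"site {i} out of range 1..{self.n}")
        return self.residues[i - 1]

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n


def read_fasta(path) -> list[RnaSequence]:
    """Read all records of a FASTA file as :class:`RnaSequence`.

    Raises :class:`SequenceError` if the file is not FASTA-formatted (the
    offending line is named) or if any record contains a non-nucleotide
    character (position and character are named).
    """
    with open(path) as fh:
        text = fh.read()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise SequenceError(
                    f"{path}: line {lineno}: expected FASTA header starting "
                    f"with '>', got {line[:30]!r}"
                )
            break
    else:
        raise SequenceError(f"{path}: empty file, no FASTA records")
    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        records.append(RnaSequence(id=rec.id, residues=str(rec.seq)))
    if not records:
        raise SequenceError(f"{path}: no FASTA records found")
    return records


def write_fasta(seqs, path, width: int = 70) -> None:
    """Write sequences to ``path`` in wrapped FASTA."""
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for off in range(0, s.n, width):
                fh.write(s.residues[off : off + width] + "\n")


def random_rna(n: int, seed: int, id: str | None = None) -> RnaSequence:
    """An i.i.d. uniform random sequence over {A,C,G,U}; deterministic in (n, seed)."""
    if n < 1:
        raise ValueError(f"sequence length must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    letters = np.array(list("ACGU"))
    residues = "".join(letters[rng.integers(0, 4, size=n)])
    return RnaSequence(id=id or f"random_n{n}_seed{seed}", residues=residues)


def _canon(x: str, y: str) -> tuple[str, str]:
    return (x, y) if x <= y else (y, x)


@dataclass(frozen=True)
class ScoringScheme:
    """Integer pair scores B plus the minimum-separation constraint.

    ``pair_scores`` maps unordered residue pairs to non-negative integers; a
    pair absent from the map scores 0.  A match (i, j) is *permitted* when its
    residues have positive score and ``j - i > d``.  ``C`` is the size of the
    difference alphabet the Four-Russians encoding uses: consecutive column
    cells of the score matrix can differ by at most the maximum pair score, so
    C = max score + 1.
    """

    pair_scores: dict = field(default_factory=dict)
    d: int = 1

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError(f"minimum separation d must be >= 1, got {self.d}")
        canon = {}
        for (x, y), s in self.pair_scores.items():
            if x not in ALPHABET or y not in ALPHABET:
                raise ValueError(f"unknown residue pair {x}{y}")
            if not isinstance(s, (int, np.integer)) or isinstance(s, bool):
                raise ValueError(f"score for {x}{y} must be an integer, got {s!r}")
            if s < 0:
                raise ValueError(f"score for {x}{y} must be >= 0, got {s}")
            canon[_canon(x, y)] = int(s)
        if not any(s > 0 for s in canon.values()):
            raise ValueError("scoring scheme has no pair with positive score")
        object.__setattr__(self, "pair_scores", canon)

    @property
    def max_score(self) -> int:
        return max(self.pair_scores.values())

    @property
    def C(self) -> int:
        """Difference-alphabet size: column marginals lie in {0, ..., C-1}."""
        return self.max_score + 1

    def score(self, x: str, y: str) -> int:
        """Score of the unordered residue pair (x, y); 0 if unscored."""
        return self.pair_scores.get(_canon(x, y), 0)


def pair_score(scheme: ScoringScheme, seq: RnaSequence, i: int, j: int) -> int:
    """B(i, j): the score of matching sites i and j, or 0 if not permitted.

    A match is permitted when the residues form a scored pair and j - i > d.
    This is the only form in which the dynamic programs consume the scheme.
    """
    if not (1 <= i < j <= seq.n):
        raise IndexError(f"need 1 <= i < j <= n, got i={i}, j={j}, n={seq.n}")
    if j - i <= scheme.d:
        return 0
    return scheme.score(seq.site(i), seq.site(j))


def pair_score_matrix(seq: RnaSequence, scheme: ScoringScheme) -> np.ndarray:
    """Dense (n+2) x (n+2) int32 matrix of B(i, j) for the solver kernels.

    Index [i, j] is 1-based; row 0, column 0 and the extra trailing row/column
    are padding so the recurrences can read S(i+1, j-1) without bounds checks.
    """
    n = seq.n
    B = np.zeros((n + 2, n + 2), dtype=np.int32)
    codes = np.frombuffer(seq.residues.encode(), dtype=np.uint8)
    lut = np.zeros((256, 256), dtype=np.int32)
    for (x, y), s in scheme.pair_scores.items():
        lut[ord(x), ord(y)] = s
        lut[ord(y), ord(x)] = s
    if n >= 1:
        B[1 : n + 1, 1 : n + 1] = lut[codes[:, None], codes[None, :]]
        iu, ju = np.indices((n, n))
        B[1 : n + 1, 1 : n + 1][ju - iu <= scheme.d] = 0
    return B


def unit_scheme(d: int = 1) -> ScoringScheme:
    """Score 1 for A.U and C.G, 0 otherwise (maximum-cardinality matching); C = 2."""
    return ScoringScheme({p: 1 for p in _CANONICAL}, d=d)


def pairwise_scheme(au: int, cg: int, gu: int = 0, d: int = 1) -> ScoringScheme:
    """Constant per-pair-type scores; C = max(au, cg, gu) + 1."""
    scores = {("A", "U"): au, ("C", "G"): cg}
    if gu:
        scores[_WOBBLE] = gu
    return ScoringScheme(scores, d=d)


def scheme_from_file(path, d: int = 1) -> ScoringScheme:
    """Read a pair-score file: one ``<XY> <integer>`` per line, '#' comments."""
    scores = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2 or len(parts[0]) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected '<XY> <integer>', got {raw!r}"
                )
            pair, val = parts[0].upper().replace("T", "U"), parts[1]
            try:
                s = int(val)
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: score {val!r} is not an integer"
                ) from None
            scores[(pair[0], pair[1])] = s
    return ScoringScheme(scores, d=d)


def make_scheme(kind: str, *, au: int = 1, cg: int = 1, gu: int = 0,
                path=None, d: int = 1) -> ScoringScheme:
    """Dispatch to one of the scheme constructors by name."""
    if kind == "unit":
        return unit_scheme(d=d)
    if kind == "pairwise":
        return pairwise_scheme(au=au, cg=cg, gu=gu, d=d)
    if kind == "file":
        if path is None:
            raise ValueError("kind='file' requires a pair-score file path")
        return scheme_from_file(path, d=d)
    raise ValueError(f"unknown scheme kind {kind!r}; expected unit, pairwise or file")
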