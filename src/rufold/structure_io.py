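"""Validation and serialization of predicted secondary structures.

A predicted structure is a :class:`~rufold.nussinov.Matching`: site-disjoint,
non-crossing, permitted pairs.  Output formats are dot-bracket strings (nested
matchings are exactly those expressible without pseudoknot brackets) and the
common 6-column CT (connectivity table) dialect emitted by widely used folding
tools.
"""

from __future__ import annotations

from .nussinov import Matching
from .sequences import RnaSequence, ScoringScheme, pair_score


class CrossingError(ValueError):
    """The matching contains crossing pairs and cannot be serialized nested."""


def validate_matching(m: Matching, seq: RnaSequence, scheme: ScoringScheme) -> list[str]:
    """Check a matching against the problem's constraints.

    Returns a list of human-readable violations (empty means valid):
    site-disjointness, non-crossing, residue complementarity under the scheme
    (positive pair score), and minimum separation j - i > d.  Out-of-range
    sites raise immediately rather than being reported.
    """
    n = seq.n
    for i, j in m.pairs:
        if not (1 <= i < j <= n):
            raise IndexError(f"pair ({i},{j}) out of range for n={n}")
    violations = []
    seen: dict[int, tuple] = {}
    for pair in sorted(m.pairs):
        for site in pair:
            if site in seen:
                violations.append(
                    f"site {site} in two pairs: {seen[site]} and {pair}"
                )
            seen[site] = pair
    pairs = sorted(m.pairs)
    for a in range(len(pairs)):
        i, j = pairs[a]
        for b in range(a + 1, len(pairs)):
            ip, jp = pairs[b]
            if i < ip < j < jp:
                violations.append(f"crossing pairs ({i},{j}) and ({ip},{jp})")
    for i, j in pairs:
        if j - i <= scheme.d:
            violations.append(
                f"pair ({i},{j}) violates minimum separation: j-i={j - i} <= d={scheme.d}"
            )
        elif pair_score(scheme, seq, i, j) == 0:
            violations.append(
                f"pair ({i},{j}) = {seq.site(i)}.{seq.site(j)} is not a scored pair"
            )
    return violations


def to_dot_bracket(m: Matching, n: int) -> str:
    """Dot-bracket string: '(' at the 5' site of each pair, ')' at the 3' site."""
    chars = ["."] * n
    pairs = sorted(m.pairs)
    for a in range(len(pairs)):
        i, j = pairs[a]
        for b in range(a + 1, len(pairs)):
            ip, jp = pairs[b]
            if i < ip < j < jp:
                raise CrossingError(
                    f"pairs ({i},{j}) and ({ip},{jp}) cross; "
                    "dot-bracket requires a nested matching"
                )
    for i, j in pairs:
        if not (1 <= i < j <= n):
            raise IndexError(f"pair ({i},{j}) out of range for n={n}")
        chars[i - 1] = "("
        chars[j - 1] = ")"
    return "".join(chars)


def write_ct(seq: RnaSequence, m: Matching, path) -> None:
    """Write the standard 6-column CT file: header ``<n> <id>``, then per
    residue: index, base, index-1, index+1, partner (0 if unpaired), index."""
    partner = [0] * (seq.n + 1)
    for i, j in m.pairs:
        partner[i] = j
        partner[j] = i
    with open(path, "w") as fh:
        fh.write(f"{seq.n} {seq.id}\n")
        for i in range(1, seq.n + 1):
            nxt = i + 1 if i < seq.n else 0
            fh.write(f"{i} {seq.site(i)} {i - 1} {nxt} {partner[i]} {i}\n")


def read_ct(path) -> tuple[RnaSequence, Matching]:
    """Parse a CT file written by :func:`write_ct` (round-trip inverse)."""
    with open(path) as fh:
        header = fh.readline().split(None, 1)
        n = int(header[0])
        sid = header[1].strip() if len(header) > 1 else "ct"
        residues = []
        pairs = set()
        for _ in range(n):
            cols = fh.readline().split()
            idx, base, partner = int(cols[0]), cols[1], int(cols[4])
            residues.append(base)
            if partner and idx < partner:
                pairs.add((idx, partner))
    return RnaSequence(id=sid, residues="".join(residues)), Matching(pairs)
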