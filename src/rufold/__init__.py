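"""rufold: exact RNA folding (maximum-score non-crossing matching) with an
O(n^3 / log n) Four-Russians speedup, interchangeable exact solvers, a
brute-force oracle, traceback, and dot-bracket / CT output."""

from .four_russians import (
    DiffVector,
    FoldStats,
    FourRussiansConfig,
    RTable,
    build_rtable_group,
    choose_q,
    decode_vector,
    encode_group,
    fold_four_russians,
    kstar_lookup,
)
from .nussinov import (
    Matching,
    ScoreMatrix,
    TracebackError,
    brute_force_score,
    fold_column,
    fold_diagonal,
    traceback,
)
from .sequences import (
    RnaSequence,
    ScoringScheme,
    SequenceError,
    make_scheme,
    pair_score,
    pairwise_scheme,
    random_rna,
    read_fasta,
    scheme_from_file,
    unit_scheme,
    write_fasta,
)
from .structure_io import read_ct, to_dot_bracket, validate_matching, write_ct

__version__ = "0.1.0"

_SOLVERS = {
    "diagonal": fold_diagonal,
    "column": fold_column,
    "four-russians": fold_four_russians,
}


def fold(seq, scheme=None, algorithm: str = "four-russians", **kwargs):
    """One-call folding: returns (score_matrix, matching)."""
    scheme = scheme or unit_scheme()
    if algorithm not in _SOLVERS:
        raise ValueError(
            f"unknown algorithm {algorithm!r}; choose from {sorted(_SOLVERS)}"
        )
    S = _SOLVERS[algorithm](seq, scheme, **kwargs)
    return S, traceback(S, seq, scheme)

__all__ = [name for name in dir() if not name.startswith("_")]
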