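import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rufold import (
    DiffVector,
    FoldStats,
    FourRussiansConfig,
    RnaSequence,
    build_rtable_group,
    choose_q,
    decode_vector,
    encode_group,
    fold_column,
    fold_four_russians,
    kstar_lookup,
    random_rna,
    unit_scheme,
)
from rufold.four_russians import RTable, RTableError
from rufold.sequences import pairwise_scheme

from conftest import make_schemes


class TestChooseQ:
    def test_unit_scheme_uses_base_three(self):
        assert choose_q(27, C=2) == 3  # floor(log3 27)

    def test_clamped_up_to_minimum_group_size(self):
        assert choose_q(8, C=2) == 2  # floor(log3 8) = 1 -> 2

    def test_clamped_to_q_max(self):
        assert choose_q(10**6, C=2, q_max=8) == 8  # floor(log3 1e6) = 12

    def test_base_exceeds_difference_alphabet(self):
        # C=4: base 5, floor(log5 625) = 4
        assert choose_q(625, C=4) == 4
        assert choose_q(624, C=4) == 3

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            choose_q(1, C=2)
        with pytest.raises(ValueError):
            choose_q(100, C=1)


class TestEncodeDecode:
    def test_encode_example(self):
        assert encode_group([2, 2, 3], C=2).digits == (0, 1)

    def test_constant_vector_encodes_to_zeros(self):
        assert encode_group([5, 5, 5], C=7).digits == (0, 0)

    def test_difference_outside_alphabet_rejected(self):
        with pytest.raises(ValueError, match="bounded-marginal"):
            encode_group([1, 3], C=2)
        with pytest.raises(ValueError):
            encode_group([3, 1], C=2)  # negative difference

    def test_decode_is_prefix_sums(self):
        v = DiffVector(q=3, C=2, digits=(0, 1))
        assert decode_vector(v) == [0, 0, 1]
        z = DiffVector(q=5, C=2, digits=(0, 0, 0, 0))
        assert decode_vector(z) == [0] * 5

    def test_key_pack_unpack_roundtrip(self):
        for C in (2, 4):
            for key in range(C ** 3):
                v = DiffVector.from_key(key, q=4, C=C)
                assert v.key == key

    @given(st.data())
    @settings(derandomize=True, max_examples=300)
    def test_decode_encode_roundtrip(self, data):
        C = data.draw(st.sampled_from([2, 3, 4]))
        q = data.draw(st.integers(2, 6))
        base = data.draw(st.integers(0, 50))
        digits = data.draw(st.lists(st.integers(0, C - 1), min_size=q - 1,
                                    max_size=q - 1))
        V = [base]
        for dgt in digits:
            V.append(V[-1] + dgt)
        v = encode_group(V, C)
        assert [x + V[0] for x in decode_vector(v)] == V
        assert DiffVector.from_key(v.key, q, C) == v


def _filled_matrix(seq, scheme):
    return fold_column(seq, scheme, engine="python")


class TestRTable:
    def test_build_matches_direct_scan(self, any_scheme):
        """Stored k* equals the argmax found by scanning every k in the group."""
        q, C = 3, any_scheme.C
        seq = random_rna(30, seed=11)
        S = _filled_matrix(seq, any_scheme)
        cfg = FourRussiansConfig(q=q)
        for g in (1, 2, 3):
            rt = build_rtable_group(S, g, cfg, any_scheme, columns_filled=seq.n)
            z = (g + 1) * q
            for key in range(C ** (q - 1)):
                v = DiffVector.from_key(key, q, C)
                off = decode_vector(v)
                for i in range(1, g * q + 1):
                    best, bestk = -1, -1
                    for k in range(g * q + 1, (g + 1) * q + 1):
                        val = S[i, k - 1] + off[z - k]
                        if val > best:
                            best, bestk = val, k
                    assert kstar_lookup(rt, i, g, v) == bestk

    def test_tie_broken_to_smallest_k(self, unit):
        # q=2, group 1 is rows {3,4}; flat offsets make both candidates equal
        # whenever S(i,2) == S(i,3).
        seq = RnaSequence("s", "AAAAAA")  # all-zero S: guaranteed tie
        S = _filled_matrix(seq, unit)
        rt = build_rtable_group(S, 1, FourRussiansConfig(q=2), unit,
                                columns_filled=6)
        flat = DiffVector(q=2, C=2, digits=(0,))
        assert kstar_lookup(rt, 1, 1, flat) == 3

    def test_offset_position_carries_the_bonus(self, unit):
        # With S(i,2) == S(i,3), offsets [0,1] must steer k* to the row
        # holding the +1: position t maps to row z - t, so digit (1,) puts
        # the bonus on k = 3.
        seq = RnaSequence("s", "AAAAAA")
        S = _filled_matrix(seq, unit)
        rt = build_rtable_group(S, 1, FourRussiansConfig(q=2), unit,
                                columns_filled=6)
        rising = DiffVector(q=2, C=2, digits=(1,))
        assert kstar_lookup(rt, 1, 1, rising) == 3
        # and the flat vector ties to the smaller k as well
        assert decode_vector(rising) == [0, 1]

    def test_build_before_cgroup_complete_raises(self, unit):
        seq = random_rna(20, seed=5)
        S = _filled_matrix(seq, unit)
        with pytest.raises(RTableError, match="incomplete"):
            build_rtable_group(S, 2, FourRussiansConfig(q=3), unit,
                               columns_filled=5)  # Cgroup 2 needs column 11

    def test_lookup_of_unbuilt_group_raises(self, unit):
        rt = RTable(np.zeros((22, 22), dtype=np.int32), 20, 3, 2)
        with pytest.raises(RTableError):
            rt.lookup(1, 1, 0)

    def test_eager_width_accounting(self, any_scheme):
        """Exactly C^(q-1) keys are stored per (group, row) slot built."""
        q, C = 3, any_scheme.C
        seq = random_rna(30, seed=13)
        S = _filled_matrix(seq, any_scheme)
        rt = build_rtable_group(S, 2, FourRussiansConfig(q=q), any_scheme,
                                columns_filled=30)
        assert rt.entries_stored == 2 * q * C ** (q - 1)


class TestFact1:
    def test_argmax_invariant_under_additive_shift(self):
        """argmax_k S(i,k-1) + V_g[k] == argmax with decode(encode(V_g)):
        additive constants never move an argmax (same tie rule both sides)."""
        rng = np.random.default_rng(42)
        for _ in range(300):
            q = int(rng.integers(2, 7))
            C = int(rng.choice([2, 4]))
            head = rng.integers(0, 20, size=q)  # S(i, k-1) values
            base = int(rng.integers(0, 30))
            digits = rng.integers(0, C, size=q - 1)
            V = [base]
            for dgt in digits:
                V.append(V[-1] + int(dgt))
            Vp = decode_vector(encode_group(V, C))
            # V and Vp are indexed by position t (row z - t)
            a = max(range(q), key=lambda t: (head[t] + V[t], -t))
            b = max(range(q), key=lambda t: (head[t] + Vp[t], -t))
            assert a == b


class TestFoldFourRussians:
    def test_small_example(self, unit):
        seq = RnaSequence("s", "GAAAUC")
        S = fold_four_russians(seq, unit, FourRussiansConfig(q=2))
        assert S.score == 2
        assert S.equals(fold_column(seq, unit))

    @pytest.mark.parametrize("q", [2, 3, 4, 5])
    def test_cell_exact_equality_with_column_order(self, q):
        """The speedup must be semantically invisible at every cell."""
        for trial in range(12):
            n = 1 + (trial * 23) % 150
            for scheme in make_schemes(d=1 + trial % 3):
                seq = random_rna(n, seed=trial * 31 + q)
                ref = fold_column(seq, scheme)
                got = fold_four_russians(seq, scheme, FourRussiansConfig(q=q),
                                         engine="python")
                assert got.equals(ref), (trial, n, q, scheme.d)

    def test_degenerate_sizes_fall_back_gracefully(self, unit):
        for n, q in [(1, 2), (2, 4), (3, 4), (5, 8), (7, 8)]:
            seq = random_rna(n, seed=n) if n > 0 else RnaSequence("s", "")
            cfg = FourRussiansConfig(q=q)
            assert fold_four_russians(seq, unit, cfg).equals(
                fold_column(seq, unit)
            )

    def test_default_q_comes_from_choose_q(self, unit):
        seq = random_rna(100, seed=2)
        st_ = FoldStats()
        fold_four_russians(seq, unit, stats=st_)
        assert st_.q == choose_q(100, C=2)

    def test_lazy_table_equals_eager(self, any_scheme):
        for trial in range(8):
            seq = random_rna(10 + trial * 17, seed=trial)
            eager = fold_four_russians(seq, any_scheme,
                                       FourRussiansConfig(q=3, lazy=False),
                                       engine="python")
            lazy = fold_four_russians(seq, any_scheme,
                                      FourRussiansConfig(q=3, lazy=True))
            assert lazy.equals(eager)

    def test_jit_engine_equals_python_engine(self, any_scheme):
        for q in (2, 3, 5):
            seq = random_rna(130, seed=q)
            cfg = FourRussiansConfig(q=q)
            assert fold_four_russians(seq, any_scheme, cfg, engine="numba").equals(
                fold_four_russians(seq, any_scheme, cfg, engine="python")
            )

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            FourRussiansConfig(q=1)
        with pytest.raises(ValueError):
            FourRussiansConfig(q=9, q_max=8)


class TestWorkAccounting:
    def test_direct_evaluations_bounded_by_two_partial_groups(self, unit):
        """Outside lookups, each (i,j) scans at most the two boundary groups:
        <= 2q direct k-evaluations per cell."""
        q = 3
        seq = random_rna(120, seed=21)
        st_ = FoldStats()
        fold_four_russians(seq, unit, FourRussiansConfig(q=q), stats=st_)
        assert st_.max_direct_per_cell <= 2 * q
        assert all(v <= 2 * q for v in st_.per_cell_direct.values())

    def test_lookups_per_cell_scale_as_groups_inside(self, unit):
        q = 4
        n = 120
        st_ = FoldStats()
        fold_four_russians(seq := random_rna(n, seed=8), unit,
                           FourRussiansConfig(q=q), stats=st_)
        # every cell issues at most ceil((j - i)/q) lookups
        assert st_.lookups <= sum(
            (j - i) // q + 1 for i in range(1, n) for j in range(i + 1, n + 1)
        )
        assert st_.lookups > 0

    def test_eager_table_entry_accounting(self, any_scheme):
        q, n = 3, 60
        st_ = FoldStats()
        fold_four_russians(random_rna(n, seed=3), any_scheme,
                           FourRussiansConfig(q=q), stats=st_)
        C = any_scheme.C
        expected = sum(
            g * q * C ** (q - 1)
            for g in range(1, n // q + 1)
            if (g + 1) * q <= n and (g + 1) * q - 1 <= n - 1
        )
        assert st_.table_entries == expected
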