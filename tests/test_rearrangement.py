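import itertools

import numpy as np
import pytest

from ogphylo.og_identify import OGPair
from ogphylo.orthology import OrthologousOGPairMatch, OrthologousOGPairSet
from ogphylo.rearrangement import (
    SignedGenomeOrder,
    apply_block_interchange,
    apply_fission,
    apply_fusion,
    apply_reversal,
    apply_translocation,
    adjacency_graph_dot,
    brute_force_distance,
    build_signed_orders,
    weighted_rearrangement_distance,
)

from conftest import random_signed_order

S = SignedGenomeOrder


def d(a, b):
    return weighted_rearrangement_distance(a, b).distance


class TestOperations:
    def test_reversal_flips_segment(self):
        assert apply_reversal(S([[1, 2, 3]]), 0, 2, 3).chromosomes == ((1, -3, -2),)

    def test_block_interchange_swaps_segments(self):
        out = apply_block_interchange(S([[1, 2, 3]]), 0, (1, 1), (3, 3))
        assert out.chromosomes == ((3, 2, 1),)

    def test_fission(self):
        out = apply_fission(S([[1, 2]]), 0, 1)
        assert sorted(out.chromosomes) == [(1,), (2,)]

    def test_fusion(self):
        out = apply_fusion(S([[1], [2]]), 0, 1)
        assert out.chromosomes == ((1, 2),)

    def test_translocation_exchanges_suffixes(self):
        out = apply_translocation(S([[1, 2], [3, 4]]), 0, 1, 1, 1)
        assert sorted(out.chromosomes) == [(1, 4), (3, 2)]

    def test_invalid_indices_error(self):
        with pytest.raises(IndexError):
            apply_reversal(S([[1, 2]]), 0, 0, 1)
        with pytest.raises(IndexError):
            apply_block_interchange(S([[1, 2, 3]]), 0, (1, 2), (2, 3))
        with pytest.raises(IndexError):
            apply_fission(S([[1, 2]]), 0, 2)


class TestDistanceExamples:
    def test_single_reversal(self):
        assert d(S([[1, 2, 3]]), S([[1, -2, 3]])) == 1

    def test_swap_adjacent_is_two(self):
        # [DERIVED] by the BFS oracle
        assert d(S([[1, 2, 3]]), S([[2, 1, 3]])) == 2
        assert brute_force_distance(S([[1, 2, 3]]), S([[2, 1, 3]])) == 2

    def test_fusion_is_one(self):
        assert d(S([[1], [2]]), S([[1, 2]])) == 1

    def test_block_interchange_is_two(self):
        # [DERIVED] by the BFS oracle
        assert d(S([[1, 2, 3, 4]]), S([[1, 3, 2, 4]])) == 2
        assert brute_force_distance(S([[1, 2, 3, 4]]), S([[1, 3, 2, 4]])) == 2

    def test_identity_zero(self):
        assert d(S([[1, 2, 3]]), S([[1, 2, 3]])) == 0
        assert brute_force_distance(S([[1, 2, 3]]), S([[1, 2, 3]])) == 0

    def test_whole_chromosome_flip_is_identity(self):
        # a chromosome is unoriented: its flip is the same genome
        assert d(S([[1, 2, 3]]), S([[-3, -2, -1]])) == 0
        assert brute_force_distance(S([[1, 2, 3]]), S([[-3, -2, -1]])) == 0

    def test_element_mismatch_errors(self):
        with pytest.raises(ValueError):
            weighted_rearrangement_distance(S([[1, 2]]), S([[1, 3]]))
        with pytest.raises(ValueError):
            brute_force_distance(S([[1, 2]]), S([[1, 3]]))

    def test_result_fields(self):
        res = weighted_rearrangement_distance(S([[1, 2, 3]]), S([[2, 1, 3]]))
        assert res.n == 3
        assert res.distance == res.n - res.cycles - res.odd_paths // 2
        assert res.odd_paths % 2 == 0


class TestOracleEquivalence:
    def test_exhaustive_n3_one_chromosome(self):
        ident = S([[1, 2, 3]])
        for perm in itertools.permutations([1, 2, 3]):
            for signs in itertools.product([1, -1], repeat=3):
                g = S([[p * s for p, s in zip(perm, signs)]])
                assert d(ident, g) == brute_force_distance(ident, g), g.chromosomes

    def test_exhaustive_n3_two_chromosomes(self):
        ident = S([[1, 2, 3]])
        for perm in itertools.permutations([1, 2, 3]):
            for signs in itertools.product([1, -1], repeat=3):
                seq = [p * s for p, s in zip(perm, signs)]
                for cut in (1, 2):
                    g = S([seq[:cut], seq[cut:]])
                    assert d(ident, g) == brute_force_distance(ident, g)

    def test_sampled_n4(self, rng):
        ident = S([[1, 2, 3, 4]])
        for _ in range(25):
            g = random_signed_order(rng, 4, max_chromosomes=2)
            assert d(ident, g) == brute_force_distance(ident, g), g.chromosomes


class TestProperties:
    def test_bound_r_le_n(self, rng):
        for _ in range(300):
            n = int(rng.integers(1, 25))
            a = random_signed_order(rng, n, max_chromosomes=3)
            b = random_signed_order(rng, n, max_chromosomes=3)
            assert 0 <= d(a, b) <= n

    def test_symmetry_and_identity(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 15))
            a = random_signed_order(rng, n)
            b = random_signed_order(rng, n)
            assert d(a, b) == d(b, a)
            assert d(a, a) == 0

    def test_triangle_inequality(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 12))
            a, b, c = (random_signed_order(rng, n) for _ in range(3))
            assert d(a, c) <= d(a, b) + d(b, c)

    def test_breakpoint_bound(self, rng):
        # d <= number of breakpoints (adjacencies of A absent from B)
        for _ in range(100):
            n = int(rng.integers(2, 15))
            a = random_signed_order(rng, n, max_chromosomes=1)
            b = random_signed_order(rng, n, max_chromosomes=1)

            def adjacencies(order):
                out = set()
                for chrom in order.chromosomes:
                    for x, y in zip(chrom, chrom[1:]):
                        out.add((x, y))
                        out.add((-y, -x))
                return out

            bp = sum(
                1
                for chrom in a.chromosomes
                for xy in zip(chrom, chrom[1:])
                if xy not in adjacencies(b)
            )
            assert d(a, b) <= bp + 1  # +1 slack for telomeric breakpoints

    def test_simulation_consistency(self, rng):
        # applying k weight-1 operations never yields distance > k
        for _ in range(40):
            n = int(rng.integers(3, 12))
            a = random_signed_order(rng, n, max_chromosomes=2)
            g = a
            k = int(rng.integers(1, 6))
            for _ in range(k):
                chroms = g.chromosomes
                if len(chroms) >= 2 and rng.random() < 0.3:
                    ci, cj = rng.choice(len(chroms), size=2, replace=False)
                    g = apply_translocation(
                        g, int(ci), int(cj),
                        int(rng.integers(0, len(chroms[int(ci)]) + 1)),
                        int(rng.integers(0, len(chroms[int(cj)]) + 1)),
                    )
                else:
                    ci = int(rng.integers(len(chroms)))
                    m = len(chroms[ci])
                    l = int(rng.integers(1, m + 1))
                    r = int(rng.integers(l, m + 1))
                    g = apply_reversal(g, ci, l, r)
            assert d(a, g) <= k

    def test_distance_zero_iff_canonical_equal(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 10))
            a = random_signed_order(rng, n, max_chromosomes=2)
            b = random_signed_order(rng, n, max_chromosomes=2)
            assert (d(a, b) == 0) == (a.canonical() == b.canonical())


class TestCircular:
    def test_identical_circular_zero(self):
        assert weighted_rearrangement_distance(
            S([[1, 2, 3]]), S([[1, 2, 3]]), circular=True
        ).distance == 0

    def test_circular_rotation_is_identity(self):
        assert weighted_rearrangement_distance(
            S([[1, 2, 3]]), S([[3, 1, 2]]), circular=True
        ).distance == 0

    def test_circular_inversion(self):
        assert weighted_rearrangement_distance(
            S([[1, 2, 3]]), S([[1, -2, 3]]), circular=True
        ).distance == 1


class TestBuildSignedOrders:
    @staticmethod
    def _match(chrom_i, idx_i, chrom_j, idx_j, sign):
        pi = OGPair(
            first=f"a{idx_i}", second=f"b{idx_i}", chromosome_id=chrom_i,
            pattern="unidirectional", uni_orientation="forward",
            position_index=idx_i,
        )
        pj = OGPair(
            first=f"x{idx_j}", second=f"y{idx_j}", chromosome_id=chrom_j,
            pattern="unidirectional", uni_orientation="forward",
            position_index=idx_j,
        )
        return OrthologousOGPairMatch(pair_i=pi, pair_j=pj, relative_sign=sign)

    def test_identity_self_comparison(self):
        matches = [self._match("c1", k, "c1", k, 1) for k in range(4)]
        oi, oj = build_signed_orders(OrthologousOGPairSet(matches=matches))
        assert oi.chromosomes == ((1, 2, 3, 4),)
        assert oj.chromosomes == ((1, 2, 3, 4),)

    def test_negative_sign_appears(self):
        matches = [self._match("c1", 0, "c1", 0, -1)]
        _, oj = build_signed_orders(OrthologousOGPairSet(matches=matches))
        assert oj.chromosomes == ((-1,),)

    def test_chromosome_split(self):
        matches = [self._match("c1", k, "cI", k, 1) for k in range(3)] + [
            self._match("c2", k, "cII", k, 1) for k in range(2)
        ]
        oi, oj = build_signed_orders(OrthologousOGPairSet(matches=matches))
        assert sorted(len(c) for c in oi.chromosomes) == [2, 3]
        assert sorted(len(c) for c in oj.chromosomes) == [2, 3]

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="no orthologous"):
            build_signed_orders(OrthologousOGPairSet(matches=[]))


def test_adjacency_graph_dot_smoke():
    dot = adjacency_graph_dot(S([[1, 2]]), S([[2, 1]]))
    assert dot.startswith("graph adjacency {")
    assert dot.rstrip().endswith("}")
    assert "A0" in dot and "B0" in dot


def test_duplicate_element_rejected():
    with pytest.raises(ValueError):
        S([[1, 2, -1]])
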