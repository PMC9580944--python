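import numpy as np
import pytest

from synthrna.structures import (
    PairTable,
    RawPairAssignment,
    RnaSequence,
    aggregate_stats,
    count_elements,
    crossing_and_multipair_census,
    loop_decomposition,
    matrix_to_structure,
    multiloop_lengths,
    pairtable_to_matrix,
    pairtype_frequencies,
    parse_dotbracket,
    read_bpseq,
    write_bpseq,
    write_dotbracket,
)


class TestRnaSequence:
    def test_valid(self):
        assert len(RnaSequence("ACGU")) == 4

    @pytest.mark.parametrize("bad", ["", "ACGT", "ACGX", "acgu"])
    def test_invalid(self, bad):
        with pytest.raises(ValueError):
            RnaSequence(bad)


class TestPairTable:
    def test_symmetry_enforced(self):
        with pytest.raises(ValueError):
            PairTable([3, -1, -1, 1])  # 0->3 but 3->1

    def test_self_pair(self):
        with pytest.raises(ValueError):
            PairTable([0, -1])

    def test_double_partner(self):
        with pytest.raises(ValueError):
            PairTable.from_pairs(5, [(0, 3), (0, 4)])

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            PairTable([5, -1])


class TestDotBracket:
    def test_simple(self):
        assert parse_dotbracket("(((...)))").pairs() == [
            (0, 8), (1, 7), (2, 6)
        ]

    def test_all_unpaired(self):
        pt = parse_dotbracket(".........")
        assert pt.pairs() == [] and pt.n == 9

    def test_crossing_tiers(self):
        pt = parse_dotbracket("((.[.)).]")
        assert pt.pairs() == [(0, 6), (1, 5), (3, 8)]
        assert pt.has_crossings

    @pytest.mark.parametrize("bad,pos", [("((.)", 0), (".))", 1), ("(]", 1)])
    def test_unbalanced_names_position(self, bad, pos):
        with pytest.raises(ValueError, match=f"position {pos}"):
            parse_dotbracket(bad)

    def test_invalid_char(self):
        with pytest.raises(ValueError, match="position 2"):
            parse_dotbracket("..x..")

    def test_write_simple(self):
        assert write_dotbracket(
            PairTable.from_pairs(9, [(0, 8), (1, 7), (2, 6)])
        ) == "(((...)))"
        assert write_dotbracket(PairTable.from_pairs(4, [])) == "...."

    def test_write_crossing_two_tiers(self):
        pt = PairTable.from_pairs(9, [(0, 6), (1, 5), (3, 8)])
        assert write_dotbracket(pt) == "((.[.)).]"

    def test_roundtrip_nested(self, small_bundle):
        from synthrna.structures import write_dotbracket as w

        for pt in small_bundle.structures:
            assert parse_dotbracket(w(pt)) == pt


class TestBpseq(object):
    def test_roundtrip(self, tmp_path):
        seq = "GGGAAACCC"
        pt = parse_dotbracket("(((...)))")
        path = tmp_path / "x.bpseq"
        write_bpseq(path, seq, pt)
        seq2, pt2 = read_bpseq(path)
        assert seq2 == seq and pt2 == pt

    def test_one_based_on_disk(self, tmp_path):
        path = tmp_path / "y.bpseq"
        write_bpseq(path, "GAAAC", PairTable.from_pairs(5, [(0, 4)]))
        lines = path.read_text().splitlines()
        assert lines[0] == "1 G 5" and lines[4] == "5 C 1"


class TestRemovePseudoknots:
    def test_nested_unchanged(self):
        from synthrna.structures import remove_pseudoknots

        pt = parse_dotbracket("((((...))))")
        assert remove_pseudoknots(pt) == pt

    def test_tie_breaks_lexicographic(self):
        from synthrna.structures import remove_pseudoknots

        r = remove_pseudoknots(RawPairAssignment(9, [(0, 5), (2, 8)]))
        assert r.pairs() == [(0, 5)]

    def test_majority_wins(self):
        from synthrna.structures import remove_pseudoknots

        r = remove_pseudoknots(
            RawPairAssignment(13, [(0, 9), (1, 8), (4, 12), (5, 11), (6, 10)])
        )
        assert r.pairs() == [(4, 12), (5, 11), (6, 10)]

    def test_weights_override_cardinality_ties(self):
        from synthrna.structures import remove_pseudoknots

        raw = RawPairAssignment(9, [(0, 5), (2, 8)])
        r = remove_pseudoknots(raw, weights={(0, 5): 0.6, (2, 8): 0.9})
        assert r.pairs() == [(2, 8)]

    def test_shared_endpoints_resolved(self):
        from synthrna.structures import remove_pseudoknots

        r = remove_pseudoknots(RawPairAssignment(10, [(0, 8), (0, 9)]))
        assert len(r.pairs()) == 1


class TestCensus:
    def test_all_nested(self, small_bundle):
        c = crossing_and_multipair_census(small_bundle.structures)
        assert c.as_tuple() == (0, 0, 0, 0)

    def test_single_crossing(self):
        c = crossing_and_multipair_census([RawPairAssignment(9, [(0, 5), (2, 8)])])
        assert c.as_tuple() == (1, 2, 0, 0)

    def test_multipair(self):
        c = crossing_and_multipair_census([RawPairAssignment(8, [(0, 5), (0, 7)])])
        assert c.as_tuple() == (0, 0, 1, 2)


class TestLoops:
    def test_hairpin(self):
        la = loop_decomposition(parse_dotbracket("(((...)))"))
        assert la.labels == ["P"] * 3 + ["HL"] * 3 + ["P"] * 3

    def test_bulge_and_exterior(self):
        la = loop_decomposition(parse_dotbracket(".((..((...))))"))
        assert la.labels[0] == "EL"
        assert la.labels[3] == "BL" and la.labels[4] == "BL"

    def test_multiloop(self):
        la = loop_decomposition(parse_dotbracket("((.((...)).((...)).))"))
        assert [la.labels[k] for k in (2, 10, 18)] == ["ML"] * 3

    def test_interior(self):
        la = loop_decomposition(parse_dotbracket("((.((...)).))"))
        assert la.labels[2] == "IL" and la.labels[10] == "IL"

    def test_crossing_rejected(self):
        with pytest.raises(ValueError, match="remove_pseudoknots"):
            loop_decomposition(parse_dotbracket("((.[.)).]"))

    def test_partition_invariant(self, small_bundle):
        for pt in small_bundle.structures:
            la = loop_decomposition(pt)
            counts = la.counts()
            assert sum(counts.values()) == pt.n
            assert counts["P"] == 2 * len(pt.pairs())


class TestElements:
    @pytest.mark.parametrize(
        "db,expect",
        [
            ("(((...)))", {"helix": 1, "HL": 1, "EL": 1, "BL": 0, "IL": 0, "ML": 0}),
            ("((...))((...))", {"helix": 2, "HL": 2, "EL": 1, "BL": 0, "IL": 0, "ML": 0}),
            ("((.((...)).((...)).))", {"helix": 3, "HL": 2, "EL": 1, "BL": 0, "IL": 0, "ML": 1}),
            (".((..((...))))", {"helix": 2, "HL": 1, "EL": 1, "BL": 1, "IL": 0, "ML": 0}),
        ],
    )
    def test_counts(self, db, expect):
        assert count_elements(parse_dotbracket(db)) == expect

    @pytest.mark.parametrize(
        "db,expect",
        [
            ("(((...)))", []),
            ("((.((...)).((...)).))", [3]),
            ("(((...))((...))((...)))", [0]),
        ],
    )
    def test_multiloop_lengths(self, db, expect):
        assert multiloop_lengths(parse_dotbracket(db)) == expect


class TestPairTypes:
    @pytest.mark.parametrize(
        "seq,tp", [("GAAAC", "GC"), ("CAAAG", "CG"), ("AAAAA", "NC"),
                   ("AAAAU", "AU"), ("GAAAU", "GU")]
    )
    def test_classify(self, seq, tp):
        counts = pairtype_frequencies(seq, PairTable.from_pairs(5, [(0, 4)]))
        assert counts[tp] == 1 and sum(counts.values()) == 1

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            pairtype_frequencies("ACGU", PairTable.from_pairs(5, [(0, 4)]))


class TestAggregateStats:
    def test_single(self):
        rep = aggregate_stats(["GGGAAACCC"], [parse_dotbracket("(((...)))")])
        assert rep.context_freq["P"] == pytest.approx(6 / 9)
        assert rep.context_freq["HL"] == pytest.approx(3 / 9)
        assert rep.pairtype_freq["GC"] == 1.0

    def test_sums_to_one(self, small_bundle):
        rep = aggregate_stats(small_bundle.sequences, small_bundle.structures)
        assert sum(rep.context_freq.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(rep.pairtype_freq.values()) == pytest.approx(1.0, abs=1e-9)
        assert rep.pairtype_freq["NC"] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_stats([], [])


class TestMatrixToStructure:
    def test_idempotent_on_valid(self, small_bundle):
        for pt in small_bundle.structures[:20]:
            m = pairtable_to_matrix(pt)
            assert matrix_to_structure(m) == pt

    def test_below_threshold_empty(self):
        assert matrix_to_structure(np.full((5, 5), 0.2)).pairs() == []

    def test_crossing_resolved_by_score(self):
        m = np.zeros((4, 4))
        m[0, 2] = m[2, 0] = 0.9
        m[1, 3] = m[3, 1] = 0.8
        assert matrix_to_structure(m).pairs() == [(0, 2)]

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            matrix_to_structure(np.zeros((3, 4)))

    def test_symmetrize_both_stricter(self):
        m = np.zeros((8, 8))
        m[0, 5] = 0.9  # row 0 max; but m[5,0]=0 -> mean 0.45 < 0.5
        assert matrix_to_structure(m, symmetrize="either").pairs() == []
        m[5, 0] = 0.7
        assert matrix_to_structure(m, symmetrize="either").pairs() == [(0, 5)]
        assert matrix_to_structure(m, symmetrize="both").pairs() == [(0, 5)]

    def test_output_never_invalid(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 30))
            m = rng.random((n, n))
            pt = matrix_to_structure(m)
            assert not pt.has_crossings  # PairTable also enforces 1 partner
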