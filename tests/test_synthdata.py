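import numpy as np
import pytest

from synthrna.structures import parse_dotbracket
from synthrna.synthdata import (
    PRESETS,
    DatasetBundle,
    LengthDistributionSpec,
    bias_emulator,
    dinucleotide_shuffle,
    fixed_length,
    fold_dataset,
    inverse_fold,
    length_series_sets,
    make_dataset,
    preset_distribution_sets,
    replicate_bias_dataset,
    sample_sequences,
)
from synthrna.synthdata.shuffle import _dinucleotide_counts


class TestSampling:
    def test_determinism_and_distinctness(self):
        a = sample_sequences(3, fixed_length(5), seed=7)
        assert a == sample_sequences(3, fixed_length(5), seed=7)
        assert len(set(a)) == 3 and all(len(s) == 5 for s in a)

    def test_degenerate_composition(self):
        seqs = sample_sequences(50, fixed_length(70), composition=(1, 0, 0, 0),
                                seed=0)
        assert all(s == "A" * 70 for s in seqs)

    def test_bad_composition(self):
        with pytest.raises(ValueError):
            sample_sequences(2, fixed_length(5), composition=(0.5, 0.5, 0.5, 0))

    def test_bad_count(self):
        with pytest.raises(ValueError):
            sample_sequences(0, fixed_length(5))

    def test_support_contract(self):
        lengths = PRESETS["D1"].sample(10_000, np.random.default_rng(0))
        assert lengths.min() >= 25 and lengths.max() <= 100

    def test_d4_shorter_than_d1(self):
        rng = np.random.default_rng(0)
        d1 = np.median(PRESETS["D1"].sample(10_000, rng))
        d4 = np.median(PRESETS["D4"].sample(10_000, rng))
        assert d4 < d1

    def test_bad_spec(self):
        with pytest.raises(ValueError):
            LengthDistributionSpec("fixed", 0, 0)
        with pytest.raises(ValueError):
            LengthDistributionSpec("weird", 5, 10)


class TestBundles:
    def test_alignment_enforced(self):
        with pytest.raises(ValueError):
            DatasetBundle(["ACGU"], [])

    def test_duplicates_rejected(self):
        pt = parse_dotbracket("....")
        with pytest.raises(ValueError):
            DatasetBundle(["ACGU", "ACGU"], [pt, pt])

    def test_fold_dataset_ground_truth(self, oracle):
        bundle = fold_dataset(["GGGGAAAACCCC", "AAAAAAA"], oracle)
        assert len(bundle.structures[0].pairs()) >= 3
        assert bundle.structures[1].pairs() == []
        assert bundle.provenance["oracle"] == oracle.ident

    def test_dbn_roundtrip(self, tmp_path, small_bundle):
        path = tmp_path / "b.dbn"
        small_bundle.to_dbn(path)
        back = DatasetBundle.from_dbn(path)
        assert back.sequences == small_bundle.sequences
        assert all(a == b for a, b in
                   zip(back.structures, small_bundle.structures))

    def test_preset_sets_disjoint_and_deterministic(self, oracle):
        t1, v1 = preset_distribution_sets("D4", 5, 40, 10, oracle)
        t2, v2 = preset_distribution_sets("D4", 5, 40, 10, oracle)
        assert t1.sequences == t2.sequences and v1.sequences == v2.sequences
        assert not (set(t1.sequences) & set(v1.sequences))
        assert len(t1) == 40 and len(v1) == 10

    def test_length_series(self, oracle):
        series = length_series_sets([30, 50, 70], 5, seed=3, oracle=oracle)
        assert sorted(series) == [30, 50, 70]
        for L, bundle in series.items():
            assert len(bundle) == 5
            assert all(len(s) == L for s in bundle.sequences)

    def test_length_series_bad_args(self, oracle):
        with pytest.raises(ValueError):
            length_series_sets([30], 0, oracle=oracle)
        with pytest.raises(ValueError):
            length_series_sets([], 5, oracle=oracle)

    def test_ground_truth_invariants(self, small_bundle):
        from synthrna.structures import crossing_and_multipair_census

        census = crossing_and_multipair_census(small_bundle.structures)
        assert census.as_tuple() == (0, 0, 0, 0)


class TestShuffle:
    def test_exact_conservation(self, rng):
        for _ in range(300):
            n = int(rng.integers(2, 80))
            s = "".join(rng.choice(list("ACGU"), n))
            sh = dinucleotide_shuffle(s, rng)
            assert _dinucleotide_counts(sh) == _dinucleotide_counts(s)
            assert sorted(sh) == sorted(s)

    def test_unique_shuffle_fixed_point(self):
        assert dinucleotide_shuffle("AAAA", 1) == "AAAA"

    def test_enumerable_case(self):
        outs = {dinucleotide_shuffle("ACACAC", k) for k in range(20)}
        assert outs == {"ACACAC"}

    def test_too_short(self):
        with pytest.raises(ValueError):
            dinucleotide_shuffle("A", 0)

    def test_actually_shuffles(self, rng):
        s = "GGGGAAAACCCCUUUUGGGGAAAACCCC"
        outs = {dinucleotide_shuffle(s, int(k)) for k in range(20)}
        assert len(outs) > 1


class TestInverseFold:
    def test_exact_design_small(self, oracle):
        target = parse_dotbracket("(((....)))")
        res = inverse_fold(target, oracle, tries=6, seed=1)
        assert res.distance == 0
        assert parse_dotbracket(oracle.fold(res.sequence)) == target

    def test_unpaired_target(self, oracle):
        target = parse_dotbracket(".........")
        res = inverse_fold(target, oracle, tries=1, seed=0)
        assert res.distance == 0

    def test_best_of_k_monotone(self, oracle):
        target = parse_dotbracket("((((((((...)))).))))")
        d1 = inverse_fold(target, oracle, tries=1, seed=9, max_steps=40).distance
        d6 = inverse_fold(target, oracle, tries=6, seed=9, max_steps=40).distance
        assert d6 <= d1

    def test_crossing_target_rejected(self, oracle):
        with pytest.raises(ValueError):
            inverse_fold(parse_dotbracket("((.[.)).]"), oracle)

    def test_designability_rate(self, oracle, rng):
        # >= 90% of small oracle-derived targets designable
        seqs = sample_sequences(
            20, LengthDistributionSpec("uniform", 18, 30), seed=rng
        )
        targets = [parse_dotbracket(oracle.fold(s)) for s in seqs]
        ok = sum(
            inverse_fold(t, oracle, tries=6, seed=rng, max_steps=200).distance
            == 0
            for t in targets
        )
        assert ok >= 18


class TestBiasEmulator:
    def test_counts(self):
        col = bias_emulator(1, 30, seed=0)
        assert len(col) == 30
        col = bias_emulator(4, 25, seed=0)
        assert len(col) == 100

    def test_contract(self):
        col = bias_emulator(4, 25, seed=3)
        assert all(25 <= pt.n <= 120 for pt in col)
        assert all(not pt.has_crossings for pt in col)

    def test_bad_args(self):
        with pytest.raises(ValueError):
            bias_emulator(0, 10)


class TestReplicateBias:
    def test_filters_and_contract(self, oracle):
        from synthrna.structures import PairTable

        col = bias_emulator(2, 8, seed=4, lmin=25, lmax=45)
        too_long = parse_dotbracket("(" * 10 + "." * 130 + ")" * 10)
        # 7 mutually crossing pairs -> dropped
        pk = PairTable.from_pairs(
            40, [(i, 20 + i) for i in range(7)]
        )
        train, val, rep = replicate_bias_dataset(
            list(col) + [too_long, pk],
            oracle,
            seed=0,
            tries=1,
            max_steps=50,
        )
        assert rep.n_input == 18
        assert rep.n_length_filtered == 1
        assert rep.n_pseudoknot_dropped == 1
        assert rep.n_kept == len(train) + len(val) <= 16
        # ground truth is the oracle refold of each designed sequence
        for s, pt in list(train)[:3]:
            assert parse_dotbracket(oracle.fold(s)) == pt
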