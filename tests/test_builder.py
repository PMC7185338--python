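import numpy as np
import pytest

from pfbwt import (
    ExplicitSetPolicy,
    RollingHashPolicy,
    build,
    parse,
    plain_suffix_array,
    representative_prefixes,
    sentinel_block,
)
from pfbwt.builder import DictIndex, parse_bwt, parse_occurrence_tables
from pfbwt import testkit

from conftest import STANDARD_POLICIES, random_text


class TestPlainSuffixArray:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("banana$", [6, 5, 3, 1, 0, 4, 2]),
            ("AAA$", [3, 2, 1, 0]),
            ("ACGACG$$", [7, 6, 3, 0, 4, 1, 5, 2]),
            ("A", [0]),
        ],
    )
    def test_known_arrays(self, text, expected):
        assert list(plain_suffix_array(text)) == expected

    def test_matches_brute_force_on_random_texts(self, rng):
        for _ in range(40):
            t = random_text(rng, rng.randint(1, 300), "ACGT$ban")
            assert list(plain_suffix_array(t)) == testkit.naive_sa(t)

    def test_integer_sequences(self):
        assert list(plain_suffix_array([2, 1, 0])) == [2, 1, 0]


class TestParseBWT:
    def test_worked_example(self):
        p = parse("ACGACG", ExplicitSetPolicy(2, {"AC"}))
        assert list(parse_bwt(p)) == [1, 2, 0]

    def test_single_phrase(self):
        p = parse("GGTT", ExplicitSetPolicy(2, set()))
        assert list(parse_bwt(p)) == [1, 0]

    def test_is_permutation_of_ranks_plus_terminator(self, rng):
        p = parse(random_text(rng, 200), RollingHashPolicy(2, 5))
        expected = sorted(list(p.parse + 1) + [0])
        assert sorted(parse_bwt(p).tolist()) == expected


class TestOccurrenceTables:
    def test_worked_example(self):
        p = parse("ACGACG", ExplicitSetPolicy(2, {"AC"}))
        arts = parse_occurrence_tables(p)
        # phrase 0 = ACG$$, phrase 1 = ACGAC
        assert list(arts.il[0]) == [0] and list(arts.il[1]) == [1]
        assert list(arts.ep[0]) == [7] and list(arts.ep[1]) == [4]
        assert bytes(arts.pr[0]) == b"G" and bytes(arts.pr[1]) == b"$"

    def test_lengths_equal_occ(self):
        p = parse("ACGACGACG", ExplicitSetPolicy(2, {"AC"}))
        arts = parse_occurrence_tables(p)
        for i in range(p.d):
            assert len(arts.il[i]) == len(arts.pr[i]) == len(arts.ep[i]) == p.occ[i]

    def test_ep_values_tile_the_text(self, rng):
        p = parse(random_text(rng, 500), RollingHashPolicy(4, 11))
        ends = p.phrase_ends()
        assert np.all(np.diff(ends) > 0)
        assert ends[-1] == p.n_prime - 1


class TestRepresentativePrefixes:
    def test_worked_example(self):
        p = parse("ACGACG", ExplicitSetPolicy(2, {"AC"}))
        groups = list(representative_prefixes(DictIndex.from_pfp(p), p.w))
        assert [g.alpha for g in groups] == [
            b"ACG$$", b"ACGAC", b"CG$$", b"CGAC", b"G$$", b"GAC",
        ]
        assert groups[0].is_full_phrase and groups[1].is_full_phrase
        assert not any(g.is_full_phrase for g in groups[2:])
        assert all(len(g.alpha) > p.w for g in groups)

    def test_shared_suffix_merges_phrases(self):
        # two phrases ending with the same suffix produce one group
        di = DictIndex(dict_str=b"GAC#TAC#",
                       sa_d=plain_suffix_array(b"GAC#TAC#"),
                       phrase_starts=np.array([0, 4]))
        groups = list(representative_prefixes(di, 1))
        by_alpha = {g.alpha: sorted(g.phrase_ids) for g in groups}
        assert by_alpha[b"AC"] == [0, 1]
        assert set(by_alpha) == {b"AC", b"GAC", b"TAC"}

    def test_short_suffixes_never_appear(self, rng):
        p = parse(random_text(rng, 300), RollingHashPolicy(2, 5))
        for g in representative_prefixes(DictIndex.from_pfp(p), p.w):
            assert len(g.alpha) > p.w


class TestSentinelBlock:
    def test_worked_example(self):
        bwt, sa = sentinel_block(ord("G"), 2, 8)
        assert bytes(bwt) == b"$G" and list(sa) == [7, 6]

    def test_single_sentinel(self):
        bwt, sa = sentinel_block(ord("T"), 1, 5)
        assert bytes(bwt) == b"T" and list(sa) == [4]

    def test_prefixes_oracle_on_random_inputs(self, rng):
        for _ in range(15):
            s = random_text(rng, rng.randint(1, 120))
            w = rng.choice([1, 2, 4])
            sp = s.encode() + b"$" * w
            bwt, sa = sentinel_block(ord(s[-1]), w, len(sp))
            assert list(sa) == testkit.naive_sa(sp)[:w]
            assert bytes(bwt) == testkit.naive_bwt(sp)[:w]


class TestBuild:
    def test_worked_example_bwt_sa(self):
        p = parse("ACGACG", ExplicitSetPolicy(2, {"AC"}))
        res = build(p, mode="bwt+sa")
        assert res.bwt == b"$GG$AACC"
        assert list(res.sa) == [7, 6, 3, 0, 4, 1, 5, 2]

    def test_worked_example_samples(self):
        p = parse("ACGACG", ExplicitSetPolicy(2, {"AC"}))
        res = build(p, mode="bwt+samples")
        s = res.samples
        assert s.r == 5
        assert s.start_pairs == [(0, 7), (1, 6), (3, 0), (4, 4), (6, 5)]
        assert s.end_pairs == [(0, 7), (2, 3), (3, 0), (5, 1), (7, 2)]
        assert res.run_heads.tobytes() == b"$G$AC"

    def test_full_phrase_as_suffix_of_another_phrase(self):
        # "ACG" is both a phrase (the forced first one) and a suffix of
        # "CGTACG"; the merge must still reproduce the oracle exactly.
        p = parse("ACGTACG", ExplicitSetPolicy(2, {"CG"}))
        assert b"ACG" in p.phrases and b"CGTACG" in p.phrases
        res = build(p, mode="bwt+sa")
        sp = b"ACGTACG$$"
        assert res.bwt == testkit.naive_bwt(sp)
        assert list(res.sa) == testkit.naive_sa(sp)

    def test_sa_formula_on_gac_group(self):
        # GAC group: ep=4, |alpha|=3 -> SA entry 4 - 3 + 1 = 2
        p = parse("ACGACG", ExplicitSetPolicy(2, {"AC"}))
        res = build(p, mode="bwt+sa")
        sp = b"ACGACG$$"
        assert res.sa[list(res.sa).index(2)] == 2
        assert sp[2:] == b"GACG$$"

    def test_bwt_is_permutation_of_extended_text(self, rng):
        for _ in range(10):
            s = random_text(rng, rng.randint(1, 400))
            pol = rng.choice(STANDARD_POLICIES)
            res = build(parse(s, pol), mode="bwt")
            assert sorted(res.bwt) == sorted(s.encode() + b"$" * pol.w)

    def test_oracle_equivalence_random_corpus(self, rng):
        for _ in range(25):
            s = random_text(rng, rng.randint(1, 800),
                            rng.choice(["ACGT", "ACGNT"]))
            for pol in STANDARD_POLICIES:
                res = build(parse(s, pol), mode="bwt+sa")
                sp = s.encode() + b"$" * pol.w
                assert res.bwt == testkit.naive_bwt(sp)
                assert list(res.sa) == testkit.naive_sa(sp)

    def test_parse_invariance_across_policies(self, rng):
        for _ in range(8):
            s = random_text(rng, rng.randint(20, 500))
            outputs = set()
            for p_mod in (1, 5, 97):
                res = build(parse(s, RollingHashPolicy(2, p_mod)),
                            mode="bwt+sa")
                outputs.add((res.bwt, tuple(res.sa)))
            assert len(outputs) == 1

    def test_samples_match_run_decomposition_of_full_output(self, rng):
        for _ in range(10):
            s = random_text(rng, rng.randint(1, 500))
            pol = rng.choice(STANDARD_POLICIES)
            p = parse(s, pol)
            full = build(p, mode="bwt+sa")
            samp = build(p, mode="bwt+samples").samples
            _, starts, ends = testkit.run_decomposition(full.bwt)
            assert samp.start_pos.tolist() == starts
            assert samp.end_pos.tolist() == ends
            assert samp.start_sa.tolist() == [int(full.sa[i]) for i in starts]
            assert samp.end_sa.tolist() == [int(full.sa[i]) for i in ends]

    def test_unknown_mode_rejected(self):
        p = parse("ACGACG", ExplicitSetPolicy(2, {"AC"}))
        with pytest.raises(ValueError):
            build(p, mode="samples")
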