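"""Target-site discovery: strict seed gate, duplex scoring, site filtering."""
import numpy as np
import pytest

from cernaforge.target_prediction import (DEFAULT_PARAMS, ScoringParams,
                                          aggregate_pairs, find_mres,
                                          revcomp_rna, score_duplex,
                                          seed_match, MRESite)

BASES = list("ACGU")


def naive_seed_check(mirna, target, offset):
    """Independent pairing oracle: six antiparallel WC pairs, no wobble."""
    wc = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
    # miRNA position p (2..7, 1-based) pairs target offset + (7 - p)
    return all((mirna[p - 1], target[offset + 7 - p]) in wc
               for p in range(2, 8))


def brute_flank(a, a_pos, b, params):
    """Exhaustive enumeration of anchored flank alignments (free distal
    ends, affine gaps charged from the anchor)."""
    la, lb = len(a), len(b)

    def rec(i, j, state):
        opts = [0.0]
        if i < la and j < lb:
            opts.append(params.position_score(a_pos[i], a[i], b[j])
                        + rec(i + 1, j + 1, "M"))
        if j < lb:
            g = params.gap_extend if state == "X" else params.gap_open
            opts.append(g + rec(i, j + 1, "X"))
        if i < la:
            g = params.gap_extend if state == "Y" else params.gap_open
            opts.append(g + rec(i + 1, j, "Y"))
        return max(opts)

    return rec(0, 0, None)


def brute_duplex_score(m, w, o, params=DEFAULT_PARAMS):
    s = sum(params.position_score(p, m[p - 1], w[o + 7 - p])
            for p in range(2, 8))
    s += brute_flank([m[0]], [1], list(w[o + 6:]), params)
    s += brute_flank(list(m[7:]), list(range(8, len(m) + 1)),
                     list(w[:o][::-1]), params)
    return s


class TestSeedMatch:
    def test_perfect_seed_window(self):
        mir = "UAGCUUAUCAGACUGAUGUUGA"
        assert seed_match(mir, "UAAGCU", 0)

    def test_wobble_in_seed_rejected(self):
        mir = "UAGCUUAUCAGACUGAUGUUGA"
        assert not seed_match(mir, "UAAGUU", 0)

    def test_non_rna_characters_rejected(self):
        with pytest.raises(ValueError):
            seed_match("UAGCUUXUCAGACUGAUGUUGA", "UAAGCU", 0)

    def test_agrees_with_naive_pairing_oracle(self, rng):
        """Random 22-mers vs random targets at every offset."""
        for _ in range(50):
            m = "".join(rng.choice(BASES, 22))
            t = "".join(rng.choice(BASES, 40))
            for o in range(len(t) - 6):
                assert seed_match(m, t, o) == naive_seed_check(m, t, o)

    def test_self_sequence_rarely_matches(self, rng):
        """A miRNA laid over its own sequence pairs only if the seed region
        happens to be a palindromic complement."""
        for _ in range(100):
            m = "".join(rng.choice(BASES, 22))
            assert seed_match(m, m, 0) == naive_seed_check(m, m, 0)


class TestScoreDuplex:
    def test_perfect_22mer_scores_215(self, rng):
        for _ in range(10):
            m = "".join(rng.choice(BASES, 22))
            d = score_duplex(m, revcomp_rna(m))
            assert d.score == pytest.approx(215.0)
            assert len(d.pairs) == 22

    def test_energy_is_per_pair_sum(self):
        # 11 G/C and 11 A/U bases -> 11 x (-3) + 11 x (-2) = -55
        m = "GCGCGCGCGCG" + "AUAUAUAUAUA"
        d = score_duplex(m, revcomp_rna(m))
        assert d.energy == pytest.approx(-55.0)

    def test_ten_gc_pairs_hit_energy_boundary(self):
        """An all-G/C 10-mer duplex has dG = -30 exactly, which passes the
        dG <= -30 threshold."""
        m = "GCGCGCGCGC"
        d = score_duplex(m, revcomp_rna(m))
        assert d.energy == pytest.approx(-30.0)
        sites = find_mres(m, "AAAA" + revcomp_rna(m) + "AAAA")
        assert len(sites) == 1  # S = 155, dG = -30: both thresholds met

    def test_mismatch_additivity(self, rng):
        """Replacing one non-seed WC pair with a mismatch costs 8 score
        units (5 - (-3)) and the lost pair energy."""
        m = "".join(rng.choice(BASES, 22))
        wc = revcomp_rna(m)
        pos = 15  # 1-based miRNA position, outside the scaled 2-8 region
        widx = 22 - pos
        mutated = wc[:widx] + m[pos - 1] + wc[widx + 1:]
        d0, d1 = score_duplex(m, wc), score_duplex(m, mutated)
        assert d1.score - d0.score == pytest.approx(-8.0)
        lost = DEFAULT_PARAMS.pair_energy(m[pos - 1], wc[widx])
        assert d1.energy - d0.energy == pytest.approx(-lost)

    def test_dp_equals_bruteforce_enumeration(self, rng):
        """Short miRNAs (8-10 nt) against windows up to 14 nt."""
        checked = 0
        while checked < 100:
            L = int(rng.integers(8, 11))
            m = "".join(rng.choice(BASES, L))
            anchor = revcomp_rna(m[1:7])
            pre = "".join(rng.choice(BASES, int(rng.integers(0, 5))))
            post = "".join(rng.choice(BASES,
                                      int(rng.integers(0, 9 - len(pre)))))
            w = pre + anchor + post
            if len(w) > 14:
                continue
            d = score_duplex(m, w, seed_offset=len(pre))
            assert d.score == pytest.approx(
                brute_duplex_score(m, w, len(pre)))
            checked += 1

    def test_window_shorter_than_seed_rejected(self):
        with pytest.raises(ValueError):
            score_duplex("GCGCGCGCGC", "GCGC")


class TestFindMres:
    def test_no_seed_complement_no_sites(self):
        assert find_mres("GGGGGGGGGG", "AAAAAAAAAAAAAAAAAAAA") == []

    def test_planted_full_complements_found_at_coordinates(self, rng):
        m = "".join(rng.choice(BASES, 22))
        site = revcomp_rna(m)
        target = ("AAAA" + site + "CCCCC" + site + "GG")
        sites = find_mres(m, target)
        assert [(s.start, s.end) for s in sites] == [(4, 26), (31, 53)]
        assert all(s.score == pytest.approx(215.0) for s in sites)

    def test_every_emitted_site_contains_a_seed_anchor(self, rng):
        """Fuzz: emitted MREs always carry the strict-seed hexamer."""
        weak = ScoringParams(score_min=145.0, energy_max=-10.0)
        for _ in range(100):
            m = "".join(rng.choice(BASES, 22))
            t = "".join(rng.choice(BASES, 300))
            for s in find_mres(m, t, weak):
                assert revcomp_rna(m[1:7]) in t[s.start:s.end]

    def test_threshold_weakening_only_adds_sites(self, rng):
        strict = DEFAULT_PARAMS
        weaker = ScoringParams(score_min=100.0, energy_max=-20.0)
        for _ in range(30):
            m = "".join(rng.choice(BASES, 22))
            t = ("".join(rng.choice(BASES, 100)) + revcomp_rna(m)
                 + "".join(rng.choice(BASES, 100)))
            keys = lambda ss: {(s.start, s.end) for s in ss}
            assert keys(find_mres(m, t, strict)) <= keys(find_mres(m, t, weaker))

    def test_retained_sites_do_not_overlap(self, rng):
        m = "".join(rng.choice(BASES, 22))
        site = revcomp_rna(m)
        # two overlapping plants: greedy keeps non-overlapping subset
        t = "AA" + site[:20] + site + "AA"
        spans = [(s.start, s.end) for s in find_mres(m, t)]
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            assert a1 <= b0


class TestAggregatePairs:
    def test_sums_and_extrema(self):
        sites = [MRESite("m1", "t1", 0, 22, 200.0, -40.0),
                 MRESite("m1", "t1", 50, 72, 160.0, -35.0)]
        df = aggregate_pairs(sites, {"t1": 1000})
        row = df.iloc[0]
        assert row["total_score"] == 360.0
        assert row["total_energy"] == -75.0
        assert row["max_score"] == 200.0
        assert row["max_energy"] == -40.0
        assert row["mre_count"] == 2
        assert row["target_length"] == 1000

    def test_single_site(self):
        df = aggregate_pairs([MRESite("m1", "t1", 0, 22, 200.0, -40.0)],
                             {"t1": 500})
        assert df.iloc[0]["max_energy"] == df.iloc[0]["total_energy"] == -40.0

    def test_no_sites_no_rows(self):
        assert len(aggregate_pairs([], {})) == 0
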