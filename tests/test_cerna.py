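"""Shared-miRNA testing, MuTaME scoring, co-expression and pair calling."""
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from cernaforge.cerna import (SiteIndex, build_ternary_network, call_cerna,
                              coexpression_pairs, mutame_score,
                              network_census, normalize_scores,
                              shared_mirna_test)
from cernaforge.target_prediction import MRESite


def exact_upper_tail(k, N, K, n):
    """Independent oracle: exact rational upper-tail hypergeometric sum."""
    total = Fraction(0)
    for j in range(k, min(K, n) + 1):
        total += Fraction(comb(K, j) * comb(N - K, n - j), comb(N, n))
    return total


class TestSharedMirnaTest:
    def universe(self, n):
        return {f"m{i}" for i in range(n)}

    def test_worked_case(self):
        """N=20, K=5, n=4, k=3 -> exactly 155/4845."""
        u = sorted(self.universe(20))
        x = set(u[:5])
        y = set(u[:3]) | {u[10]}
        t = shared_mirna_test(x, y, set(u))
        assert (t.N, t.K, t.n, t.k) == (20, 5, 4, 3)
        assert t.p_hyper == pytest.approx(155 / 4845, rel=1e-12)

    def test_no_overlap_p_one(self):
        u = sorted(self.universe(10))
        t = shared_mirna_test(set(u[:3]), set(u[5:8]), set(u))
        assert t.k == 0 and t.p_hyper == 1.0

    def test_full_marking_forces_overlap(self):
        u = self.universe(12)
        t = shared_mirna_test(set(u), {list(u)[0], list(u)[1]}, u)
        assert t.k == t.n and t.p_hyper == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            shared_mirna_test(set(), set(), set())

    def test_small_sweep_matches_enumeration(self):
        """All (N <= 12, K, n, k): float vs exact rational arithmetic."""
        from cernaforge._stats import hypergeom_upper_tail

        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        assert hypergeom_upper_tail(k, N, K, n) == \
                            pytest.approx(float(exact_upper_tail(k, N, K, n)),
                                          rel=1e-10)

    def test_monotone_in_k(self):
        from cernaforge._stats import hypergeom_upper_tail

        ps = [hypergeom_upper_tail(k, 30, 10, 8) for k in range(9)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestCoexpression:
    def frame(self, rows, ids):
        return pd.DataFrame(rows, index=ids,
                            columns=[f"s{i}" for i in range(len(rows[0]))])

    def test_identical_vectors_retained(self):
        x = self.frame([[1, 2, 3, 4]], ["l1"])
        y = self.frame([[1, 2, 3, 4]], ["m1"])
        out = coexpression_pairs(x, y)
        assert len(out) == 1 and out["r"].iloc[0] == pytest.approx(1.0)

    def test_perfect_linearity(self):
        out = coexpression_pairs(self.frame([[1, 2, 3, 4]], ["l1"]),
                                 self.frame([[2, 4, 6, 8]], ["m1"]))
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_matches_scipy_pearsonr(self, rng):
        x = rng.normal(size=(4, 8))
        y = rng.normal(size=(5, 8))
        lx = self.frame(x, [f"l{i}" for i in range(4)])
        ly = self.frame(y, [f"m{i}" for i in range(5)])
        out = coexpression_pairs(lx, ly, min_r=0.0, max_p=1.1)
        for row in out.itertuples():
            i, j = int(row.lncrna[1:]), int(row.mrna[1:])
            r_ref, p_ref = pearsonr(x[i], y[j])
            assert row.r == pytest.approx(r_ref)
            assert row.p_r == pytest.approx(p_ref, rel=1e-9)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=(1, 10))
        y = 3.0 * x + 7.0 + 0.01 * rng.normal(size=(1, 10))
        out1 = coexpression_pairs(self.frame(x, ["l1"]),
                                  self.frame(y, ["m1"]), min_r=0.0, max_p=1.1)
        out2 = coexpression_pairs(self.frame(5 * x - 2, ["l1"]),
                                  self.frame(y, ["m1"]), min_r=0.0, max_p=1.1)
        assert out1["r"].iloc[0] == pytest.approx(out2["r"].iloc[0])

    def test_positive_mode_drops_anticorrelation(self):
        x = self.frame([[1, 2, 3, 4]], ["l1"])
        y = self.frame([[4, 3, 2, 1]], ["m1"])
        assert len(coexpression_pairs(x, y, mode="absolute")) == 1
        assert len(coexpression_pairs(x, y, mode="positive")) == 0

    def test_long_lncrnas_excluded(self):
        x = self.frame([[1, 2, 3, 4]], ["l1"])
        y = self.frame([[1, 2, 3, 4]], ["m1"])
        out = coexpression_pairs(x, y, lnc_lengths={"l1": 6000})
        assert len(out) == 0  # strict <: 6000 nt is excluded

    def test_zero_variance_skipped(self):
        x = self.frame([[5, 5, 5, 5]], ["l1"])
        y = self.frame([[1, 2, 3, 4]], ["m1"])
        assert len(coexpression_pairs(x, y)) == 0


class TestMutame:
    def test_single_shared_site_worked_example(self):
        """1000-nt partners, one 20-nt shared site each and nothing else:
        s1=1, s2=1.0, s3=0.02, s4=1 -> raw = 0.02."""
        sites = [MRESite("m1", "x", 100, 120, 200.0, -40.0),
                 MRESite("m1", "y", 300, 320, 200.0, -40.0)]
        idx = SiteIndex(sites)
        s1, s2, s3, s4, raw = mutame_score("x", 1000, "y", 1000, {"m1"}, idx)
        assert (s1, s2, s3, s4) == (1.0, 1.0, 0.02, 1.0)
        assert raw == pytest.approx(0.02)

    def test_doubling_shared_sites_doubles_s2(self):
        one = SiteIndex([MRESite("m1", "x", 0, 20, 200.0, -40.0),
                         MRESite("m1", "y", 0, 20, 200.0, -40.0)])
        two = SiteIndex([MRESite("m1", "x", 0, 20, 200.0, -40.0),
                         MRESite("m1", "x", 480, 500, 180.0, -35.0),
                         MRESite("m1", "y", 0, 20, 200.0, -40.0),
                         MRESite("m1", "y", 480, 500, 180.0, -35.0)])
        r1 = mutame_score("x", 500, "y", 500, {"m1"}, one)
        r2 = mutame_score("x", 500, "y", 500, {"m1"}, two)
        assert r2[1] == pytest.approx(2 * r1[1])  # s2 doubles
        assert r2[3] == r1[3] == 1.0              # s4 stays 1

    def test_partner_without_sites_rejected(self):
        idx = SiteIndex([MRESite("m1", "x", 0, 20, 200.0, -40.0)])
        with pytest.raises(ValueError):
            mutame_score("x", 500, "y", 500, {"m1"}, idx)

    def test_empty_shared_set_rejected(self):
        with pytest.raises(ValueError):
            mutame_score("x", 500, "y", 500, set(), SiteIndex([]))


class TestNormalizeAndCall:
    def pairs(self, raws):
        return pd.DataFrame({
            "lncrna": [f"l{i}" for i in range(len(raws))],
            "mrna": [f"m{i}" for i in range(len(raws))],
            "shared_mirnas": [("mir1",)] * len(raws),
            "p_hyper": [0.01] * len(raws),
            "raw_score": raws,
        })

    def test_single_pair_normalizes_to_100(self):
        out = normalize_scores(self.pairs([0.37]))
        assert out["norm_score"].iloc[0] == pytest.approx(100.0)

    def test_two_to_one_ratio(self):
        out = normalize_scores(self.pairs([2.0, 1.0]))
        assert list(out["norm_score"]) == [100.0, 50.0]

    def test_rank_order_preserved(self, rng):
        raws = rng.uniform(0, 5, 20)
        out = normalize_scores(self.pairs(list(raws)))
        assert list(out["raw_score"]) == sorted(raws, reverse=True)

    def test_all_zero_scores(self):
        out = normalize_scores(self.pairs([0.0, 0.0]))
        assert (out["norm_score"] == 0.0).all()

    def test_call_cerna_disjoint_inputs(self):
        scored = normalize_scores(self.pairs([1.0]))
        coexpr = pd.DataFrame({"lncrna": ["lX"], "mrna": ["mX"],
                               "r": [0.9], "p_r": [0.01]})
        merged, venn = call_cerna(scored, coexpr)
        assert len(merged) == 0
        assert venn == {"scored": 1, "coexpressed": 1, "intersection": 0}

    def test_call_cerna_merges_matching_pair_once(self):
        scored = normalize_scores(self.pairs([1.0]))
        coexpr = pd.DataFrame({"lncrna": ["l0"], "mrna": ["m0"],
                               "r": [0.92], "p_r": [0.001]})
        merged, venn = call_cerna(scored, coexpr)
        assert len(merged) == 1
        assert merged["r"].iloc[0] == 0.92
        assert venn["intersection"] <= min(venn["scored"],
                                           venn["coexpressed"])


class TestTernaryNetwork:
    def pair(self, mirnas):
        return pd.DataFrame({"lncrna": ["l1"], "mrna": ["m1"],
                             "shared_mirnas": [tuple(mirnas)],
                             "p_hyper": [0.01], "raw_score": [1.0],
                             "norm_score": [100.0]})

    def test_one_shared_mirna(self):
        g = build_ternary_network(self.pair(["mir1"]))
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 2

    def test_three_shared_mirnas(self):
        g = build_ternary_network(self.pair(["mir1", "mir2", "mir3"]))
        census = network_census(g)
        assert census["n_nodes"] == 5 and census["n_edges"] == 6
        assert census["n_miRNA"] == 3

    def test_shared_mirna_node_deduplicated(self):
        two = pd.concat([self.pair(["mir1"]),
                         self.pair(["mir1"]).assign(lncrna="l2", mrna="m2")],
                        ignore_index=True)
        g = build_ternary_network(two)
        assert sum(1 for _, d in g.nodes(data=True)
                   if d["kind"] == "miRNA") == 1
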