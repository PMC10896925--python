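"""ceRNA pair calling.

A lncRNA and an mRNA are called a competing-endogenous pair when (i) they
share predicted miRNA response elements for significantly more miRNAs than
chance (upper-tail hypergeometric test over the miRNA universe), (ii) their
composite MuTaME-style score is high, and (iii) they are positively
co-expressed (Pearson r >= 0.8, p < 0.05).  The four MuTaME components used
here are normative for this package: shared-miRNA count (s1), shared-MRE
density per kilobase (s2), positional spread of shared MREs (s3) and the
shared fraction of all MREs (s4); the raw score is their product, normalized
to [0, 100] against the best pair in the batch.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from ._stats import hypergeom_upper_tail, pearson_matrix
from .target_prediction import MRESite

logger = logging.getLogger("cernaforge")


def coexpression_pairs(expr_lnc: pd.DataFrame, expr_mrna: pd.DataFrame,
                       lnc_lengths: Mapping[str, int] | None = None,
                       min_r: float = 0.8, max_p: float = 0.05,
                       max_lnc_length: int = 6000,
                       mode: str = "absolute") -> pd.DataFrame:
    """All lncRNA x mRNA pairs passing the correlation filter.

    Expression rows are features, columns samples (matched between the two
    frames).  ``mode`` is "absolute" (|r| >= min_r) or "positive"
    (r >= min_r).  lncRNAs at or above ``max_lnc_length`` nt are excluded
    when lengths are given (strict <, as the inherited filter prints it).
    Zero-variance features are skipped with a warning.
    """
    if mode not in ("absolute", "positive"):
        raise ValueError(f"unknown mode {mode!r}")
    if list(expr_lnc.columns) != list(expr_mrna.columns):
        raise ValueError("sample columns differ between matrices")
    if expr_lnc.shape[1] < 3:
        raise ValueError("need >= 3 samples for correlation p-values")
    if lnc_lengths is not None:
        keep = [i for i in expr_lnc.index if lnc_lengths[i] < max_lnc_length]
        expr_lnc = expr_lnc.loc[keep]
    if len(expr_lnc) == 0 or len(expr_mrna) == 0:
        return pd.DataFrame(columns=["lncrna", "mrna", "r", "p_r"])
    R, P = pearson_matrix(expr_lnc.to_numpy(), expr_mrna.to_numpy())
    if np.isnan(R).any():
        logger.warning("zero-variance feature(s): %d pair(s) skipped",
                       int(np.isnan(R).sum()))
    passed = R >= min_r if mode == "positive" else np.abs(R) >= min_r
    passed &= P < max_p
    passed &= ~np.isnan(R)
    li, mi = np.nonzero(passed)
    out = pd.DataFrame({
        "lncrna": expr_lnc.index[li],
        "mrna": expr_mrna.index[mi],
        "r": R[li, mi],
        "p_r": P[li, mi],
    })
    return out.sort_values(["lncrna", "mrna"], ignore_index=True)


@dataclass(frozen=True)
class SharedMiRNATest:
    """Upper-tail hypergeometric test of miRNA sharing between two RNAs."""

    N: int  # miRNA universe
    K: int  # miRNAs targeting X
    n: int  # miRNAs targeting Y
    k: int  # shared
    p_hyper: float


def shared_mirna_test(targets_x: set, targets_y: set,
                      universe: set) -> SharedMiRNATest:
    """P(shared >= k) when K and n miRNAs are drawn from a universe of N."""
    if not universe:
        raise ValueError("empty miRNA universe")
    if not (targets_x <= set(universe) and targets_y <= set(universe)):
        raise ValueError("target miRNA sets must be subsets of the universe")
    N, K, n = len(universe), len(targets_x), len(targets_y)
    k = len(set(targets_x) & set(targets_y))
    return SharedMiRNATest(N=N, K=K, n=n, k=k,
                           p_hyper=hypergeom_upper_tail(k, N, K, n))


class SiteIndex:
    """MRE sites indexed by (miRNA, target) and by target."""

    def __init__(self, sites: Iterable[MRESite]):
        self.by_pair: dict[tuple, list[MRESite]] = {}
        self.by_target: dict[str, list[MRESite]] = {}
        for s in sites:
            self.by_pair.setdefault((s.mirna, s.target), []).append(s)
            self.by_target.setdefault(s.target, []).append(s)

    def mirnas_of(self, target_id: str) -> set:
        return {s.mirna for s in self.by_target.get(target_id, [])}

    def sites_for(self, target_id: str, mirnas) -> list[MRESite]:
        mirnas = set(mirnas)
        return [s for s in self.by_target.get(target_id, [])
                if s.mirna in mirnas]


def mutame_score(x_id: str, x_len: int, y_id: str, y_len: int,
                 shared: set, index: SiteIndex):
    """MuTaME components and raw score for one candidate pair.

    s1 = number of shared miRNAs; s2 = mean shared-MRE count per kb;
    s3 = mean fractional span (max site end - min site start)/length of the
    shared-miRNA sites; s4 = mean fraction of each transcript's MREs that
    belong to shared miRNAs; raw = s1*s2*s3*s4.
    """
    if not shared:
        raise ValueError("shared miRNA set must be nonempty")
    s2s, s3s, s4s = [], [], []
    for tid, tlen in ((x_id, x_len), (y_id, y_len)):
        all_sites = index.by_target.get(tid, [])
        if not all_sites:
            raise ValueError(f"transcript {tid} has no MREs; score undefined")
        ss = index.sites_for(tid, shared)
        if not ss:
            raise ValueError(f"transcript {tid} has no shared-miRNA MREs")
        s2s.append(1000.0 * len(ss) / tlen)
        s3s.append((max(s.end for s in ss) - min(s.start for s in ss)) / tlen)
        s4s.append(len(ss) / len(all_sites))
    s1 = float(len(shared))
    s2, s3, s4 = (float(np.mean(v)) for v in (s2s, s3s, s4s))
    return s1, s2, s3, s4, s1 * s2 * s3 * s4


def score_candidate_pairs(sites: Iterable[MRESite] | SiteIndex,
                          lnc_lengths: Mapping[str, int],
                          mrna_lengths: Mapping[str, int],
                          universe: set) -> pd.DataFrame:
    """Hypergeometric + MuTaME scoring for every lncRNA-mRNA pair sharing
    at least one miRNA.

    Pairs whose MuTaME score is undefined (a partner with no MREs) are
    dropped with a warning.
    """
    index = sites if isinstance(sites, SiteIndex) else SiteIndex(sites)
    rows, dropped = [], 0
    for lnc in sorted(lnc_lengths):
        mirs_l = index.mirnas_of(lnc)
        if not mirs_l:
            continue
        for mrna in sorted(mrna_lengths):
            mirs_m = index.mirnas_of(mrna)
            shared = mirs_l & mirs_m
            if not shared:
                continue
            test = shared_mirna_test(mirs_l, mirs_m, universe)
            try:
                s1, s2, s3, s4, raw = mutame_score(
                    lnc, lnc_lengths[lnc], mrna, mrna_lengths[mrna],
                    shared, index)
            except ValueError:
                dropped += 1
                continue
            rows.append({
                "lncrna": lnc, "mrna": mrna,
                "shared_mirnas": tuple(sorted(shared)),
                "k": test.k, "K": test.K, "n": test.n, "N": test.N,
                "p_hyper": test.p_hyper,
                "s1": s1, "s2": s2, "s3": s3, "s4": s4, "raw_score": raw,
            })
    if dropped:
        logger.warning("%d candidate pair(s) dropped (undefined score)",
                       dropped)
    return pd.DataFrame(rows, columns=[
        "lncrna", "mrna", "shared_mirnas", "k", "K", "n", "N", "p_hyper",
        "s1", "s2", "s3", "s4", "raw_score"])


def normalize_scores(pairs: pd.DataFrame) -> pd.DataFrame:
    """Scale raw scores to [0, 100] against the batch maximum and rank.

    Ties break by p_hyper ascending, then lexicographic ids.
    """
    if len(pairs) == 0:
        out = pairs.copy()
        out["norm_score"] = pd.Series(dtype=float)
        return out
    out = pairs.copy()
    top = out["raw_score"].max()
    if top <= 0:
        logger.warning("all raw scores are zero; normalized scores set to 0")
        out["norm_score"] = 0.0
    else:
        out["norm_score"] = 100.0 * out["raw_score"] / top
    out = out.sort_values(
        ["norm_score", "p_hyper", "lncrna", "mrna"],
        ascending=[False, True, True, True], ignore_index=True)
    return out


def call_cerna(scored_pairs: pd.DataFrame, coexpr_pairs: pd.DataFrame,
               p_hyper_max: float = 0.05, min_r: float = 0.8):
    """Intersect score-passing pairs with positively co-expressed pairs.

    Returns the merged CeRNA pair table (ranked like ``normalize_scores``)
    and the Venn census of both inputs and their intersection.
    """
    a = scored_pairs[scored_pairs["p_hyper"] < p_hyper_max]
    b = coexpr_pairs[coexpr_pairs["r"] >= min_r]
    merged = a.merge(b, on=["lncrna", "mrna"], how="inner")
    if "norm_score" in merged.columns:
        merged = merged.sort_values(
            ["norm_score", "p_hyper", "lncrna", "mrna"],
            ascending=[False, True, True, True], ignore_index=True)
    venn = {"scored": len(a), "coexpressed": len(b),
            "intersection": len(merged)}
    return merged, venn


def build_ternary_network(cerna_pairs: pd.DataFrame,
                          top_pairs: int = 100) -> nx.Graph:
    """lncRNA-miRNA-mRNA graph from the top-ranked ceRNA pairs.

    Each shared miRNA of a pair contributes two edges (lncRNA-miRNA and
    miRNA-mRNA); nodes are deduplicated and typed via the ``kind``
    attribute.
    """
    g = nx.Graph()
    for _, row in cerna_pairs.head(top_pairs).iterrows():
        g.add_node(row["lncrna"], kind="lncRNA")
        g.add_node(row["mrna"], kind="mRNA")
        for mir in row["shared_mirnas"]:
            g.add_node(mir, kind="miRNA")
            g.add_edge(row["lncrna"], mir)
            g.add_edge(mir, row["mrna"])
    return g


def network_census(g: nx.Graph) -> dict:
    kinds = nx.get_node_attributes(g, "kind")
    census = {"n_nodes": g.number_of_nodes(), "n_edges": g.number_of_edges()}
    for kind in ("lncRNA", "miRNA", "mRNA"):
        census[f"n_{kind}"] = sum(1 for v in kinds.values() if v == kind)
    return census
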