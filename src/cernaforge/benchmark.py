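"""Seeded benchmark experiments on synthetic data.

These are the package's standard calibration and recovery experiments:
type-I error of the NB Wald test under the null, recall of planted fold
changes, ceRNA planted-pair recovery through target prediction +
hypergeometric testing + co-expression, TF ternary edge recovery, and
end-to-end determinism.  Problem sizes are scaled so each experiment runs
in seconds; every draw is controlled by the supplied seed.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .cerna import (call_cerna, coexpression_pairs, normalize_scores,
                    score_candidate_pairs)
from .diffexpr import call_de, nb_wald_test, size_factors
from .quantify import CountMatrix
from .synthetic_data import SimConfig, simulate_counts, simulate_transcriptome
from .target_prediction import find_all_mres
from .tf_network import build_tf_ternary, scan_sequence

#: study conditions for the planted-pair recovery experiment: 10 triplets
#: with 3 shared miRNAs and 2 MREs per transcript, co-expression target
#: r = 0.9, 10 samples per group, ~5000 candidate lncRNA-mRNA pairs
RECOVERY_CONFIG = dict(n_mrna=100, n_lncrna=50, n_per_group=10,
                       n_triplets=10, shared_mirnas_per_triplet=3,
                       mres_per_transcript=2, cor_target=0.9)


def _nb_counts(rng, mu, alpha, n_samples):
    shape = 1.0 / alpha
    return rng.negative_binomial(shape, shape / (shape + mu[:, None]),
                                 size=(len(mu), n_samples))


def _count_matrix(nor, mod):
    n = nor.shape[1]
    samples = [f"NOR_{i+1}" for i in range(n)] + [f"MOD_{i+1}" for i in range(n)]
    return CountMatrix(
        counts=pd.DataFrame(np.hstack([nor, mod]), columns=samples,
                            index=[f"g{i}" for i in range(nor.shape[0])]),
        groups=pd.Series(["NOR"] * n + ["MOD"] * n, index=samples))


def null_rejection_rate(seed: int, n_features: int = 2000,
                        n_per_group: int = 5, alpha: float = 0.05) -> float:
    """Fraction of null features with Wald p < 0.05 (nominal: 0.05)."""
    rng = np.random.default_rng([seed, 31])
    mu = np.exp(rng.uniform(np.log(50), np.log(500), n_features))
    cm = _count_matrix(_nb_counts(rng, mu, alpha, n_per_group),
                       _nb_counts(rng, mu, alpha, n_per_group))
    res = nb_wald_test(cm, size_factors(cm), alpha)
    return float((res["p"] < 0.05).mean())


def planted_de_recall(seed: int, n_planted: int = 200, n_null: int = 1800,
                      mu_planted: float = 200.0, log2fc: float = 2.0,
                      n_per_group: int = 5, alpha: float = 0.05) -> float:
    """Recall of planted fold changes at |log2FC| >= 1 and adjusted
    p < 0.05, with the planted features embedded in a null background."""
    rng = np.random.default_rng([seed, 32])
    mu_bg = np.exp(rng.uniform(np.log(50), np.log(500), n_null))
    mu_pl = np.full(n_planted, mu_planted)
    nor = _nb_counts(rng, np.concatenate([mu_bg, mu_pl]), alpha, n_per_group)
    mod = _nb_counts(rng, np.concatenate([mu_bg, 2.0**log2fc * mu_pl]),
                     alpha, n_per_group)
    cm = _count_matrix(nor, mod)
    res, _ = call_de(nb_wald_test(cm, size_factors(cm), alpha))
    return float(res["is_de"].to_numpy()[-n_planted:].mean())


def cerna_recovery(seeds) -> dict:
    """Planted ceRNA pair recovery pooled over seeds.

    Runs target prediction over all transcripts, scores every candidate
    pair (hypergeometric + MuTaME), intersects with positive co-expression
    and compares the called pairs with the planted ground truth.
    """
    tp = called = planted_total = 0
    for seed in seeds:
        cfg = SimConfig(seed=int(seed), **RECOVERY_CONFIG)
        transcripts, truth = simulate_transcriptome(cfg)
        cm = simulate_counts(transcripts, truth, cfg)
        mirnas = {t.id: t.sequence for t in transcripts.values()
                  if t.biotype == "miRNA"}
        txs = [t for t in transcripts.values()
               if t.biotype in ("mRNA", "lncRNA")]
        sites = find_all_mres(mirnas, txs)
        lengths = {t.id: t.length for t in txs}
        lnc = [t.id for t in txs if t.biotype == "lncRNA"]
        mrna = [t.id for t in txs if t.biotype == "mRNA"]
        expr = np.log2(cm.counts + 1)
        coexpr = coexpression_pairs(expr.loc[lnc], expr.loc[mrna],
                                    lnc_lengths=lengths, mode="positive")
        scored = normalize_scores(score_candidate_pairs(
            sites, {i: lengths[i] for i in lnc},
            {i: lengths[i] for i in mrna}, set(mirnas)))
        pairs, _ = call_cerna(scored, coexpr)
        got = set(zip(pairs["lncrna"], pairs["mrna"]))
        want = {(l, m) for l, m, _ in truth.planted_pairs}
        tp += len(got & want)
        called += len(got)
        planted_total += len(want)
    return {"precision": tp / max(1, called),
            "recall": tp / max(1, planted_total),
            "n_called": called, "n_planted": planted_total}


def tf_edge_recovery(seed: int) -> dict:
    """Fraction of planted lncRNA-TF-mRNA edges recovered by the motif
    scan + regulation pairs + co-expression conjunction."""
    from .synthetic_data import simulate_tf_data

    cfg = SimConfig(seed=int(seed), **RECOVERY_CONFIG)
    transcripts, truth = simulate_transcriptome(cfg)
    pfms, tf_gene_pairs = simulate_tf_data(cfg, transcripts, truth)
    cm = simulate_counts(transcripts, truth, cfg)
    lnc = [t.id for t in transcripts.values() if t.biotype == "lncRNA"]
    mrna = [t.id for t in transcripts.values() if t.biotype == "mRNA"]
    lengths = {t.id: t.length for t in transcripts.values()}
    expr = np.log2(cm.counts + 1)
    coexpr = coexpression_pairs(expr.loc[lnc], expr.loc[mrna],
                                lnc_lengths=lengths, mode="positive")
    hits = []
    for pwm in pfms:
        for lid in lnc:
            hits.extend(scan_sequence(pwm, transcripts[lid].sequence,
                                      sequence_id=lid))
    ternary = build_tf_ternary(hits, tf_gene_pairs, coexpr, top=10**6)
    got = set(zip(ternary["lncrna"], ternary["tf"], ternary["mrna"]))
    want = set(truth.planted_tf_edges)
    recovered = len(got & want)
    return {"recovery": recovered / max(1, len(want)),
            "n_planted": len(want), "n_recovered": recovered}
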