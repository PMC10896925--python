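"""End-to-end pipeline: simulate -> quantify -> DE -> targets -> ceRNA ->
TF -> enrichment.

`run_all` executes the stages in dependency order on one seeded
configuration, writes every table under the output directory (TSV; networks
additionally as GraphML) and returns a manifest with the config echo,
per-file checksums, stage timings and the summary counts of the analysis
funnel.  Identical config + seed yields identical output checksums.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import cerna, diffexpr, enrichment, quantify, synthetic_data, tf_network
from .synthetic_data import SimConfig, sha256_of
from .target_prediction import ScoringParams, find_all_mres, aggregate_pairs

logger = logging.getLogger("cernaforge")

__version__ = "0.1.0"

STAGES = ("simulate", "quantify", "de", "targets", "cerna", "tf", "enrich")

DEFAULTS = {
    "seed": 0,
    "stages": {s: True for s in STAGES},
    "sim": {f.name: f.default if f.default is not dataclasses.MISSING
            else f.default_factory()
            for f in dataclasses.fields(SimConfig) if f.name != "seed"},
    "quantify": {"min_length": 200, "min_exons": 2, "min_mean": 2.0},
    "de": {"lfc_min": 1.0, "p_max": 0.05, "use_adjusted": True},
    "targets": {"score_min": 150.0, "energy_max": -30.0},
    "cerna": {"min_r": 0.8, "max_p": 0.05, "max_lnc_length": 6000,
              "p_hyper_max": 0.05, "top_pairs": 100},
    "tf": {"rel_threshold": 0.8, "top": 500},
    "enrich": {"top": 30},
    "bundle": None,  # path to an existing bundle when simulate is disabled
}


class ConfigError(ValueError):
    """Aggregated configuration problems."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


def validate_config(raw: dict | None) -> dict:
    """Fill defaults, reject unknown keys and out-of-range thresholds.

    All problems are collected and reported at once.
    """
    raw = dict(raw or {})
    errors = []
    config = json.loads(json.dumps(DEFAULTS))  # deep copy
    for key, value in raw.items():
        if key not in DEFAULTS:
            errors.append(f"unknown config key {key!r}")
            continue
        if isinstance(DEFAULTS[key], dict) and key != "stages":
            if not isinstance(value, dict):
                errors.append(f"{key} must be a mapping")
                continue
            for sub, v in value.items():
                if sub not in DEFAULTS[key]:
                    errors.append(f"unknown config key {key}.{sub}")
                else:
                    config[key][sub] = v
        elif key == "stages":
            for sub, v in (value or {}).items():
                if sub not in STAGES:
                    errors.append(f"unknown stage {sub!r}")
                else:
                    config["stages"][sub] = bool(v)
        else:
            config[key] = value

    def check(cond, msg):
        if not cond:
            errors.append(msg)

    c = config
    check(0.0 <= c["cerna"]["min_r"] <= 1.0, "cerna.min_r must be in [0, 1]")
    check(0.0 < c["cerna"]["max_p"] <= 1.0, "cerna.max_p must be in (0, 1]")
    check(0.0 < c["cerna"]["p_hyper_max"] <= 1.0,
          "cerna.p_hyper_max must be in (0, 1]")
    check(c["targets"]["score_min"] > 0, "targets.score_min must be > 0")
    check(c["targets"]["energy_max"] < 0, "targets.energy_max must be < 0")
    check(0.0 < c["de"]["p_max"] <= 1.0, "de.p_max must be in (0, 1]")
    check(c["de"]["lfc_min"] >= 0, "de.lfc_min must be >= 0")
    check(c["quantify"]["min_mean"] >= 0, "quantify.min_mean must be >= 0")
    check(0.0 <= c["tf"]["rel_threshold"] <= 1.0,
          "tf.rel_threshold must be in [0, 1]")
    check(int(c["seed"]) >= 0, "seed must be >= 0")
    if errors:
        raise ConfigError(errors)
    return config


def _write(df: pd.DataFrame, path: Path, files: dict, index=False) -> None:
    df.to_csv(path, sep="\t", index=index)
    files[path.name] = sha256_of(path)


def _write_graphml(g: nx.Graph, path: Path, files: dict) -> None:
    nx.write_graphml(g, str(path))
    files[path.name] = sha256_of(path)


def run_all(config: dict | None, outdir) -> dict:
    """Run the enabled stages in order and return the run manifest."""
    config = validate_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    timings: dict[str, float] = {}
    summary: dict[str, object] = {}
    stages = config["stages"]

    def timed(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, *exc):
                timings[name] = round(time.perf_counter() - self.t0, 3)
        return _T()

    def fail(stage, exc):
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # --- simulate / load -------------------------------------------------
    with timed("simulate"):
        try:
            if stages["simulate"]:
                sim = SimConfig(seed=int(config["seed"]), **config["sim"])
                bundle = synthetic_data.simulate_bundle(sim)
                manifest = synthetic_data.write_fixture_bundle(
                    out / "bundle", *bundle)
                for f, h in manifest["files"].items():
                    files[f"bundle/{f}"] = h
            elif config["bundle"]:
                bundle = synthetic_data.read_fixture_bundle(config["bundle"])
            else:
                raise FileNotFoundError(
                    "simulate disabled and no bundle path given")
        except Exception as exc:
            fail("simulate", exc)
    transcripts, counts, pfms, tf_gene_pairs, gene_sets, truth = bundle
    lengths = {t.id: t.length for t in transcripts.values()}
    mirnas = {t.id: t.sequence for t in transcripts.values()
              if t.biotype == "miRNA"}

    # --- quantify ---------------------------------------------------------
    fpkm = None
    lnc_kept: list[str] = []
    if stages["quantify"]:
        with timed("quantify"):
            try:
                q = config["quantify"]
                fpkm = quantify.compute_fpkm(counts, lengths)
                _write(fpkm, out / "fpkm.tsv", files, index=True)
                lncs = [t for t in transcripts.values()
                        if t.biotype == "lncRNA"]
                candidates = set(quantify.filter_lncrna_candidates(
                    lncs, q["min_length"], q["min_exons"]))
                expressed = set(quantify.filter_expressed(
                    counts, q["min_mean"]))
                lnc_kept = sorted(candidates & expressed)
                anno = quantify.genes_from_transcripts(transcripts.values())
                classes = pd.DataFrame(
                    [{"lncrna": t.id,
                      "class": quantify.classify_lncrna(t, anno).label()}
                     for t in lncs])
                _write(classes, out / "lncrna_classes.tsv", files)
                summary["n_lncrna_candidates"] = len(candidates)
                summary["n_lncrna_kept"] = len(lnc_kept)
            except Exception as exc:
                fail("quantify", exc)

    # --- differential expression ------------------------------------------
    de_ids: dict[str, list[str]] = {"lncRNA": [], "mRNA": []}
    if stages["de"]:
        with timed("de"):
            try:
                d = config["de"]
                factors = diffexpr.size_factors(counts)
                for biotype, fname in (("lncRNA", "de_lncrna.tsv"),
                                       ("mRNA", "de_mrna.tsv")):
                    ids = [t.id for t in transcripts.values()
                           if t.biotype == biotype]
                    if biotype == "lncRNA" and lnc_kept:
                        ids = [i for i in ids if i in set(lnc_kept)]
                    sub = quantify.CountMatrix(
                        counts=counts.counts.loc[ids], groups=counts.groups)
                    alpha = diffexpr.estimate_dispersion(sub, factors)
                    res = diffexpr.nb_wald_test(sub, factors, alpha)
                    res, census = diffexpr.call_de(
                        res, d["lfc_min"], d["p_max"], d["use_adjusted"])
                    _write(res, out / fname, files, index=True)
                    de_ids[biotype] = list(res.index[res["is_de"]])
                    summary[f"n_de_{biotype}"] = census
            except Exception as exc:
                fail("de", exc)

    # --- target prediction -------------------------------------------------
    sites = []
    if stages["targets"]:
        with timed("targets"):
            try:
                params = ScoringParams(
                    score_min=config["targets"]["score_min"],
                    energy_max=config["targets"]["energy_max"])
                targets = [transcripts[i]
                           for i in de_ids["lncRNA"] + de_ids["mRNA"]]
                sites = find_all_mres(mirnas, targets, params)
                site_df = pd.DataFrame(
                    [{"mirna": s.mirna, "target": s.target, "start": s.start,
                      "end": s.end, "score": s.score, "energy": s.energy}
                     for s in sites])
                _write(site_df, out / "mre_sites.tsv", files)
                pairs = aggregate_pairs(sites, lengths)
                biotype = {t.id: t.biotype for t in transcripts.values()}
                for bt, fname in (("lncRNA", "mirna_lncrna_pairs.tsv"),
                                  ("mRNA", "mirna_mrna_pairs.tsv")):
                    sel = pairs[pairs["target"].map(biotype) == bt]
                    _write(sel, out / fname, files)
                    summary[f"n_mirna_{bt}_pairs"] = len(sel)
            except Exception as exc:
                fail("targets", exc)

    # --- ceRNA --------------------------------------------------------------
    cerna_pairs = pd.DataFrame()
    coexpr = pd.DataFrame(columns=["lncrna", "mrna", "r", "p_r"])
    if stages["cerna"]:
        with timed("cerna"):
            try:
                cc = config["cerna"]
                expr = np.log2(fpkm + 1) if fpkm is not None else None
                if expr is None:
                    raise RuntimeError("cerna requires the quantify stage")
                lnc_de = [i for i in de_ids["lncRNA"]]
                mrna_de = list(de_ids["mRNA"])
                if lnc_de and mrna_de:
                    coexpr = cerna.coexpression_pairs(
                        expr.loc[lnc_de], expr.loc[mrna_de],
                        lnc_lengths=lengths, min_r=cc["min_r"],
                        max_p=cc["max_p"],
                        max_lnc_length=cc["max_lnc_length"],
                        mode="absolute")
                _write(coexpr, out / "coexpression.tsv", files)
                summary["n_coexpression_pairs"] = len(coexpr)
                scored = cerna.score_candidate_pairs(
                    sites,
                    {i: lengths[i] for i in lnc_de},
                    {i: lengths[i] for i in mrna_de},
                    set(mirnas))
                scored = cerna.normalize_scores(scored)
                pos = coexpr[coexpr["r"] >= cc["min_r"]]
                cerna_pairs, venn = cerna.call_cerna(
                    scored, pos, p_hyper_max=cc["p_hyper_max"],
                    min_r=cc["min_r"])
                flat = cerna_pairs.copy()
                if len(flat):
                    flat["shared_mirnas"] = flat["shared_mirnas"].map(
                        ",".join)
                _write(flat, out / "cerna_pairs.tsv", files)
                summary["cerna_venn"] = venn
                g = cerna.build_ternary_network(cerna_pairs,
                                                cc["top_pairs"])
                _write_graphml(g, out / "cerna_network.graphml", files)
                _write(nx.to_pandas_edgelist(g),
                       out / "cerna_network_edges.tsv", files)
                summary["cerna_network"] = cerna.network_census(g)
            except Exception as exc:
                fail("cerna", exc)

    # --- TF ternary network ---------------------------------------------------
    if stages["tf"]:
        with timed("tf"):
            try:
                tc = config["tf"]
                hits = []
                for pwm in pfms:
                    for lid in de_ids["lncRNA"]:
                        hits.extend(tf_network.scan_sequence(
                            pwm, transcripts[lid].sequence,
                            rel_threshold=tc["rel_threshold"],
                            sequence_id=lid))
                _write(tf_network.hits_to_frame(hits),
                       out / "tfbs_hits.tsv", files)
                ternary = tf_network.build_tf_ternary(
                    hits, tf_gene_pairs, coexpr, top=tc["top"])
                _write(ternary, out / "tf_ternary.tsv", files)
                summary["n_tf_ternary"] = len(ternary)
            except Exception as exc:
                fail("tf", exc)

    # --- enrichment --------------------------------------------------------------
    if stages["enrich"]:
        with timed("enrich"):
            try:
                collection = enrichment.GeneSetCollection.from_terms(
                    gene_sets) if gene_sets else None
                query = set(coexpr["mrna"]) if len(coexpr) else set()
                if collection and query & set(collection.universe):
                    res = enrichment.enrich(query, collection)
                    top = enrichment.top_items(res, config["enrich"]["top"])
                else:
                    res = top = pd.DataFrame(
                        columns=["term", "name", "k", "n", "K", "N", "p",
                                 "fold", "p_adj"])
                _write(res, out / "enrichment.tsv", files)
                _write(top, out / "enrichment_top.tsv", files)
                summary["n_enriched_terms"] = int(
                    (res["p_adj"] < 0.05).sum()) if len(res) else 0
            except Exception as exc:
                fail("enrich", exc)

    manifest = {
        "version": __version__,
        "config": config,
        "files": files,
        "timings": timings,
        "summary": summary,
    }
    (out / "run_manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str))
    return manifest
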