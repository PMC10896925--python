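"""Synthetic transcriptomes with planted ground truth.

The generator emulates the study design the pipeline targets: two groups of
negative-binomially distributed counts (three biological replicates each by
default), a fraction of features with a planted log2 fold change, and a set
of planted ceRNA triplets — a lncRNA and an mRNA that both carry miRNA
response elements for the same miRNAs and are co-expressed through a shared
log-normal latent factor.  Planted MREs are full reverse complements of the
miRNA, which deterministically clear the S >= 150 / dG <= -30 thresholds of
the target scanner, so downstream recovery can be scored against exact
ground truth.  TF motifs are planted by embedding a PWM consensus in the
lncRNA sequence and registering the (TF, gene) regulation pair.

Every draw flows from ``SimConfig.seed`` through per-stage
``numpy.random.default_rng`` streams, so identical configs produce
byte-identical bundles.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .quantify import CountMatrix, Transcript, _exon_blocks
from .target_prediction import revcomp_rna
from .tf_network import PWM, parse_pfm, write_pfm

_RNA = np.array(list("ACGU"))

#: intron size used when laying transcripts onto the synthetic genome
_INTRON = 100
_CHROMS = [f"chr{i}" for i in range(1, 6)]


@dataclass
class SimConfig:
    """Study conditions for the synthetic bundle.

    Defaults mirror the emulated design: 3 samples per group, 22-nt miRNAs,
    NB dispersion 0.05, planted |log2FC| = 2, triplets sharing 3 miRNAs with
    2 MREs per transcript and a target co-expression of r = 0.9.
    """

    n_mrna: int = 120
    n_lncrna: int = 40
    n_mirna: int = 60
    n_per_group: int = 3
    mirna_len: int = 22
    mrna_len_range: tuple = (400, 1500)
    lncrna_len_range: tuple = (300, 1200)
    de_fraction: float = 0.15
    planted_log2fc: float = 2.0
    nb_mean_range: tuple = (50.0, 500.0)
    nb_dispersion: float = 0.05
    n_triplets: int = 6
    shared_mirnas_per_triplet: int = 3
    mres_per_transcript: int = 2
    cor_target: float = 0.9
    n_tf: int = 6
    seed: int = 0

    def __post_init__(self):
        errors = []
        for name in ("n_mrna", "n_lncrna", "n_mirna", "n_per_group",
                     "mirna_len"):
            if getattr(self, name) <= 0:
                errors.append(f"{name} must be > 0")
        for name in ("n_triplets", "shared_mirnas_per_triplet",
                     "mres_per_transcript", "n_tf"):
            if getattr(self, name) < 0:
                errors.append(f"{name} must be >= 0")
        if not 0.0 <= self.de_fraction <= 1.0:
            errors.append("de_fraction must be in [0, 1]")
        if not 0.0 < self.cor_target <= 1.0:
            errors.append("cor_target must be in (0, 1]")
        if self.nb_dispersion <= 0:
            errors.append("nb_dispersion must be > 0")
        for name in ("mrna_len_range", "lncrna_len_range", "nb_mean_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                errors.append(f"{name} must satisfy 0 < lo <= hi")
        if self.n_triplets > min(self.n_lncrna, self.n_mrna):
            errors.append("n_triplets exceeds available lncRNAs or mRNAs")
        if self.shared_mirnas_per_triplet > self.n_mirna:
            errors.append("shared_mirnas_per_triplet exceeds n_mirna")
        if errors:
            raise ValueError("; ".join(errors))


@dataclass
class GroundTruth:
    """Everything that was planted, for downstream recovery scoring."""

    #: {(feature id, +1 | -1)}
    de_features: set = field(default_factory=set)
    #: [(miRNA id, transcript id, 0-based start)]
    planted_sites: list = field(default_factory=list)
    #: [(lncRNA id, mRNA id, (shared miRNA ids...))]
    planted_pairs: list = field(default_factory=list)
    #: [(lncRNA id, TF id, gene id)]
    planted_tf_edges: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "de_features": sorted([f, int(s)] for f, s in self.de_features),
            "planted_sites": [[m, t, int(p)] for m, t, p in self.planted_sites],
            "planted_pairs": [[l, m, list(ms)]
                              for l, m, ms in self.planted_pairs],
            "planted_tf_edges": [list(e) for e in self.planted_tf_edges],
        }, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            de_features={(f, int(s)) for f, s in d["de_features"]},
            planted_sites=[(m, t, int(p)) for m, t, p in d["planted_sites"]],
            planted_pairs=[(l, m, tuple(ms))
                           for l, m, ms in d["planted_pairs"]],
            planted_tf_edges=[tuple(e) for e in d["planted_tf_edges"]],
        )


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def _random_rna(rng, n: int) -> str:
    return "".join(rng.choice(_RNA, size=n))


def _plant_slots(length: int, k: int, site_len: int, rng,
                 transcript_id: str) -> list[int]:
    """k non-overlapping 0-based starts, one per equal slot of the
    transcript."""
    slot = length // k if k else length
    if slot < site_len:
        raise ValueError(
            f"transcript {transcript_id} too short ({length} nt) for "
            f"{k} planted site(s) of {site_len} nt")
    starts = []
    for i in range(k):
        starts.append(i * slot + int(rng.integers(0, slot - site_len + 1)))
    return starts


def simulate_transcriptome(config: SimConfig):
    """Sequences, annotation and planted sites/pairs/DE labels.

    Returns ``(transcripts, truth)`` where transcripts is an ordered dict of
    :class:`Transcript` (mRNAs, lncRNAs and miRNAs) and truth records every
    planted feature.  For each planted triplet, the designated lncRNA and
    mRNA each carry ``mres_per_transcript`` full-reverse-complement sites
    per shared miRNA; triplet members are also planted as upregulated DE
    features so they survive the DE funnel and correlate positively.
    """
    rng = _rng(config, 1)
    mirna_ids = [f"miR_{i+1:03d}" for i in range(config.n_mirna)]
    mrna_ids = [f"mRNA_{i+1:04d}" for i in range(config.n_mrna)]
    lnc_ids = [f"lnc_{i+1:04d}" for i in range(config.n_lncrna)]

    mirnas = {mid: _random_rna(rng, config.mirna_len) for mid in mirna_ids}
    lengths = {}
    for tid in mrna_ids:
        lengths[tid] = int(rng.integers(*config.mrna_len_range))
    for tid in lnc_ids:
        lengths[tid] = int(rng.integers(*config.lncrna_len_range))
    seqs = {tid: _random_rna(rng, lengths[tid])
            for tid in mrna_ids + lnc_ids}

    truth = GroundTruth()

    # planted ceRNA triplets: distinct partners per triplet; miRNA sets are
    # disjoint across triplets when the universe allows (independent ceRNA
    # modules), otherwise sampled independently
    trip_lncs = list(rng.choice(lnc_ids, config.n_triplets, replace=False))
    trip_mrnas = list(rng.choice(mrna_ids, config.n_triplets, replace=False))
    n_needed = config.n_triplets * config.shared_mirnas_per_triplet
    if n_needed <= config.n_mirna:
        flat = list(rng.choice(mirna_ids, n_needed, replace=False))
        mir_sets = [flat[i:i + config.shared_mirnas_per_triplet]
                    for i in range(0, n_needed,
                                   config.shared_mirnas_per_triplet)]
    else:
        mir_sets = [list(rng.choice(mirna_ids,
                                    config.shared_mirnas_per_triplet,
                                    replace=False))
                    for _ in range(config.n_triplets)]
    for (lnc, mrna), mirs in zip(zip(trip_lncs, trip_mrnas), mir_sets):
        shared = tuple(sorted(mirs))
        truth.planted_pairs.append((lnc, mrna, shared))
        for tid in (lnc, mrna):
            k = len(shared) * config.mres_per_transcript
            starts = _plant_slots(lengths[tid], k, config.mirna_len, rng, tid)
            s = list(seqs[tid])
            i = 0
            for mir in shared:
                for _ in range(config.mres_per_transcript):
                    start = starts[i]
                    i += 1
                    site = revcomp_rna(mirnas[mir])
                    s[start:start + len(site)] = site
                    truth.planted_sites.append((mir, tid, start))
            seqs[tid] = "".join(s)

    # planted DE features: triplet members up, the rest of the quota random
    planted = set()
    for lnc, mrna, _ in truth.planted_pairs:
        for tid in (lnc, mrna):
            truth.de_features.add((tid, +1))
            planted.add(tid)
    quota = int(round(config.de_fraction * (config.n_mrna + config.n_lncrna)))
    pool = [t for t in mrna_ids + lnc_ids if t not in planted]
    extra = max(0, quota - len(planted))
    for tid in rng.choice(pool, min(extra, len(pool)), replace=False):
        truth.de_features.add((str(tid), int(rng.choice([-1, 1]))))

    # genome layout: round-robin chromosomes, sequential intervals
    transcripts: dict[str, Transcript] = {}
    cursor = {c: 1 for c in _CHROMS}
    order = mrna_ids + lnc_ids + mirna_ids
    for i, tid in enumerate(order):
        if tid in mirnas:
            biotype, seq, n_exons = "miRNA", mirnas[tid], 1
        elif tid in lnc_ids:
            biotype, seq, n_exons = "lncRNA", seqs[tid], 3
        else:
            biotype, seq = "mRNA", seqs[tid]
            n_exons = int(rng.integers(2, 13))
        chrom = _CHROMS[i % len(_CHROMS)]
        start = cursor[chrom]
        span = len(seq) + _INTRON * (n_exons - 1)
        strand = "+" if rng.random() < 0.5 else "-"
        transcripts[tid] = Transcript(
            id=tid, biotype=biotype, sequence=seq, chrom=chrom,
            start=start, end=start + span - 1, strand=strand,
            n_exons=n_exons)
        cursor[chrom] = start + span + 5000
    return transcripts, truth


def simulate_counts(transcripts: dict, truth: GroundTruth,
                    config: SimConfig) -> CountMatrix:
    """NB counts for mRNA/lncRNA features over 2 x n_per_group samples.

    Planted DE features have their mean multiplied by 2^(sign * log2FC) in
    the MOD group.  Each planted pair shares a per-sample log-normal latent
    factor whose scale is set from the NB noise floor so the expected
    Pearson correlation of the pair's log counts is at least
    ``cor_target``.
    """
    rng = _rng(config, 2)
    features = [t.id for t in transcripts.values()
                if t.biotype in ("mRNA", "lncRNA")]
    samples = ([f"NOR_{i+1}" for i in range(config.n_per_group)]
               + [f"MOD_{i+1}" for i in range(config.n_per_group)])
    groups = pd.Series(["NOR"] * config.n_per_group
                       + ["MOD"] * config.n_per_group, index=samples)
    is_mod = (groups == "MOD").to_numpy()

    lo, hi = config.nb_mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(features)))
    lfc = np.zeros(len(features))
    fidx = {f: i for i, f in enumerate(features)}
    for fid, sign in truth.de_features:
        lfc[fidx[fid]] = sign * config.planted_log2fc

    log_mu = (np.log(base)[:, None]
              + np.log(2.0) * lfc[:, None] * is_mod[None, :])

    # Shared latent factor per planted pair.  The pair's log counts already
    # share the planted group shift (both partners are planted up), whose
    # across-sample variance is (ln2 * lfc)^2 / 4; the log-normal latent
    # factor tops the shared variance up to r/(1-r) times the independent
    # NB noise floor (1/mu + alpha on the log scale), so the expected
    # Pearson r of the pair's log counts is at least cor_target.
    alpha = config.nb_dispersion
    r = config.cor_target
    shift_var = (np.log(2.0) * config.planted_log2fc) ** 2 / 4.0
    for lnc, mrna, _ in truth.planted_pairs:
        z = rng.normal(size=len(samples))
        idx = [fidx[lnc], fidx[mrna]]
        noise = float(np.mean([1.0 / base[i] + alpha for i in idx]))
        lam_sq = max(0.0, 1.2 * r / (1.0 - r + 1e-12) * noise - shift_var)
        lam = np.sqrt(lam_sq)
        log_mu[idx] += lam * z[None, :] - lam_sq / 2.0

    mu = np.exp(log_mu)
    if alpha < 1e-9:
        counts = rng.poisson(mu)
    else:
        n_shape = 1.0 / alpha
        counts = rng.negative_binomial(n_shape, n_shape / (n_shape + mu))
    return CountMatrix(
        counts=pd.DataFrame(counts, index=features, columns=samples),
        groups=groups)


def simulate_tf_data(config: SimConfig, transcripts: dict,
                     truth: GroundTruth):
    """TF motifs, regulation pairs and planted ternary edges.

    One TF edge is planted per ceRNA triplet (when TFs are requested): the
    TF's consensus is embedded in the triplet's lncRNA at a position free of
    planted MREs, and (TF, mRNA partner) is registered as a regulation
    pair.  Decoy regulation pairs are added on top.  Mutates the lncRNA
    sequences in place.
    """
    rng = _rng(config, 3)
    if config.n_tf == 0:
        return [], pd.DataFrame(columns=["tf", "gene"])
    pwms = []
    for i in range(config.n_tf):
        L = int(rng.integers(8, 13))
        consensus = rng.integers(0, 4, size=L)
        counts = np.ones((4, L))
        counts[consensus, np.arange(L)] = 12.0
        pwms.append(PWM(tf_id=f"TF_{i+1:02d}", counts=counts))

    occupied: dict[str, list] = {}
    for mir, tid, start in truth.planted_sites:
        occupied.setdefault(tid, []).append((start, start + config.mirna_len))

    pairs = []
    for lnc, mrna, _ in truth.planted_pairs:
        pwm = pwms[int(rng.integers(0, len(pwms)))]
        motif = pwm.consensus.replace("T", "U")
        t = transcripts[lnc]
        pos = _free_position(len(t.sequence), len(motif),
                             occupied.get(lnc, []), rng)
        if pos is None:
            raise ValueError(f"transcript {lnc} has no room for a TF motif")
        t.sequence = (t.sequence[:pos] + motif
                      + t.sequence[pos + len(motif):])
        occupied.setdefault(lnc, []).append((pos, pos + len(motif)))
        truth.planted_tf_edges.append((lnc, pwm.tf_id, mrna))
        pairs.append((pwm.tf_id, mrna))

    # decoys: TFs paired with random genes not used above
    mrna_ids = [t.id for t in transcripts.values() if t.biotype == "mRNA"]
    for _ in range(2 * config.n_tf):
        tf = pwms[int(rng.integers(0, len(pwms)))].tf_id
        gene = str(rng.choice(mrna_ids))
        if (tf, gene) not in pairs:
            pairs.append((tf, gene))
    tf_gene_pairs = pd.DataFrame(pairs, columns=["tf", "gene"])
    return pwms, tf_gene_pairs


def _free_position(length: int, size: int, occupied: list, rng,
                   tries: int = 200):
    for _ in range(tries):
        pos = int(rng.integers(0, length - size + 1))
        if all(pos + size <= s or pos >= e for s, e in occupied):
            return pos
    return None


def simulate_gene_sets(config: SimConfig, transcripts: dict,
                       truth: GroundTruth) -> dict:
    """GMT-style terms over the mRNA universe.

    Eight random terms plus, when triplets were planted, one term collecting
    the planted mRNA partners (padded with random genes) so the enrichment
    stage has a recoverable signal.
    """
    rng = _rng(config, 4)
    mrna_ids = sorted(t.id for t in transcripts.values()
                      if t.biotype == "mRNA")
    terms = {}
    for i in range(8):
        hi = min(31, len(mrna_ids) + 1)
        lo = min(10, max(2, hi - 1))
        size = int(rng.integers(lo, hi)) if hi > lo else max(1, hi - 1)
        members = sorted(rng.choice(mrna_ids, size, replace=False))
        terms[f"GS_{i+1:02d}"] = (f"random gene set {i+1}", frozenset(members))
    planted = sorted({m for _, m, _ in truth.planted_pairs})
    if planted:
        pad = [g for g in mrna_ids if g not in planted]
        extra = list(rng.choice(pad, min(5, len(pad)), replace=False))
        terms["GS_planted"] = ("planted ceRNA target genes",
                               frozenset(planted + extra))
    return terms


# ---------------------------------------------------------------------------
# bundle I/O

def _write_fasta(path: Path, records: dict) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    recs = [SeqRecord(Seq(seq), id=rid, description="")
            for rid, seq in records.items()]
    SeqIO.write(recs, str(path), "fasta")


def _write_gtf(path: Path, transcripts: dict) -> None:
    biotype_attr = {"mRNA": "protein_coding", "lncRNA": "lncRNA",
                    "miRNA": "miRNA"}
    with open(path, "w") as fh:
        for t in transcripts.values():
            attrs = (f'gene_id "{t.id}"; transcript_id "{t.id}"; '
                     f'gene_biotype "{biotype_attr[t.biotype]}";')
            fh.write("\t".join([t.chrom, "cernaforge", "transcript",
                                str(t.start), str(t.end), ".", t.strand, ".",
                                attrs]) + "\n")
            for i, (e0, e1) in enumerate(_exon_blocks(t), 1):
                fh.write("\t".join([
                    t.chrom, "cernaforge", "exon", str(e0), str(e1), ".",
                    t.strand, ".", attrs + f' exon_number "{i}";']) + "\n")


def sha256_of(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_fixture_bundle(outdir, transcripts: dict, counts: CountMatrix,
                         pfms, tf_gene_pairs: pd.DataFrame, gene_sets: dict,
                         truth: GroundTruth) -> dict:
    """Serialize the whole synthetic bundle as plain-text files.

    Emits FASTA (transcripts, miRNAs), GTF, TSVs (counts, groups, TF-gene
    pairs), JASPAR PFM text, GMT, the ground-truth JSON and a manifest with
    a sha256 checksum per file.
    """
    out = Path(outdir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create bundle directory {out}: {exc}") from exc

    _write_fasta(out / "transcripts.fasta",
                 {t.id: t.sequence for t in transcripts.values()
                  if t.biotype in ("mRNA", "lncRNA")})
    _write_fasta(out / "mirnas.fasta",
                 {t.id: t.sequence for t in transcripts.values()
                  if t.biotype == "miRNA"})
    _write_gtf(out / "annotation.gtf", transcripts)
    counts.to_tsv(out / "counts.tsv", out / "groups.tsv")
    tf_gene_pairs.to_csv(out / "tf_gene_pairs.tsv", sep="\t", index=False)
    (out / "motifs.jaspar").write_text(write_pfm(pfms) if pfms else "")
    with open(out / "gene_sets.gmt", "w") as fh:
        for term in sorted(gene_sets):
            name, genes = gene_sets[term]
            fh.write("\t".join([term, name, *sorted(genes)]) + "\n")
    (out / "truth.json").write_text(truth.to_json())

    files = ["transcripts.fasta", "mirnas.fasta", "annotation.gtf",
             "counts.tsv", "groups.tsv", "tf_gene_pairs.tsv",
             "motifs.jaspar", "gene_sets.gmt", "truth.json"]
    manifest = {"files": {f: sha256_of(out / f) for f in files}}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return manifest


def read_fixture_bundle(bundle_dir):
    """Load a bundle back into the in-memory objects written by
    :func:`write_fixture_bundle`."""
    from Bio import SeqIO

    d = Path(bundle_dir)
    seqs = {}
    for fname in ("transcripts.fasta", "mirnas.fasta"):
        for rec in SeqIO.parse(str(d / fname), "fasta"):
            seqs[rec.id] = str(rec.seq)

    biotype_by_attr = {"protein_coding": "mRNA", "lncRNA": "lncRNA",
                       "miRNA": "miRNA"}
    transcripts: dict[str, Transcript] = {}
    with open(d / "annotation.gtf") as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if f[2] != "transcript":
                continue
            attrs = dict(
                kv.strip().split(" ", 1)
                for kv in f[8].rstrip(";").split(";") if kv.strip())
            tid = attrs["transcript_id"].strip('"')
            transcripts[tid] = Transcript(
                id=tid, biotype=biotype_by_attr[attrs["gene_biotype"].strip('"')],
                sequence=seqs[tid], chrom=f[0], start=int(f[3]),
                end=int(f[4]), strand=f[6], n_exons=0)
    with open(d / "annotation.gtf") as fh:
        for line in fh:
            f = line.split("\t")
            if f[2] == "exon":
                tid = f[8].split('transcript_id "')[1].split('"')[0]
                transcripts[tid].n_exons += 1

    counts = CountMatrix.from_tsv(d / "counts.tsv", d / "groups.tsv")
    pfm_text = (d / "motifs.jaspar").read_text()
    pfms = parse_pfm(pfm_text) if pfm_text.strip() else []
    tf_gene_pairs = pd.read_csv(d / "tf_gene_pairs.tsv", sep="\t")
    if tf_gene_pairs.empty:
        tf_gene_pairs = pd.DataFrame(columns=["tf", "gene"])
    gene_sets = {}
    with open(d / "gene_sets.gmt") as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 3:
                gene_sets[fields[0]] = (fields[1], frozenset(fields[2:]))
    truth = GroundTruth.from_json((d / "truth.json").read_text())
    return transcripts, counts, pfms, tf_gene_pairs, gene_sets, truth


def simulate_bundle(config: SimConfig):
    """Run every simulation stage; returns (transcripts, counts, pfms,
    tf_gene_pairs, gene_sets, truth)."""
    transcripts, truth = simulate_transcriptome(config)
    pfms, tf_gene_pairs = simulate_tf_data(config, transcripts, truth)
    counts = simulate_counts(transcripts, truth, config)
    gene_sets = simulate_gene_sets(config, transcripts, truth)
    return transcripts, counts, pfms, tf_gene_pairs, gene_sets, truth
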