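"""Expression quantification and lncRNA candidate handling.

FPKM is computed directly from a count matrix (counts x 1e9 / (length x
library size)), so per sample the identity sum_i FPKM_i x length_i = 1e9
holds whenever the library size is nonzero.  Candidate lncRNAs are kept when
longer than 200 nt with more than 2 exons (strict inequalities, as this
pipeline's inherited filter prints them), and when their mean count exceeds
2 in at least one group.  Positional classes (sense/antisense x
genic/intergenic x exonic/intronic/upstream/downstream) are assigned against
a protein-coding annotation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("cernaforge")

#: search window (bp) for the nearest coding gene of an intergenic lncRNA
INTERGENIC_WINDOW = 100_000


@dataclass
class Transcript:
    """A transcript with its sequence and genomic footprint.

    Genomic coordinates are 1-based closed (GTF convention); all site
    coordinates elsewhere in the package are 0-based half-open on the
    transcript sequence.
    """

    id: str
    biotype: str  # mRNA | lncRNA | miRNA
    sequence: str
    chrom: str = "chr1"
    start: int = 1
    end: int = 0
    strand: str = "+"
    n_exons: int = 1

    def __post_init__(self):
        if self.end < self.start:
            # default footprint: contiguous exons with 100-bp introns
            self.end = self.start + len(self.sequence) - 1 \
                + 100 * (self.n_exons - 1)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class CountMatrix:
    """Integer feature-by-sample counts plus a group label per sample."""

    counts: pd.DataFrame
    groups: pd.Series  # sample id -> {NOR, MOD}

    def __post_init__(self):
        self.groups = self.groups.reindex(self.counts.columns)
        if self.groups.isna().any():
            missing = self.counts.columns[self.groups.isna()].tolist()
            raise ValueError(f"samples without a group label: {missing}")
        if self.counts.isna().any().any():
            raise ValueError("count matrix contains missing cells")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if self.groups.nunique() < 1:
            raise ValueError("at least one group required")

    def group_means(self) -> pd.DataFrame:
        """Mean raw count per feature for each group (columns = groups)."""
        return self.counts.T.groupby(self.groups).mean().T

    def to_tsv(self, counts_path, groups_path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="feature_id")
        self.groups.rename("group").to_csv(
            groups_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, counts_path, groups_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        groups = pd.read_csv(groups_path, sep="\t", index_col=0)["group"]
        return cls(counts=counts, groups=groups)


def compute_fpkm(counts, lengths: Mapping[str, int]) -> pd.DataFrame:
    """FPKM_ij = counts_ij * 1e9 / (length_i * total_j).

    ``counts`` is a CountMatrix or a feature-by-sample DataFrame.  A sample
    with zero total reads yields an all-zero column (with a warning) rather
    than NaN.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    missing = [f for f in df.index if f not in lengths]
    if missing:
        raise KeyError(f"no length for feature(s): {missing[:5]}")
    lens = np.array([float(lengths[f]) for f in df.index])
    if (lens <= 0).any():
        raise ValueError("feature lengths must be positive")
    totals = df.sum(axis=0).to_numpy(dtype=float)
    zero = totals == 0
    if zero.any():
        logger.warning("sample(s) with zero total counts: %s",
                       list(df.columns[zero]))
        totals = np.where(zero, 1.0, totals)
    fpkm = df.to_numpy(dtype=float) * 1e9 / np.outer(lens, totals)
    fpkm[:, zero] = 0.0
    return pd.DataFrame(fpkm, index=df.index, columns=df.columns)


def filter_lncrna_candidates(transcripts: Iterable[Transcript],
                             min_length: int = 200,
                             min_exons: int = 2) -> list[str]:
    """Ids of transcripts with length > min_length AND n_exons > min_exons."""
    return [t.id for t in transcripts
            if t.length > min_length and t.n_exons > min_exons]


def filter_expressed(counts: CountMatrix, min_mean: float = 2.0) -> list[str]:
    """Ids whose mean count exceeds ``min_mean`` in at least one group."""
    gm = counts.group_means()
    keep = (gm > min_mean).any(axis=1)
    return list(gm.index[keep])


@dataclass(frozen=True)
class LncClass:
    """Positional class of a lncRNA relative to protein-coding annotation."""

    direction: str | None  # sense | antisense
    location: str          # genic | intergenic
    subtype: str | None    # exonic | intronic | upstream | downstream
    partner: str | None    # coding gene id, None when no gene in the window
    flagged: bool = False

    def label(self) -> str:
        parts = [p for p in (self.direction, self.location, self.subtype) if p]
        return "-".join(parts) if parts else self.location


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list = field(default_factory=list)  # (start, end) 1-based closed


def load_coding_annotation(gtf_path) -> dict[str, list[GeneModel]]:
    """Protein-coding gene/exon intervals from a GTF, keyed by chromosome."""
    import gffutils

    db = gffutils.create_db(str(gtf_path), ":memory:",
                            merge_strategy="create_unique",
                            disable_infer_genes=True,
                            disable_infer_transcripts=True)
    genes: dict[str, GeneModel] = {}
    for feat in db.features_of_type(("transcript", "exon")):
        biotype = feat.attributes.get("gene_biotype", [""])[0]
        if biotype != "protein_coding":
            continue
        gid = feat.attributes["gene_id"][0]
        g = genes.get(gid)
        if g is None:
            g = genes[gid] = GeneModel(gid, feat.seqid, feat.start, feat.end,
                                       feat.strand)
        g.start = min(g.start, feat.start)
        g.end = max(g.end, feat.end)
        if feat.featuretype == "exon":
            g.exons.append((feat.start, feat.end))
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes.values():
        by_chrom.setdefault(g.chrom, []).append(g)
    for lst in by_chrom.values():
        lst.sort(key=lambda g: (g.start, g.end))
    return by_chrom


def genes_from_transcripts(transcripts: Iterable[Transcript],
                           biotype: str = "mRNA") -> dict[str, list[GeneModel]]:
    """Coding annotation directly from in-memory transcripts (one gene per
    transcript; exons split uniformly with 100-bp introns, mirroring the
    bundle's GTF)."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for t in transcripts:
        if t.biotype != biotype:
            continue
        g = GeneModel(t.id, t.chrom, t.start, t.end, t.strand,
                      exons=list(_exon_blocks(t)))
        by_chrom.setdefault(t.chrom, []).append(g)
    for lst in by_chrom.values():
        lst.sort(key=lambda g: (g.start, g.end))
    return by_chrom


def _exon_blocks(t: Transcript):
    """1-based closed exon intervals: uniform split with 100-bp introns."""
    n = max(1, t.n_exons)
    sizes = [t.length // n] * n
    for i in range(t.length % n):
        sizes[i] += 1
    pos = t.start
    for size in sizes:
        yield (pos, pos + size - 1)
        pos += size + 100


def _overlap(a0, a1, b0, b1) -> int:
    return max(0, min(a1, b1) - max(a0, b0) + 1)


def classify_lncrna(lnc: Transcript,
                    annotation: Mapping[str, list[GeneModel]],
                    window: int = INTERGENIC_WINDOW) -> LncClass:
    """Assign the positional class of one lncRNA.

    Genic when the lncRNA span overlaps a coding gene span by >= 1 bp
    (subtype exonic if any exon is touched, else intronic); otherwise
    intergenic with the nearest coding gene within ``window`` bp as partner
    (subtype upstream when the lncRNA lies 5' of that gene in the gene's
    orientation).  Direction is sense when the strands agree.  With no
    coding gene in the window the class is flagged and carries no partner.
    """
    genes = annotation.get(lnc.chrom, [])
    overlapping = [g for g in genes
                   if _overlap(lnc.start, lnc.end, g.start, g.end) > 0]
    if overlapping:
        partner = max(overlapping,
                      key=lambda g: (_overlap(lnc.start, lnc.end,
                                              g.start, g.end), -g.start))
        exonic = any(_overlap(lnc.start, lnc.end, e0, e1) > 0
                     for e0, e1 in partner.exons)
        return LncClass(
            direction="sense" if lnc.strand == partner.strand else "antisense",
            location="genic",
            subtype="exonic" if exonic else "intronic",
            partner=partner.gene_id)

    def distance(g: GeneModel) -> int:
        if g.end < lnc.start:
            return lnc.start - g.end
        return g.start - lnc.end

    nearby = [g for g in genes if distance(g) <= window]
    if not nearby:
        logger.warning("lncRNA %s: no coding gene within %d bp", lnc.id, window)
        return LncClass(direction=None, location="intergenic", subtype=None,
                        partner=None, flagged=True)
    # ties broken toward the 5' (genomically leftward) gene
    partner = min(nearby, key=lambda g: (distance(g), g.start))
    lnc_is_left = lnc.end < partner.start
    if partner.strand == "+":
        subtype = "upstream" if lnc_is_left else "downstream"
    else:
        subtype = "downstream" if lnc_is_left else "upstream"
    return LncClass(
        direction="sense" if lnc.strand == partner.strand else "antisense",
        location="intergenic", subtype=subtype, partner=partner.gene_id)
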