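"""PWM-based TF binding prediction and the lncRNA-TF-mRNA ternary network.

JASPAR-style position frequency matrices are turned into log-odds matrices
(pseudocount 0.25 per cell, uniform background) and slid over both strands
of a sequence; a hit is emitted when the relative score — (score - min) /
(max - min), with min/max the sums of per-column extrema — reaches the
threshold (default 0.8).  A ternary edge (lncRNA, TF, mRNA) requires all
three evidence legs: a motif hit on the lncRNA, a (TF, gene) regulation
pair, and lncRNA-mRNA co-expression.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

_DNA = "ACGT"
_DNA_INDEX = {b: i for i, b in enumerate(_DNA)}
_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class PWM:
    """A TF motif: 4 x L count matrix (rows A, C, G, T)."""

    tf_id: str
    counts: np.ndarray
    pseudocount: float = 0.25
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape[0] != 4 or self.counts.shape[1] < 4:
            raise ValueError(f"{self.tf_id}: PWM must be 4 x L with L >= 4")
        if (self.counts < 0).any():
            raise ValueError(f"{self.tf_id}: negative counts")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def probabilities(self) -> np.ndarray:
        c = self.counts + self.pseudocount
        return c / c.sum(axis=0, keepdims=True)

    @property
    def log_odds(self) -> np.ndarray:
        """log2(P(base)/background), per cell."""
        return np.log2(self.probabilities / self.background[:, None])

    @property
    def consensus(self) -> str:
        return "".join(_DNA[i] for i in self.counts.argmax(axis=0))

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=0).sum())

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())


def parse_pfm(text: str) -> list[PWM]:
    """Parse JASPAR-format PFM text (4 base rows A/C/G/T per record)."""
    from Bio import motifs

    try:
        records = motifs.parse(StringIO(text), "jaspar")
    except Exception as exc:  # ragged rows, malformed numbers, ...
        raise ValueError(f"JASPAR PFM parse error: {exc}") from exc
    pwms = []
    for m in records:
        counts = np.array([m.counts[b] for b in _DNA], dtype=float)
        name = m.name or m.matrix_id
        pwms.append(PWM(tf_id=name, counts=counts))
    return pwms


def write_pfm(pwms: Iterable[PWM]) -> str:
    lines = []
    for p in pwms:
        lines.append(f">{p.tf_id} {p.tf_id}")
        for b in _DNA:
            row = " ".join(f"{int(v):6d}" for v in p.counts[_DNA_INDEX[b]])
            lines.append(f"{b} [{row} ]")
    return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class TFBSHit:
    tf: str
    sequence_id: str
    start: int  # 0-based half-open on the input (+) sequence
    end: int
    strand: str
    log_odds: float
    rel_score: float


def _scan_one_strand(lom: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Sliding log-odds sums; ambiguous bases (row 4) contribute 0."""
    L = lom.shape[1]
    n = len(idx) - L + 1
    if n <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(idx, L)
    return lom[windows, np.arange(L)].sum(axis=1)


def scan_sequence(pwm: PWM, seq: str, rel_threshold: float = 0.8,
                  strands: Sequence[str] = ("+", "-"),
                  sequence_id: str = "seq") -> list[TFBSHit]:
    """All motif hits with relative score >= threshold on the requested
    strands.  RNA input is accepted (U is read as T); N scores as
    background.  Minus-strand hits carry plus-strand coordinates.
    """
    s = seq.upper().replace("U", "T")
    L = pwm.length
    if len(s) < L:
        raise ValueError("sequence shorter than the motif")
    lom = np.vstack([pwm.log_odds, np.zeros(L)])  # row 4 = N
    lo, hi = pwm.min_score, pwm.max_score
    span = hi - lo if hi > lo else 1.0
    hits = []
    for strand in strands:
        scan_seq = s if strand == "+" else s.translate(_DNA_COMPLEMENT)[::-1]
        idx = np.array([_DNA_INDEX.get(b, 4) for b in scan_seq])
        scores = _scan_one_strand(lom, idx)
        rel = (scores - lo) / span
        for o in np.nonzero(rel >= rel_threshold)[0]:
            start = int(o) if strand == "+" else len(s) - int(o) - L
            hits.append(TFBSHit(
                tf=pwm.tf_id, sequence_id=sequence_id,
                start=start, end=start + L, strand=strand,
                log_odds=float(scores[o]), rel_score=float(rel[o])))
    return sorted(hits, key=lambda h: (h.start, h.strand))


def hits_to_frame(hits: Iterable[TFBSHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [vars(h) for h in hits],
        columns=["tf", "sequence_id", "start", "end", "strand",
                 "log_odds", "rel_score"])


def build_tf_ternary(lnc_hits: Iterable[TFBSHit],
                     tf_gene_pairs: pd.DataFrame,
                     coexpr: pd.DataFrame, top: int = 500) -> pd.DataFrame:
    """lncRNA-TF-mRNA triplets supported by all three evidence legs.

    (L, T, G) is emitted iff T has a motif hit on L, (T, G) is a known
    regulation pair, and (L, G) is a co-expression pair; triplets are ranked
    by |r| of (L, G) descending and truncated to ``top``.
    """
    hit_pairs = {(h.sequence_id, h.tf) for h in lnc_hits}
    reg = {(str(r.tf), str(r.gene)) for r in tf_gene_pairs.itertuples()}
    rows = []
    for row in coexpr.itertuples():
        for lnc, tf in hit_pairs:
            if lnc == row.lncrna and (tf, row.mrna) in reg:
                rows.append({"lncrna": lnc, "tf": tf, "mrna": row.mrna,
                             "r": row.r})
    out = pd.DataFrame(rows, columns=["lncrna", "tf", "mrna", "r"])
    out = out.drop_duplicates(["lncrna", "tf", "mrna"])
    out["abs_r"] = out["r"].abs()
    out = out.sort_values(["abs_r", "lncrna", "tf", "mrna"],
                          ascending=[False, True, True, True],
                          ignore_index=True).drop(columns="abs_r")
    return out.head(top)
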