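"""miRanda-style miRNA target-site discovery.

A candidate site is anchored by strict 5' seed pairing: miRNA positions 2-7
(1-based from the 5' end) must form six consecutive antiparallel Watson-Crick
pairs with the target (G.U wobble disallowed).  Each anchored site is then
extended by a gapped dynamic-programming alignment of the full miRNA against
the surrounding target window, scored with position weights (Watson-Crick +5,
G.U +2, mismatch -3, affine gaps -8/-2) in which miRNA positions 2-8 are
multiplied by a seed scale of 4.  The duplex free energy dG is a per-pair sum
(G-C -3, A-U -2, G-U -1 kcal/mol) over the paired positions of the S-optimal
alignment.  Sites are retained when S >= 150 and dG <= -30 kcal/mol, the
thresholds this pipeline inherits; the per-pair weights themselves are this
package's documented surrogate for miRanda/Vienna internals, and every one of
them is overridable through :class:`ScoringParams`.

Coordinates are 0-based half-open on the target sense strand; the miRNA is
never reverse-complemented (the target window is read antiparallel).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_RNA_BASES = frozenset("ACGU")

#: extra target bases allowed on each side of the ungapped footprint, to give
#: the aligner room for bulges
_GAP_PAD = 4


def as_rna(seq: str) -> str:
    """Uppercase and map T->U; reject anything outside {A, C, G, U}."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - _RNA_BASES
    if bad:
        raise ValueError(f"non-RNA characters in sequence: {sorted(bad)}")
    return s


def revcomp_rna(seq: str) -> str:
    return as_rna(seq).translate(_RNA_COMPLEMENT)[::-1]


def _pair_kind(m: str, t: str) -> str:
    """'wc', 'gu' or 'mm' for a miRNA base aligned to a target base."""
    if (m, t) in (("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")):
        return "wc"
    if (m, t) in (("G", "U"), ("U", "G")):
        return "gu"
    return "mm"


@dataclass(frozen=True)
class ScoringParams:
    """Surrogate miRanda scoring scheme; thresholds S >= 150, dG <= -30."""

    wc_score: float = 5.0
    gu_score: float = 2.0
    mismatch_score: float = -3.0
    gap_open: float = -8.0
    gap_extend: float = -2.0
    seed_scale: float = 4.0
    seed_scale_start: int = 2  # 1-based miRNA positions scaled ...
    seed_scale_end: int = 8    # ... inclusive
    score_min: float = 150.0
    energy_max: float = -30.0
    # kcal/mol per paired position, keyed by unordered base pair
    pair_energies: Mapping[frozenset, float] = field(
        default_factory=lambda: {
            frozenset("GC"): -3.0,
            frozenset("AU"): -2.0,
            frozenset("GU"): -1.0,
        }
    )

    def __post_init__(self):
        if self.score_min <= 0:
            raise ValueError("score_min must be > 0")
        if self.energy_max >= 0:
            raise ValueError("energy_max must be < 0")
        if self.seed_scale < 1:
            raise ValueError("seed_scale must be >= 1")

    def base_score(self, m: str, t: str) -> float:
        kind = _pair_kind(m, t)
        if kind == "wc":
            return self.wc_score
        if kind == "gu":
            return self.gu_score
        return self.mismatch_score

    def position_score(self, mirna_pos: int, m: str, t: str) -> float:
        """Score for miRNA position ``mirna_pos`` (1-based) aligned to t."""
        s = self.base_score(m, t)
        if self.seed_scale_start <= mirna_pos <= self.seed_scale_end:
            s *= self.seed_scale
        return s

    def pair_energy(self, m: str, t: str) -> float:
        if _pair_kind(m, t) == "mm":
            return 0.0
        return self.pair_energies[frozenset((m, t))]


DEFAULT_PARAMS = ScoringParams()


@dataclass(frozen=True)
class DuplexResult:
    """S-optimal constrained duplex between a miRNA and a target window."""

    score: float
    energy: float
    #: (miRNA position 1-based, window position 0-based, 'wc'|'gu'|'mm')
    pairs: tuple
    #: aligned footprint on the window, 0-based half-open
    span: tuple
    diagram: str


@dataclass(frozen=True)
class MRESite:
    """One predicted miRNA response element on a target transcript."""

    mirna: str
    target: str
    start: int
    end: int
    score: float
    energy: float
    paired_string: str = ""


def seed_match(mirna: str, target: str, offset: int) -> bool:
    """Strict 5' seed pairing at ``offset`` on the target.

    True iff miRNA positions 2-7 form six consecutive antiparallel
    Watson-Crick pairs (no G.U) with target[offset:offset+6), i.e. the
    target hexamer equals the reverse complement of the seed.
    """
    m = as_rna(mirna)
    t = as_rna(target)
    if len(m) < 8:
        raise ValueError("miRNA must be at least 8 nt")
    if offset < 0 or offset + 6 > len(t):
        raise ValueError("seed offset outside target")
    return t[offset:offset + 6] == revcomp_rna(m[1:7])


def _extend_flank(a: Sequence[str], a_pos: Sequence[int],
                  b: Sequence[str], b_pos: Sequence[int],
                  params: ScoringParams):
    """Best-scoring anchored extension of miRNA flank ``a`` along target
    flank ``b``.

    Both flanks are listed in extension order (moving away from the seed);
    gaps are affine and charged from the anchor, unaligned distal tails are
    free.  Returns (score, pairs) where pairs use the original coordinate
    labels carried in ``a_pos``/``b_pos``.
    """
    la, lb = len(a), len(b)
    if la == 0 or lb == 0:
        return 0.0, []
    NEG = -1e18
    go, ge = params.gap_open, params.gap_extend
    # M: ends in an aligned (paired) column; X: gap in miRNA (target bulge);
    # Y: gap in target (miRNA bulge).  back[state][i][j] = previous state.
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)
    Y = np.full((la + 1, lb + 1), NEG)
    back = {s: [[None] * (lb + 1) for _ in range(la + 1)] for s in "MXY"}
    M[0, 0] = 0.0
    for j in range(1, lb + 1):
        X[0, j] = go + (j - 1) * ge
        back["X"][0][j] = "M" if j == 1 else "X"
    for i in range(1, la + 1):
        Y[i, 0] = go + (i - 1) * ge
        back["Y"][i][0] = "M" if i == 1 else "Y"
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = params.position_score(a_pos[i - 1], a[i - 1], b[j - 1])
            prev = {"M": M[i - 1, j - 1], "X": X[i - 1, j - 1],
                    "Y": Y[i - 1, j - 1]}
            st = max(prev, key=lambda k: prev[k])
            M[i, j] = s + prev[st]
            back["M"][i][j] = st
            prev = {"M": M[i, j - 1] + go, "X": X[i, j - 1] + ge,
                    "Y": Y[i, j - 1] + go}
            st = max(prev, key=lambda k: prev[k])
            X[i, j] = prev[st]
            back["X"][i][j] = st
            prev = {"M": M[i - 1, j] + go, "Y": Y[i - 1, j] + ge,
                    "X": X[i - 1, j] + go}
            st = max(prev, key=lambda k: prev[k])
            Y[i, j] = prev[st]
            back["Y"][i][j] = st
    # free distal ends: stop at any aligned column (or not extend at all)
    best, bi, bj = 0.0, 0, 0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            if M[i, j] > best + 1e-12:
                best, bi, bj = M[i, j], i, j
    if bi == 0:
        return 0.0, []
    pairs = []
    i, j, state = bi, bj, "M"
    while not (i == 0 and j == 0):
        if state == "M":
            pairs.append((a_pos[i - 1], b_pos[j - 1],
                          _pair_kind(a[i - 1], b[j - 1])))
            state = back["M"][i][j]
            i, j = i - 1, j - 1
        elif state == "X":
            state = back["X"][i][j]
            j -= 1
        else:
            state = back["Y"][i][j]
            i -= 1
    pairs.reverse()
    return float(best), pairs


def score_duplex(mirna: str, window: str,
                 params: ScoringParams = DEFAULT_PARAMS,
                 seed_offset: int | None = None) -> DuplexResult:
    """Score the constrained duplex of a full miRNA against a target window.

    The seed hexamer (miRNA positions 2-7) is constrained to pair at
    ``seed_offset`` on the window (found automatically when omitted); the
    5' base and the 3' remainder of the miRNA are extended by gapped
    alignment with free distal ends.
    """
    m = as_rna(mirna)
    w = as_rna(window)
    if len(w) < 6:
        raise ValueError("target window shorter than the seed hexamer")
    if seed_offset is None:
        offsets = [o for o in range(len(w) - 5) if seed_match(m, w, o)]
        if not offsets:
            raise ValueError("no strict seed match in window")
        # best-scoring anchor wins; ties go to the leftmost
        return max((score_duplex(m, w, params, o) for o in offsets),
                   key=lambda d: d.score)
    if not seed_match(m, w, seed_offset):
        raise ValueError("strict seed pairing does not hold at seed_offset")

    o = seed_offset
    # fixed seed block: miRNA position p (2..7) pairs window o + (7 - p)
    pairs = [(p, o + 7 - p, "wc") for p in range(2, 8)]
    score = sum(params.position_score(p, m[p - 1], w[o + 7 - p])
                for p in range(2, 8))
    # 5' flank: miRNA position 1 extends to window positions o+6, o+7, ...
    s5, p5 = _extend_flank(
        [m[0]], [1],
        list(w[o + 6:]), list(range(o + 6, len(w))), params)
    # 3' flank: miRNA positions 8..L extend to window positions o-1, o-2, ...
    s3, p3 = _extend_flank(
        list(m[7:]), list(range(8, len(m) + 1)),
        list(w[:o][::-1]), list(range(o - 1, -1, -1)), params)
    score += s5 + s3
    pairs = sorted(pairs + p5 + p3, key=lambda x: x[1])

    energy = sum(params.pair_energy(m[p - 1], w[q]) for p, q, _ in pairs)
    span = (min(q for _, q, _ in pairs), max(q for _, q, _ in pairs) + 1)
    diagram = _diagram(m, w, pairs, span)
    return DuplexResult(float(score), float(energy), tuple(pairs), span, diagram)


def _diagram(m: str, w: str, pairs, span) -> str:
    """Three-line duplex diagram: target 5'->3', pairing marks, miRNA 3'->5'."""
    marks = {"wc": "|", "gu": ":", "mm": " "}
    by_window = {q: (p, kind) for p, q, kind in pairs}
    top, mid, bot = [], [], []
    for q in range(span[0], span[1]):
        top.append(w[q])
        if q in by_window:
            p, kind = by_window[q]
            mid.append(marks[kind])
            bot.append(m[p - 1])
        else:
            mid.append(" ")
            bot.append("-")
    return (f"target 5'-{''.join(top)}-3'\n"
            f"          {''.join(mid)}\n"
            f"mirna  3'-{''.join(bot)}-5'")


def find_mres(mirna: str, target, params: ScoringParams = DEFAULT_PARAMS,
              mirna_id: str = "miRNA", target_id: str | None = None
              ) -> list[MRESite]:
    """All retained miRNA response elements of one miRNA on one target.

    ``target`` may be a raw sequence or any object with ``id`` and
    ``sequence`` attributes.  Every strict-seed anchor is scored; candidate
    sites are first resolved for overlap greedily by descending S (ties:
    leftmost), then filtered by S >= score_min and dG <= energy_max, so that
    weakening either threshold can only add sites.
    """
    if hasattr(target, "sequence"):
        t = as_rna(target.sequence)
        target_id = target_id or target.id
    else:
        t = as_rna(target)
        target_id = target_id or "target"
    m = as_rna(mirna)
    L = len(m)
    anchor = revcomp_rna(m[1:7])
    candidates = []
    o = t.find(anchor)
    while o != -1:
        ws = max(0, o - (L - 7) - _GAP_PAD)
        we = min(len(t), o + 7 + _GAP_PAD)
        dup = score_duplex(m, t[ws:we], params, seed_offset=o - ws)
        candidates.append(MRESite(
            mirna=mirna_id, target=target_id,
            start=ws + dup.span[0], end=ws + dup.span[1],
            score=dup.score, energy=dup.energy,
            paired_string=dup.diagram))
        o = t.find(anchor, o + 1)
    # greedy overlap resolution over all candidates, then thresholds
    accepted: list[MRESite] = []
    for site in sorted(candidates, key=lambda s: (-s.score, s.start)):
        if all(site.end <= a.start or site.start >= a.end for a in accepted):
            accepted.append(site)
    kept = [s for s in accepted
            if s.score >= params.score_min and s.energy <= params.energy_max]
    return sorted(kept, key=lambda s: s.start)


def find_all_mres(mirnas: Mapping[str, str], targets: Iterable,
                  params: ScoringParams = DEFAULT_PARAMS) -> list[MRESite]:
    """find_mres over every (miRNA, target) combination."""
    sites: list[MRESite] = []
    for mid in sorted(mirnas):
        for tr in targets:
            sites.extend(find_mres(mirnas[mid], tr, params, mirna_id=mid))
    return sites


def aggregate_pairs(sites: Iterable[MRESite],
                    target_lengths: Mapping[str, int]) -> pd.DataFrame:
    """Per-(miRNA, target) aggregation of retained sites.

    Columns mirror the standard target-prediction table: total/max score,
    total/max energy (max energy = the strongest, i.e. most negative, site),
    target length and MRE count.
    """
    rows: dict[tuple, list[MRESite]] = {}
    for s in sites:
        rows.setdefault((s.mirna, s.target), []).append(s)
    out = []
    for (mid, tid), ss in sorted(rows.items()):
        out.append({
            "mirna": mid,
            "target": tid,
            "total_score": sum(s.score for s in ss),
            "total_energy": sum(s.energy for s in ss),
            "max_score": max(s.score for s in ss),
            "max_energy": min(s.energy for s in ss),
            "target_length": int(target_lengths[tid]),
            "mre_count": len(ss),
        })
    return pd.DataFrame(
        out, columns=["mirna", "target", "total_score", "total_energy",
                      "max_score", "max_energy", "target_length", "mre_count"])
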