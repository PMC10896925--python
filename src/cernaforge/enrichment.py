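"""Gene-set over-representation analysis (GO/KEGG-style, GMT input).

For a query gene set of size n drawn from a universe of N genes, a term with
K members and k query hits gets the upper-tail hypergeometric p-value
P(X >= k); p-values are Benjamini-Hochberg adjusted across all tested terms
and results are ranked by (p ascending, fold enrichment descending, term
id).  The universe defaults to the union of all GMT terms.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from ._stats import bh_adjust, hypergeom_upper_tail

logger = logging.getLogger("cernaforge")


@dataclass
class GeneSetCollection:
    """term id -> (term name, member genes); plus the gene universe."""

    sets: dict
    universe: frozenset

    def __post_init__(self):
        self.sets = {t: (name, frozenset(g) & self.universe)
                     for t, (name, g) in self.sets.items()}
        empty = [t for t, (_, g) in self.sets.items() if not g]
        if empty:
            raise ValueError(f"empty term(s) after harmonization: {empty}")

    @classmethod
    def from_terms(cls, terms: dict, universe=None) -> "GeneSetCollection":
        """``terms``: term id -> (name, iterable of gene ids)."""
        if universe is None:
            universe = frozenset().union(*(g for _, g in terms.values()))
        return cls(sets=dict(terms), universe=frozenset(universe))


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: term <tab> description <tab> gene1 <tab> gene2 ..."""
    terms = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs a term, "
                                 "a description and >= 1 gene")
            terms[fields[0]] = (fields[1], frozenset(fields[2:]))
    return GeneSetCollection.from_terms(terms)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for term in sorted(collection.sets):
            name, genes = collection.sets[term]
            fh.write("\t".join([term, name, *sorted(genes)]) + "\n")


def enrich(query, collection: GeneSetCollection) -> pd.DataFrame:
    """Hypergeometric over-representation of every term in the query."""
    query = set(query)
    harmonized = query & collection.universe
    dropped = len(query) - len(harmonized)
    if dropped:
        logger.warning("%d query gene(s) outside the universe dropped",
                       dropped)
    if not harmonized:
        raise ValueError("query is empty after harmonization to the universe")
    N = len(collection.universe)
    n = len(harmonized)
    rows = []
    for term in sorted(collection.sets):
        name, members = collection.sets[term]
        K = len(members)
        k = len(harmonized & members)
        p = hypergeom_upper_tail(k, N, K, n)
        rows.append({"term": term, "name": name, "k": k, "n": n, "K": K,
                     "N": N, "p": p, "fold": (k / n) / (K / N)})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"])
    return out.sort_values(["p", "fold", "term"],
                           ascending=[True, False, True], ignore_index=True)


def top_items(results: pd.DataFrame, m: int = 30) -> pd.DataFrame:
    """First ``m`` terms by (p asc, fold desc, term id) — a total order."""
    ranked = results.sort_values(["p", "fold", "term"],
                                 ascending=[True, False, True],
                                 ignore_index=True)
    return ranked.head(m)
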