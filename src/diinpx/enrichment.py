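"""Over-representation analysis with fold enrichment.

Given a query protein list (e.g. the differentially abundant proteins)
and an annotation collection (term -> member proteins over a declared
background), each term with at least one query hit is scored with the
one-sided hypergeometric upper tail

    p = P[X >= k],  X ~ Hypergeom(N population, K term members, n drawn)

and the fold enrichment (k/n) / (K/N).  P-values are BH-adjusted across
tested terms; a term is significant at FDR < 0.05 by default.  Terms may
carry a category label (immune-inflammatory, cell-cell signaling,
metabolic, other) used only for book-keeping tallies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_fdr

CATEGORIES = ("immune-inflammatory", "cell-cell signaling", "metabolic", "other")


@dataclass(frozen=True)
class AnnotationCollection:
    """Gene-set terms over a fixed background panel."""

    terms: dict[str, set[str]]
    background: set[str]
    descriptions: dict[str, str] = field(default_factory=dict)
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for term, members in self.terms.items():
            if not members:
                raise ValueError(f"term {term!r} is empty")
            extra = members - self.background
            if extra:
                raise ValueError(
                    f"term {term!r} has members outside the background: {sorted(extra)[:5]}"
                )


def load_gmt(path, background: set[str] | None = None) -> AnnotationCollection:
    """Read a GMT file (term <tab> description <tab> member ...).

    If ``background`` is not given it defaults to the union of all term
    members.  Members outside an explicit background are an error.
    """
    terms: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            term, desc, members = parts[0], parts[1], set(parts[2:]) - {""}
            terms[term] = members
            descriptions[term] = desc
    if background is None:
        background = set().union(*terms.values()) if terms else set()
    return AnnotationCollection(
        terms=terms, background=set(background), descriptions=descriptions
    )


def load_background(path) -> set[str]:
    """One identifier per line."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def enrich(
    query: set[str],
    collection: AnnotationCollection,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each term.

    Only terms hit by the query (k >= 1) are tested and BH-adjusted.
    Returns a table sorted by p with columns ``term description category
    k n K N fold_enrichment p fdr significant``.
    """
    query = set(query)
    if not query:
        raise ValueError("query set is empty")
    outside = query - collection.background
    if outside:
        raise ValueError(f"query proteins outside background: {sorted(outside)}")
    N = len(collection.background)
    n = len(query)
    rows = []
    for term, members in collection.terms.items():
        K = len(members)
        k = len(query & members)
        if k == 0:
            continue
        rows.append(
            {
                "term": term,
                "description": collection.descriptions.get(term, ""),
                "category": collection.categories.get(term, "other"),
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "fold_enrichment": (k / n) / (K / N),
                "p": float(stats.hypergeom.sf(k - 1, N, K, n)),
            }
        )
    res = pd.DataFrame(
        rows,
        columns=[
            "term", "description", "category", "k", "n", "K", "N",
            "fold_enrichment", "p", "fdr",
        ] if not rows else None,
    )
    if res.empty:
        res["fdr"] = []
        res["significant"] = []
        return res
    res["fdr"] = bh_fdr(res["p"])
    res["significant"] = res["fdr"] < alpha
    return res.sort_values(["p", "term"], ignore_index=True)


def category_tally(results: pd.DataFrame) -> pd.Series:
    """Counts of significant terms per category (sums to total significant)."""
    sig = results.loc[results["significant"]]
    return sig.groupby("category").size()
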