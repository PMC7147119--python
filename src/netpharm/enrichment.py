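"""Over-representation analysis of network targets.

Local replacement for web-service enrichment tools: annotation terms are
read from GMT files, the query gene list is filtered from a network by
degree, each term is scored with the exact hypergeometric upper tail,
and p-values are Benjamini-Hochberg adjusted.

Conventions: the background defaults to all genes appearing in the
annotation collection; only terms intersecting the query (k >= 1) are
reported, but every term with at least one background gene counts toward
the BH denominator, which is conservative and reproducible.  Only
over-representation is tested, never depletion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .disease import normalize_symbol
from .networks import BipartiteNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationCollection",
    "EnrichmentResult",
    "EnrichmentReport",
    "read_gmt",
    "write_gmt",
    "filter_by_degree",
    "hypergeom_upper",
    "bh_adjust",
    "enrich",
]


@dataclass
class AnnotationCollection:
    """term id -> (term name, gene set), plus an optional background."""

    terms: dict[str, tuple[str, frozenset[str]]]
    background: frozenset[str] | None = None

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for _, genes in self.terms.values():
            out.update(genes)
        return frozenset(out)


def read_gmt(path: str | Path) -> AnnotationCollection:
    """Read a GMT file (term, description, genes... per tab-separated line)."""
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    n_skipped = 0
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            logger.warning("%s:%d: malformed GMT line skipped", path, lineno)
            n_skipped += 1
            continue
        term, name = parts[0], parts[1]
        genes = frozenset(normalize_symbol(g) for g in parts[2:] if g.strip())
        if not genes:
            logger.warning("%s:%d: empty term %r dropped", path, lineno, term)
            n_skipped += 1
            continue
        terms[term] = (name, genes)
    if not terms:
        raise ValueError(f"no usable terms in GMT file {path}")
    return AnnotationCollection(terms=terms)


def write_gmt(ann: AnnotationCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in sorted(ann.terms):
            name, genes = ann.terms[term]
            fh.write("\t".join([term, name, *sorted(genes)]) + "\n")


def filter_by_degree(net: BipartiteNetwork, min_degree_exclusive: int = 2) -> list[str]:
    """Target nodes with degree strictly greater than the cutoff, sorted."""
    degrees = dict(net.graph.degree())
    return sorted(
        t for t in net.nodes_of_type("target")
        if degrees[t] > min_degree_exclusive
    )


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N is the background size, K the term size in background, n the query
    size, k the observed overlap.  Computed via the survival function in
    log space (scipy), exact to double precision.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K <= N and 0 <= n <= N, got k={k} K={K} n={n} N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"need 0 <= k <= min(K, n), got k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues: Iterable[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


@dataclass
class EnrichmentResult:
    """One term's overlap statistics: k of K term genes among the n query
    genes drawn from a background of N."""

    term: str
    name: str
    k: int
    K: int
    n: int
    N: int
    p: float
    p_adj: float
    genes: frozenset[str]


@dataclass
class EnrichmentReport:
    """Ranked term results plus the retained (top-k, significant) subset."""

    results: list[EnrichmentResult]
    retained: list[EnrichmentResult]
    background_size: int
    query_size: int
    n_terms_tested: int

    def to_frame(self, retained_only: bool = False) -> pd.DataFrame:
        rows = self.retained if retained_only else self.results
        return pd.DataFrame(
            [
                {
                    "term": r.term, "name": r.name, "k": r.k, "K": r.K,
                    "n": r.n, "N": r.N, "p": r.p, "p_adj": r.p_adj,
                    "genes": ";".join(sorted(r.genes)),
                }
                for r in rows
            ]
        )

    def to_tsv(self, path: str | Path, retained_only: bool = False) -> None:
        self.to_frame(retained_only).to_csv(path, sep="\t", index=False,
                                            float_format="%.6g")


def enrich(
    query: Iterable[str],
    ann: AnnotationCollection,
    background: Iterable[str] | None = None,
    top_k: int = 20,
    alpha: float = 0.05,
) -> EnrichmentReport:
    """Hypergeometric over-representation of the query in each term.

    Query genes outside the background are dropped with a warning.  One
    result per term with k >= 1, sorted by (p_adj asc, p asc, term id);
    ``retained`` is the first ``top_k`` of those with p_adj < ``alpha``.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if background is None:
        bg = ann.background or ann.all_genes()
    else:
        bg = frozenset(normalize_symbol(g) for g in background)
    query_set = {normalize_symbol(g) for g in query}
    dropped = query_set - bg
    if dropped:
        logger.warning("dropping %d query gene(s) outside the background",
                       len(dropped))
        query_set -= dropped
    if not query_set:
        raise ValueError("query is empty after restricting to the background")

    N, n = len(bg), len(query_set)
    tested: list[tuple[str, str, int, int, frozenset[str]]] = []
    n_family = 0
    for term in sorted(ann.terms):
        name, genes = ann.terms[term]
        term_bg = genes & bg
        K = len(term_bg)
        if K == 0:
            continue
        n_family += 1  # every term present in background counts toward BH
        hit = term_bg & query_set
        if hit:
            tested.append((term, name, len(hit), K, frozenset(hit)))

    pvals = [hypergeom_upper(k, K, n, N) for _, _, k, K, _ in tested]
    # pad with p=1 for family members with k=0 so BH uses the full denominator
    padded = bh_adjust(pvals + [1.0] * (n_family - len(pvals)))[: len(pvals)]
    results = [
        EnrichmentResult(term=term, name=name, k=k, K=K, n=n, N=N,
                         p=p, p_adj=p_adj, genes=hit)
        for (term, name, k, K, hit), p, p_adj in zip(tested, pvals, padded)
    ]
    results.sort(key=lambda r: (r.p_adj, r.p, r.term))
    retained = [r for r in results[:top_k] if r.p_adj < alpha]
    return EnrichmentReport(results=results, retained=retained,
                            background_size=N, query_size=n,
                            n_terms_tested=n_family)
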